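"""Domain records for a hospital antibiotic-prescribing cohort.

The unit of analysis throughout the package is the *medication order*: one
prescription episode for one antimicrobial agent via one route, with explicit
start and (possibly open) stop timestamps.  Laboratory observations (CRP,
leukocytes, neutrophils) and daily oral-intake status records hang off the
patient and feed the switch trigger rules.

All timestamps are ISO-8601 date-times and all durations are computed in
hours, because the trigger windows are defined in hours ("48 to 72 h").
Lab units: CRP in mg/L; leukocyte and neutrophil counts in 10^9 cells per
litre.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Route",
    "WardGroup",
    "Analyte",
    "MedicationOrder",
    "LabObservation",
    "IntakeStatus",
    "Cohort",
    "CohortValidationError",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "duration_hours",
    "write_reminder_report",
]


class Route(str, enum.Enum):
    IV = "iv"
    ORAL = "oral"


class WardGroup(str, enum.Enum):
    INTERVENTION = "intervention"
    CONTROL = "control"


class Analyte(str, enum.Enum):
    CRP = "crp"
    LEUKOCYTES = "leukocytes"
    NEUTROPHILS = "neutrophils"


class SchemaError(ValueError):
    """A CSV file does not conform to the expected schema."""


class CohortValidationError(ValueError):
    """One or more records violate a cohort invariant."""


def _canon_drug(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


@dataclass
class MedicationOrder:
    """One antibiotic prescription episode.

    ``stop`` is ``None`` for an order still running at the end of the
    observation window; duration-based outcomes censor such orders at the
    window end.  ``high_dose_flag`` marks severe-infection dosing as judged
    by the hospital's per-agent dose table (carried as a boolean because the
    cut-offs are configuration, not data).
    """

    order_id: str
    patient_id: str
    admission_id: str
    drug: str
    route: Route
    dose_mg_per_day: float
    start: datetime
    stop: datetime | None
    ward_group: WardGroup
    high_dose_flag: bool = False

    def __post_init__(self) -> None:
        self.drug = _canon_drug(self.drug)
        self.route = Route(self.route)
        self.ward_group = WardGroup(self.ward_group)
        if self.dose_mg_per_day <= 0:
            raise CohortValidationError(
                f"order {self.order_id!r}: dose_mg_per_day must be positive"
            )
        if self.stop is not None and self.stop <= self.start:
            raise CohortValidationError(
                f"order {self.order_id!r}: stop {self.stop} is not after start {self.start}"
            )

    def active_at(self, ts: datetime) -> bool:
        """True while the order is running: start <= ts < stop (open = no stop)."""
        return self.start <= ts and (self.stop is None or ts < self.stop)


def duration_hours(order: MedicationOrder, as_of: datetime) -> float:
    """Hours elapsed from order start to ``min(stop, as_of)``.

    Open orders use ``as_of``.  Raises if ``as_of`` precedes the start.
    """
    if as_of < order.start:
        raise ValueError(
            f"as_of {as_of} precedes start of order {order.order_id!r} ({order.start})"
        )
    end = as_of if order.stop is None else min(order.stop, as_of)
    return max(0.0, (end - order.start).total_seconds() / 3600.0)


@dataclass
class LabObservation:
    patient_id: str
    analyte: Analyte
    value: float
    taken_at: datetime

    def __post_init__(self) -> None:
        self.analyte = Analyte(self.analyte)
        if self.value < 0:
            raise CohortValidationError(
                f"lab for {self.patient_id!r}: value {self.value} is negative"
            )


@dataclass
class IntakeStatus:
    """Daily oral-intake proxy: parenteral-only medication and/or TPN flags."""

    patient_id: str
    date: date
    parenteral_only: bool = False
    tpn: bool = False
    discharged_on: date | None = None


@dataclass
class Cohort:
    """Validated container binding orders, labs and intake records."""

    orders: list[MedicationOrder]
    labs: list[LabObservation] = field(default_factory=list)
    intake: list[IntakeStatus] = field(default_factory=list)
    observation_window: tuple[date, date] | None = None

    def __post_init__(self) -> None:
        if self.observation_window is None:
            self.observation_window = self._infer_window()
        self.validate()
        self._index()

    def _infer_window(self) -> tuple[date, date]:
        if not self.orders:
            today = date.today()
            return (today, today)
        lo = min(o.start for o in self.orders).date()
        ts: list[datetime] = [o.stop for o in self.orders if o.stop is not None]
        ts += [l.taken_at for l in self.labs]
        hi = max([o.start for o in self.orders] + ts).date()
        for rec in self.intake:
            hi = max(hi, rec.date)
            if rec.discharged_on is not None:
                hi = max(hi, rec.discharged_on)
        return (lo, hi)

    def validate(self) -> None:
        problems: list[str] = []
        order_patients = {o.patient_id for o in self.orders}
        lo, hi = self.observation_window
        lo_dt = datetime.combine(lo, datetime.min.time())
        hi_dt = datetime.combine(hi, datetime.max.time())

        stray = sorted(
            {r.patient_id for r in self.labs} | {r.patient_id for r in self.intake}
        ) if not order_patients else sorted(
            {r.patient_id for r in (*self.labs, *self.intake)} - order_patients
        )
        if stray:
            problems.append(
                f"lab/intake records for patients with no medication order: {stray[:10]}"
            )
        out = [
            o.order_id
            for o in self.orders
            if o.start < lo_dt or (o.stop is not None and o.stop > hi_dt)
        ]
        if out:
            problems.append(f"orders outside observation window: {out[:10]}")
        bad_labs = [
            l.patient_id for l in self.labs if not (lo_dt <= l.taken_at <= hi_dt)
        ]
        if bad_labs:
            problems.append(f"labs outside observation window for: {bad_labs[:10]}")
        seen: set[tuple[str, date]] = set()
        dupes = []
        for rec in self.intake:
            key = (rec.patient_id, rec.date)
            if key in seen:
                dupes.append(key)
            seen.add(key)
        if dupes:
            problems.append(f"duplicate intake records (patient, day): {dupes[:10]}")
        dup_orders = pd.Series([o.order_id for o in self.orders])
        dup_ids = dup_orders[dup_orders.duplicated()].tolist()
        if dup_ids:
            problems.append(f"duplicate order ids: {dup_ids[:10]}")
        if problems:
            raise CohortValidationError("; ".join(problems))

    def _index(self) -> None:
        self._orders_by_patient: dict[str, list[MedicationOrder]] = {}
        for o in self.orders:
            self._orders_by_patient.setdefault(o.patient_id, []).append(o)
        self._labs_by_patient: dict[tuple[str, Analyte], list[LabObservation]] = {}
        for l in self.labs:
            self._labs_by_patient.setdefault((l.patient_id, l.analyte), []).append(l)
        for obs in self._labs_by_patient.values():
            obs.sort(key=lambda l: l.taken_at)
        self._intake_by_patient_day = {
            (r.patient_id, r.date): r for r in self.intake
        }

    # -- query helpers used by the trigger engine -------------------------

    def orders_for_patient(self, patient_id: str) -> list[MedicationOrder]:
        return self._orders_by_patient.get(patient_id, [])

    def labs_for(self, patient_id: str, analyte: Analyte) -> list[LabObservation]:
        """Observations for one patient and analyte, sorted by time."""
        return self._labs_by_patient.get((patient_id, Analyte(analyte)), [])

    def latest_lab(
        self, patient_id: str, analyte: Analyte, as_of: datetime
    ) -> LabObservation | None:
        obs = [
            l for l in self.labs_for(patient_id, analyte) if l.taken_at <= as_of
        ]
        return obs[-1] if obs else None

    def intake_on(self, patient_id: str, day: date) -> IntakeStatus | None:
        return self._intake_by_patient_day.get((patient_id, day))

    def iv_orders(self) -> list[MedicationOrder]:
        return [o for o in self.orders if o.route is Route.IV]


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_ORDER_COLS = [
    "order_id", "patient_id", "admission_id", "drug", "route",
    "dose_mg_per_day", "start", "stop", "ward_group", "high_dose_flag",
]
_LAB_COLS = ["patient_id", "analyte", "value", "taken_at"]
_INTAKE_COLS = ["patient_id", "date", "parenteral_only", "tpn", "discharged_on"]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _parse_bool(raw, path, line: int, col: str) -> bool:
    s = "" if raw is None or (isinstance(raw, float) and pd.isna(raw)) else str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise SchemaError(f"{path} line {line}: cannot parse {col}={raw!r} as boolean")


def _parse_dt(raw, path, line: int, col: str, *, optional: bool = False):
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
        if optional:
            return None
        raise SchemaError(f"{path} line {line}: empty {col}")
    try:
        return pd.Timestamp(str(raw)).to_pydatetime()
    except (ValueError, TypeError) as exc:
        raise SchemaError(
            f"{path} line {line}: unparseable timestamp {col}={raw!r}"
        ) from exc


def read_cohort(
    orders_path,
    labs_path=None,
    intake_path=None,
    observation_window: tuple[date, date] | None = None,
) -> Cohort:
    """Load and validate a cohort from the three CSV interchange files.

    ``labs_path`` and ``intake_path`` may be omitted (empty collections).
    Raises :class:`SchemaError` for malformed files (naming the column or
    the offending line) and :class:`CohortValidationError` for records that
    violate a cohort invariant (naming the offending ids).
    """
    odf = pd.read_csv(orders_path, dtype=str, keep_default_na=False)
    _require_columns(odf, _ORDER_COLS, orders_path)
    orders = []
    for i, row in enumerate(odf.itertuples(index=False), start=2):
        try:
            dose = float(row.dose_mg_per_day)
        except ValueError as exc:
            raise SchemaError(
                f"{orders_path} line {i}: bad dose_mg_per_day {row.dose_mg_per_day!r}"
            ) from exc
        orders.append(
            MedicationOrder(
                order_id=row.order_id,
                patient_id=row.patient_id,
                admission_id=row.admission_id,
                drug=row.drug,
                route=Route(row.route),
                dose_mg_per_day=dose,
                start=_parse_dt(row.start, orders_path, i, "start"),
                stop=_parse_dt(row.stop, orders_path, i, "stop", optional=True),
                ward_group=WardGroup(row.ward_group),
                high_dose_flag=_parse_bool(row.high_dose_flag, orders_path, i, "high_dose_flag"),
            )
        )

    labs: list[LabObservation] = []
    if labs_path is not None:
        ldf = pd.read_csv(labs_path, dtype=str, keep_default_na=False)
        _require_columns(ldf, _LAB_COLS, labs_path)
        for i, row in enumerate(ldf.itertuples(index=False), start=2):
            labs.append(
                LabObservation(
                    patient_id=row.patient_id,
                    analyte=Analyte(row.analyte),
                    value=float(row.value),
                    taken_at=_parse_dt(row.taken_at, labs_path, i, "taken_at"),
                )
            )

    intake: list[IntakeStatus] = []
    if intake_path is not None:
        idf = pd.read_csv(intake_path, dtype=str, keep_default_na=False)
        _require_columns(idf, _INTAKE_COLS, intake_path)
        for i, row in enumerate(idf.itertuples(index=False), start=2):
            disch = _parse_dt(row.discharged_on, intake_path, i, "discharged_on", optional=True)
            intake.append(
                IntakeStatus(
                    patient_id=row.patient_id,
                    date=_parse_dt(row.date, intake_path, i, "date").date(),
                    parenteral_only=_parse_bool(row.parenteral_only, intake_path, i, "parenteral_only"),
                    tpn=_parse_bool(row.tpn, intake_path, i, "tpn"),
                    discharged_on=disch.date() if disch is not None else None,
                )
            )

    return Cohort(orders=orders, labs=labs, intake=intake,
                  observation_window=observation_window)


def _iso(ts) -> str:
    return "" if ts is None else pd.Timestamp(ts).isoformat()


def write_cohort(cohort: Cohort, out_dir) -> dict[str, str]:
    """Write ``orders.csv``, ``labs.csv`` and ``intake.csv`` into ``out_dir``.

    Returns the mapping of logical name to written path.  ``read_cohort`` on
    the output reproduces the cohort field-by-field (round-trip invariant).
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "orders": os.path.join(out_dir, "orders.csv"),
        "labs": os.path.join(out_dir, "labs.csv"),
        "intake": os.path.join(out_dir, "intake.csv"),
    }
    pd.DataFrame(
        [
            {
                "order_id": o.order_id,
                "patient_id": o.patient_id,
                "admission_id": o.admission_id,
                "drug": o.drug,
                "route": o.route.value,
                "dose_mg_per_day": repr(o.dose_mg_per_day),
                "start": _iso(o.start),
                "stop": _iso(o.stop),
                "ward_group": o.ward_group.value,
                "high_dose_flag": o.high_dose_flag,
            }
            for o in cohort.orders
        ],
        columns=_ORDER_COLS,
    ).to_csv(paths["orders"], index=False)
    pd.DataFrame(
        [
            {
                "patient_id": l.patient_id,
                "analyte": l.analyte.value,
                "value": repr(l.value),
                "taken_at": _iso(l.taken_at),
            }
            for l in cohort.labs
        ],
        columns=_LAB_COLS,
    ).to_csv(paths["labs"], index=False)
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "date": r.date.isoformat(),
                "parenteral_only": r.parenteral_only,
                "tpn": r.tpn,
                "discharged_on": "" if r.discharged_on is None else r.discharged_on.isoformat(),
            }
            for r in cohort.intake
        ],
        columns=_INTAKE_COLS,
    ).to_csv(paths["intake"], index=False)
    return paths


REMINDER_REPORT_COLS = [
    "patient_id", "order_id", "drug", "reminder_number", "generated_on",
    "suggested_oral_options", "exclusions_fired",
]


def write_reminder_report(reminders: Iterable, path) -> None:
    """Write one CSV row per reminder — the analogue of the printed switch
    notice handed to the ward (patient, agent, suggested oral options).

    The ``exclusions_fired`` column carries the rule trace and is empty for
    an eligible (emitted) reminder.
    """
    rows = [
        {
            "patient_id": ev.patient_id,
            "order_id": ev.order_id,
            "drug": ev.drug,
            "reminder_number": ev.reminder_number,
            "generated_on": ev.generated_on.isoformat(),
            "suggested_oral_options": ";".join(ev.suggested_oral_options),
            "exclusions_fired": ";".join(
                r.value for r, fired in ev.exclusions_evaluated if fired
            ),
        }
        for ev in reminders
    ]
    pd.DataFrame(rows, columns=REMINDER_REPORT_COLS).to_csv(path, index=False)
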