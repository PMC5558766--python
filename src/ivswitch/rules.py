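"""Electronic switch-trigger rule engine.

Every morning the engine scans all active intravenous antibiotic orders and
emits a switch reminder for each order that (a) falls in one of two elapsed-
time windows — by default 48–72 h for the first reminder and 96–120 h for
the second — (b) trips none of five exclusion rules (rising CRP,
neutropenia, leukopenia, no oral intake, severe-infection regimen), and
(c) has not already been converted to oral therapy.  At most two reminders
are ever issued per order, to limit alert fatigue, and no reminders go out
on weekend days.

Rule semantics are deliberately conservative on missing data: an absent lab
or intake record never excludes a patient — the reminder is advisory and
the switch decision stays with the physician.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable, Literal, Mapping, Sequence

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .records import (
    Analyte,
    Cohort,
    LabObservation,
    MedicationOrder,
    Route,
)

__all__ = [
    "ExclusionReason",
    "RuleConfig",
    "ReminderEvent",
    "ReminderState",
    "crp_is_increasing",
    "check_exclusions",
    "reminder_window",
    "suggest_oral_options",
    "has_switched",
    "run_daily_trigger",
    "run_trigger_range",
    "DEFAULT_PROTOCOL_MAP",
]


class ExclusionReason(str, enum.Enum):
    """The five conditions that preclude an iv-to-oral switch reminder."""

    CRP_INCREASE = "crp_increase"
    NEUTROPENIA = "neutropenia"
    LEUKOPENIA = "leukopenia"
    NO_ORAL_INTAKE = "no_oral_intake"
    SEVERE_INFECTION_REGIMEN = "severe_infection_regimen"


#: Default iv → oral substitution protocol.  Third-generation cephalosporins
#: map to amoxicillin/clavulanic acid (similar empirical spectrum); agents
#: with good oral bioavailability map to their own oral formulation.
DEFAULT_PROTOCOL_MAP: dict[str, list[str]] = {
    "ceftriaxone": ["amoxicillin/clavulanic acid"],
    "cefotaxim": ["amoxicillin/clavulanic acid"],
    "ciprofloxacin": ["ciprofloxacin"],
    "clindamycin": ["clindamycin"],
    "metronidazole": ["metronidazole"],
    "fluconazole": ["fluconazole"],
    "amoxicillin": ["amoxicillin"],
    "flucloxacillin": ["flucloxacillin"],
}

#: Agents reserved for severe infection / no oral formulation (carbapenems).
DEFAULT_SEVERE_AGENTS = ["meropenem", "imipenem", "ertapenem"]


class RuleConfig(BaseModel):
    """Tunable thresholds and windows of the trigger algorithm.

    Windows are half-open ``[lo, hi)`` intervals in hours elapsed since the
    order start, evaluated at the daily run time; lab thresholds are in
    10^9 cells per litre.
    """

    first_window_hours: tuple[float, float] = (48.0, 72.0)
    second_window_hours: tuple[float, float] = (96.0, 120.0)
    neutrophil_threshold: float = 0.5
    leukocyte_threshold: float = 1.0
    severe_infection_agents: set[str] = Field(
        default_factory=lambda: set(DEFAULT_SEVERE_AGENTS)
    )
    high_dose_is_severe: bool = True
    protocol_map: dict[str, list[str]] = Field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_PROTOCOL_MAP.items()}
    )
    max_reminders: int = 2
    run_time_of_day: time = time(7, 0)
    weekend_days: set[int] = Field(default_factory=lambda: {5, 6})  # Mon=0 .. Sun=6
    crp_mode: Literal["previous", "minimum", "first"] = "previous"
    switch_detection_window_hours: float = 24.0

    @field_validator("neutrophil_threshold", "leukocyte_threshold")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("lab thresholds must be positive")
        return v

    @field_validator("max_reminders")
    @classmethod
    def _at_least_one(cls, v: int) -> int:
        if v < 1:
            raise ValueError("max_reminders must be >= 1")
        return v

    @field_validator("weekend_days")
    @classmethod
    def _valid_weekdays(cls, v: set[int]) -> set[int]:
        if not all(0 <= d <= 6 for d in v):
            raise ValueError("weekend_days must be weekday numbers 0..6 (Mon=0)")
        return v

    @model_validator(mode="after")
    def _windows_ordered(self) -> "RuleConfig":
        lo1, hi1 = self.first_window_hours
        lo2, hi2 = self.second_window_hours
        if not (lo1 < hi1 and lo2 < hi2):
            raise ValueError("each window must satisfy lo < hi")
        if hi1 > lo2:
            raise ValueError("first window must precede (and not overlap) the second")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RuleConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = self.model_dump(mode="json")
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class ReminderEvent:
    """One emitted switch reminder with its full rule trace.

    ``exclusions_evaluated`` records every exclusion rule checked and its
    outcome; an emitted event necessarily has all booleans false.
    """

    order_id: str
    patient_id: str
    reminder_number: int
    generated_on: date
    drug: str
    suggested_oral_options: list[str]
    exclusions_evaluated: list[tuple[ExclusionReason, bool]]

    def __post_init__(self) -> None:
        if self.reminder_number not in (1, 2):
            raise ValueError("reminder_number must be 1 or 2")


@dataclass
class ReminderState:
    """Per-order reminder history threaded through the daily runs."""

    counts: dict[str, int] = field(default_factory=dict)
    dates: dict[str, list[date]] = field(default_factory=dict)

    def count(self, order_id: str) -> int:
        return self.counts.get(order_id, 0)

    def record(self, event: ReminderEvent) -> None:
        self.counts[event.order_id] = self.counts.get(event.order_id, 0) + 1
        self.dates.setdefault(event.order_id, []).append(event.generated_on)


def crp_is_increasing(
    labs: Sequence[LabObservation],
    treatment_start: datetime,
    as_of: datetime,
    mode: Literal["previous", "minimum", "first"] = "previous",
) -> bool:
    """Is the patient's CRP rising during the current iv treatment episode?

    Considers CRP observations in ``[treatment_start, as_of]``.  With fewer
    than two observations the answer is False — missing data never
    precludes a switch.  ``mode`` selects the comparator for the most
    recent value: the immediately preceding value (default), the episode
    minimum, or the first value of the episode.
    """
    if as_of <= treatment_start:
        raise ValueError("as_of must be after treatment_start")
    window = sorted(
        (l for l in labs
         if l.analyte is Analyte.CRP and treatment_start <= l.taken_at <= as_of),
        key=lambda l: l.taken_at,
    )
    if len(window) < 2:
        return False
    latest = window[-1].value
    if mode == "previous":
        ref = window[-2].value
    elif mode == "minimum":
        ref = min(l.value for l in window[:-1])
    else:  # first
        ref = window[0].value
    return latest > ref


def _run_datetime(day: date, config: RuleConfig) -> datetime:
    return datetime.combine(day, config.run_time_of_day)


def check_exclusions(
    order: MedicationOrder,
    cohort: Cohort,
    config: RuleConfig,
    as_of: date,
) -> list[ExclusionReason]:
    """Evaluate the five exclusion rules for one active iv order.

    Returns the reasons that fired, in fixed enum order.  Rules consult the
    latest data available at the morning run time; absent data never fires
    a rule.
    """
    if order.route is not Route.IV:
        raise ValueError(f"order {order.order_id!r} is not an iv order")
    run_dt = _run_datetime(as_of, config)
    fired: list[ExclusionReason] = []

    crp = crp_is_increasing(
        cohort.labs_for(order.patient_id, Analyte.CRP),
        order.start,
        run_dt,
        mode=config.crp_mode,
    ) if run_dt > order.start else False
    if crp:
        fired.append(ExclusionReason.CRP_INCREASE)

    neut = cohort.latest_lab(order.patient_id, Analyte.NEUTROPHILS, run_dt)
    if neut is not None and neut.value < config.neutrophil_threshold:
        fired.append(ExclusionReason.NEUTROPENIA)

    leuk = cohort.latest_lab(order.patient_id, Analyte.LEUKOCYTES, run_dt)
    if leuk is not None and leuk.value < config.leukocyte_threshold:
        fired.append(ExclusionReason.LEUKOPENIA)

    intake = cohort.intake_on(order.patient_id, as_of)
    if intake is not None and (intake.parenteral_only or intake.tpn):
        fired.append(ExclusionReason.NO_ORAL_INTAKE)

    if order.drug in config.severe_infection_agents or (
        order.high_dose_flag and config.high_dose_is_severe
    ):
        fired.append(ExclusionReason.SEVERE_INFECTION_REGIMEN)

    return fired


def evaluate_exclusions(
    order: MedicationOrder,
    cohort: Cohort,
    config: RuleConfig,
    as_of: date,
) -> list[tuple[ExclusionReason, bool]]:
    """Full trace: every exclusion reason paired with whether it fired."""
    fired = set(check_exclusions(order, cohort, config, as_of))
    return [(r, r in fired) for r in ExclusionReason]


def reminder_window(
    order: MedicationOrder,
    as_of: date,
    prior_reminders: int,
    config: RuleConfig,
) -> int:
    """Which reminder (1, 2, or 0 = none) the elapsed time calls for.

    Elapsed hours are measured from the order start to the configured
    morning run time on ``as_of``; windows are half-open.  The second
    window may issue a first reminder for an order that was missed in the
    first window, but never beyond ``max_reminders`` total.
    """
    if prior_reminders < 0:
        raise ValueError("prior_reminders must be >= 0")
    if prior_reminders >= config.max_reminders:
        return 0
    run_dt = _run_datetime(as_of, config)
    if run_dt < order.start:
        return 0
    elapsed = (run_dt - order.start).total_seconds() / 3600.0
    lo1, hi1 = config.first_window_hours
    lo2, hi2 = config.second_window_hours
    if lo1 <= elapsed < hi1 and prior_reminders == 0:
        return 1
    if lo2 <= elapsed < hi2 and prior_reminders <= 1:
        return 2
    return 0


def suggest_oral_options(drug: str, config: RuleConfig) -> list[str]:
    """Oral options from the switch protocol; empty when the agent is
    unmapped (the reminder is still emitted with the options field blank)."""
    return list(config.protocol_map.get(drug, []))


def has_switched(
    order: MedicationOrder,
    cohort: Cohort,
    config: RuleConfig,
    as_of_run: datetime,
) -> bool:
    """Has an oral conversion already been performed for this iv order?

    A switch is an oral order for the same patient, for the same agent or a
    protocol alternative, starting within the configured window (default
    24 h) of the iv order's stop, and already started by ``as_of_run``.
    An open iv order has by definition not been switched.
    """
    if order.stop is None:
        return False
    candidates = {order.drug, *config.protocol_map.get(order.drug, [])}
    tol = timedelta(hours=config.switch_detection_window_hours)
    for other in cohort.orders_for_patient(order.patient_id):
        if other.route is not Route.ORAL or other.drug not in candidates:
            continue
        if other.start <= as_of_run and abs(other.start - order.stop) <= tol:
            return True
    return False


def run_daily_trigger(
    cohort: Cohort,
    day: date,
    config: RuleConfig,
    state: ReminderState,
) -> list[ReminderEvent]:
    """One morning run: scan every active iv order and emit reminders.

    Each prescription is checked independently, so a patient on two iv
    antibiotics can receive two reminders the same morning.  Weekend days
    produce nothing (reminders are suppressed, not deferred).  Emitted
    events are ordered by (patient_id, order_id) and recorded in ``state``.
    """
    lo, hi = cohort.observation_window
    if not (lo <= day <= hi):
        raise ValueError(f"day {day} outside observation window [{lo}, {hi}]")
    if day.weekday() in config.weekend_days:
        return []
    run_dt = _run_datetime(day, config)
    events: list[ReminderEvent] = []
    for order in sorted(cohort.iv_orders(), key=lambda o: (o.patient_id, o.order_id)):
        if not order.active_at(run_dt):
            continue
        number = reminder_window(order, day, state.count(order.order_id), config)
        if number == 0:
            continue
        trace = evaluate_exclusions(order, cohort, config, day)
        if any(f for _, f in trace):
            continue
        if has_switched(order, cohort, config, run_dt):
            continue
        events.append(
            ReminderEvent(
                order_id=order.order_id,
                patient_id=order.patient_id,
                reminder_number=number,
                generated_on=day,
                drug=order.drug,
                suggested_oral_options=suggest_oral_options(order.drug, config),
                exclusions_evaluated=trace,
            )
        )
    for ev in events:
        state.record(ev)
    return events


def run_trigger_range(
    cohort: Cohort,
    start_day: date,
    end_day: date,
    config: RuleConfig | None = None,
    state: ReminderState | None = None,
) -> list[ReminderEvent]:
    """Run the daily trigger over an inclusive date range, threading the
    reminder history, and return all emitted events in chronological order."""
    if config is None:
        config = RuleConfig()
    if state is None:
        state = ReminderState()
    events: list[ReminderEvent] = []
    day = start_day
    while day <= end_day:
        events.extend(run_daily_trigger(cohort, day, config, state))
        day += timedelta(days=1)
    return events
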