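"""Appropriateness review of switch reminders.

After a reminder, the attending physician either converts the order to oral
therapy or continues iv, and returns a form stating the considerations.  A
reviewer then scores each order against four switch criteria — no
indication for prolonged iv treatment (e.g. S. aureus bacteremia,
endocarditis, meningitis), improving vital signs, cultured organism (if
any) susceptible to an oral agent, and a functional GI tract — and the
combination of criteria and action yields one of four appropriateness
categories.  Orders whose patient left hospital on the possible switch day
are excluded up front, and forms not returned (or generated on a weekend)
are not evaluable.

Adherence is the fraction of switch-eligible prescriptions (all four
criteria met, evaluable) that were actually converted to oral therapy.
"""

from __future__ import annotations

import enum
import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SwitchCriteria",
    "ImpedingReason",
    "SwitchForm",
    "SwitchCategory",
    "ReviewSummary",
    "categorize",
    "summarize",
    "second_reminder_summary",
    "read_forms",
    "write_forms",
]


class ImpedingReason(str, enum.Enum):
    """Physician-reported reasons for not switching."""

    CLINICAL_INSTABILITY = "clinical_instability"
    NO_ORAL_INTAKE = "no_oral_intake"
    SEVERE_INFECTION = "severe_infection"
    RESISTANT_ORGANISM_NO_ORAL_OPTION = "resistant_organism_no_oral_option"


class SwitchCategory(str, enum.Enum):
    APPROPRIATE_SWITCH = "appropriate_switch"
    INAPPROPRIATE_SWITCH = "inappropriate_switch"
    APPROPRIATE_IV_CONTINUATION = "appropriate_iv_continuation"
    INAPPROPRIATE_IV_CONTINUATION = "inappropriate_iv_continuation"
    NOT_EVALUABLE = "not_evaluable"
    EXCLUDED_DISCHARGE = "excluded_discharge"


@dataclass(frozen=True)
class SwitchCriteria:
    """The reviewer's four switch criteria; all four must hold for a
    prescription to be eligible for oral conversion."""

    no_prolonged_iv_indication: bool
    improving_vitals: bool
    organism_oral_susceptible_or_not_cultured: bool
    functional_gi_tract: bool

    def all_met(self) -> bool:
        return (
            self.no_prolonged_iv_indication
            and self.improving_vitals
            and self.organism_oral_susceptible_or_not_cultured
            and self.functional_gi_tract
        )


@dataclass(frozen=True)
class SwitchForm:
    """One returned (or missing) switch form attached to a reminder."""

    order_id: str
    reminder_number: int
    criteria: SwitchCriteria
    switched: bool
    impeding_reason: ImpedingReason | None = None
    returned: bool = True
    generated_on_weekend: bool = False
    discharged_on_switch_day: bool = False

    def __post_init__(self) -> None:
        if self.switched and self.impeding_reason is not None:
            raise ValueError(
                f"form for order {self.order_id!r}: impeding_reason is only "
                "meaningful when the order was not switched"
            )


def categorize(form: SwitchForm) -> SwitchCategory:
    """Map one form to exactly one appropriateness category.

    Precedence: discharge-day exclusion first, then evaluability, then the
    four-criteria × switched/continued grid.  A total, pure function.
    """
    if form.discharged_on_switch_day:
        return SwitchCategory.EXCLUDED_DISCHARGE
    if not form.returned or form.generated_on_weekend:
        return SwitchCategory.NOT_EVALUABLE
    if form.criteria.all_met():
        return (
            SwitchCategory.APPROPRIATE_SWITCH
            if form.switched
            else SwitchCategory.INAPPROPRIATE_IV_CONTINUATION
        )
    return (
        SwitchCategory.INAPPROPRIATE_SWITCH
        if form.switched
        else SwitchCategory.APPROPRIATE_IV_CONTINUATION
    )


@dataclass
class ReviewSummary:
    """Category counts plus the adherence fraction.

    ``n_eligible`` counts evaluable forms whose four criteria all held
    (appropriate switches plus inappropriate continuations); adherence is
    appropriate switches over eligible, undefined (None) when no form was
    eligible.
    """

    counts: dict[SwitchCategory, int]
    n_total: int
    n_eligible: int
    adherence_fraction: float | None
    impeding_reasons: Counter = field(default_factory=Counter)

    def count(self, category: SwitchCategory) -> int:
        return self.counts.get(category, 0)

    @property
    def n_analysed(self) -> int:
        """Forms remaining after the discharge-day exclusion."""
        return self.n_total - self.count(SwitchCategory.EXCLUDED_DISCHARGE)

    def to_dict(self) -> dict:
        return {
            "counts": {c.value: self.counts.get(c, 0) for c in SwitchCategory},
            "n_total": self.n_total,
            "n_analysed": self.n_analysed,
            "n_eligible": self.n_eligible,
            "adherence_fraction": self.adherence_fraction,
            "impeding_reasons": {
                (k.value if isinstance(k, ImpedingReason) else str(k)): v
                for k, v in sorted(self.impeding_reasons.items())
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def summarize(forms: Iterable[SwitchForm]) -> ReviewSummary:
    """Categorise every form and aggregate counts, eligibility and adherence."""
    counts: Counter = Counter()
    impeding: Counter = Counter()
    n = 0
    for form in forms:
        counts[categorize(form)] += 1
        if form.impeding_reason is not None:
            impeding[form.impeding_reason] += 1
        n += 1
    n_eligible = (
        counts[SwitchCategory.APPROPRIATE_SWITCH]
        + counts[SwitchCategory.INAPPROPRIATE_IV_CONTINUATION]
    )
    adherence = (
        counts[SwitchCategory.APPROPRIATE_SWITCH] / n_eligible
        if n_eligible > 0
        else None
    )
    return ReviewSummary(
        counts=dict(counts),
        n_total=n,
        n_eligible=n_eligible,
        adherence_fraction=adherence,
        impeding_reasons=impeding,
    )


def second_reminder_summary(forms: Iterable[SwitchForm]) -> ReviewSummary:
    """The same aggregation restricted to second-round forms."""
    return summarize(f for f in forms if f.reminder_number == 2)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

FORM_COLS = [
    "order_id", "reminder_number", "no_prolonged_iv_indication",
    "improving_vitals", "organism_ok", "functional_gi", "switched",
    "impeding_reason", "returned", "generated_on_weekend",
    "discharged_on_switch_day",
]

_TRUE = {"true", "1", "yes", "t"}


def _b(raw) -> bool:
    return str(raw).strip().lower() in _TRUE


def read_forms(path) -> list[SwitchForm]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in FORM_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    forms = []
    for row in df.itertuples(index=False):
        reason = row.impeding_reason.strip()
        forms.append(
            SwitchForm(
                order_id=row.order_id,
                reminder_number=int(row.reminder_number),
                criteria=SwitchCriteria(
                    no_prolonged_iv_indication=_b(row.no_prolonged_iv_indication),
                    improving_vitals=_b(row.improving_vitals),
                    organism_oral_susceptible_or_not_cultured=_b(row.organism_ok),
                    functional_gi_tract=_b(row.functional_gi),
                ),
                switched=_b(row.switched),
                impeding_reason=ImpedingReason(reason) if reason else None,
                returned=_b(row.returned),
                generated_on_weekend=_b(row.generated_on_weekend),
                discharged_on_switch_day=_b(row.discharged_on_switch_day),
            )
        )
    return forms


def write_forms(forms: Iterable[SwitchForm], path) -> None:
    rows = [
        {
            "order_id": f.order_id,
            "reminder_number": f.reminder_number,
            "no_prolonged_iv_indication": f.criteria.no_prolonged_iv_indication,
            "improving_vitals": f.criteria.improving_vitals,
            "organism_ok": f.criteria.organism_oral_susceptible_or_not_cultured,
            "functional_gi": f.criteria.functional_gi_tract,
            "switched": f.switched,
            "impeding_reason": "" if f.impeding_reason is None else f.impeding_reason.value,
            "returned": f.returned,
            "generated_on_weekend": f.generated_on_weekend,
            "discharged_on_switch_day": f.discharged_on_switch_day,
        }
        for f in forms
    ]
    pd.DataFrame(rows, columns=FORM_COLS).to_csv(path, index=False)
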