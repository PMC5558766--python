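"""Deterministic detailed-evaluation fixture.

A hand-constructed 4-month cohort plus the matching set of returned switch
forms, sized so that running the trigger engine and the review layer over
it reproduces a canonical prospective-evaluation flow:

    244 reminder-activated orders
     ├─ 21 excluded (patient discharged on the possible switch day)
     └─ 223 analysed
         ├─ 116 eligible for switch: 84 switched, 32 incorrectly continued
         ├─  78 not eligible (appropriately continued on iv)
         └─  29 not evaluable (no form returned)

and, within the second reminder round: 56 forms, of which 20 led to a
correct switch, 0 to an incorrect switch, 31 were not eligible and 5 were
incorrectly not switched.

The fixture hard-codes criteria booleans and switch decisions — it pins
the counting logic of the engine and the categorizer, it does not model
physician behaviour.  The split of the discharge exclusions and the
unevaluable forms across reminder rounds is under-determined by the
marginals above; this fixture assigns all of both to the first round,
which is consistent with every marginal simultaneously.

Geometry (why the engine emits exactly these counts):

* second-round orders start on a Monday at 04:00 — elapsed time at the
  07:00 run is 51 h on Wednesday (first window) and 99 h on Friday
  (second window), both weekdays;
* first-round-only orders that stay on iv start on a Tuesday at 04:00 —
  their first window falls on Thursday (51 h) but the second lands on
  Saturday (99 h, suppressed) and is already past 120 h by Monday, so the
  engine itself never issues them a second reminder;
* orders that were switched stop before their next window, with an oral
  follow-on order starting within 24 h of the iv stop.
"""

from __future__ import annotations

import itertools
from datetime import date, datetime, time, timedelta

from .records import (
    Analyte,
    Cohort,
    IntakeStatus,
    LabObservation,
    MedicationOrder,
    Route,
    WardGroup,
)
from .review import ImpedingReason, SwitchCriteria, SwitchForm
from .rules import DEFAULT_PROTOCOL_MAP

__all__ = ["build_fig2_fixture", "FIXTURE_WINDOW"]

#: 4-month evaluation window (starts on a Sunday; first order Monday Feb 2).
FIXTURE_WINDOW = (date(2015, 2, 1), date(2015, 6, 30))

# role name -> (count, reminder_round, eligible, switched, returned, discharged)
_ROLES: list[tuple[str, int]] = [
    ("r2_switch", 20),        # round 2, eligible, switched
    ("r2_not_switched", 5),   # round 2, eligible, not switched
    ("r2_not_eligible", 31),  # round 2, not eligible, continued
    ("r1_switch", 64),        # round 1, eligible, switched
    ("r1_not_switched", 27),  # round 1, eligible, not switched
    ("r1_not_eligible", 47),  # round 1, not eligible, continued
    ("r1_unevaluable", 29),   # round 1, form never returned
    ("r1_discharged", 21),    # round 1, patient left on the switch day
]

# deterministic agent rotation, weighted like the observed case mix
_AGENT_CYCLE = (
    ["cefotaxim"] * 7 + ["ciprofloxacin"] * 5 + ["amoxicillin"] * 4
    + ["metronidazole"] * 4 + ["cefazolin"] * 3 + ["penicillin"] * 1
    + ["clindamycin"] * 1
)

_IMPEDING_CYCLE = [
    ImpedingReason.CLINICAL_INSTABILITY,
    ImpedingReason.NO_ORAL_INTAKE,
    ImpedingReason.SEVERE_INFECTION,
    ImpedingReason.RESISTANT_ORGANISM_NO_ORAL_OPTION,
]


def _mondays(window: tuple[date, date]) -> list[date]:
    lo, hi = window
    d = lo
    while d.weekday() != 0:
        d += timedelta(days=1)
    out = []
    # keep at least 9 days of tail room for post-reminder activity
    while d <= hi - timedelta(days=14):
        out.append(d)
        d += timedelta(days=7)
    return out


def build_fig2_fixture() -> tuple[Cohort, list[SwitchForm]]:
    """Build the fixture cohort and its switch forms (seed-free)."""
    mondays = _mondays(FIXTURE_WINDOW)
    orders: list[MedicationOrder] = []
    labs: list[LabObservation] = []
    intake: list[IntakeStatus] = []
    forms: list[SwitchForm] = []
    agent_iter = itertools.cycle(_AGENT_CYCLE)
    impeding_iter = itertools.cycle(_IMPEDING_CYCLE)
    week_iter = itertools.cycle(range(len(mondays)))

    idx = 0
    for role, count in _ROLES:
        for _ in range(count):
            idx += 1
            monday = mondays[next(week_iter)]
            pid = f"P{idx:03d}"
            oid = f"O{idx:03d}"
            drug = next(agent_iter)
            second_round = role.startswith("r2")
            anchor = monday if second_round else monday + timedelta(days=1)
            start = datetime.combine(anchor, time(4, 0))
            reminder_day = anchor + timedelta(days=2)  # Wed (r2) / Thu (r1)

            if role in ("r1_switch",):
                stop = start + timedelta(hours=56)  # afternoon of the reminder day
                oral_start = stop
            elif role == "r2_switch":
                stop = start + timedelta(hours=105)  # Friday 13:00, after reminder 2
                oral_start = stop
            elif role == "r1_discharged":
                stop = start + timedelta(hours=54)  # reminder morning; discharged that day
                oral_start = None
            elif second_round:  # r2_not_switched / r2_not_eligible: stay on iv
                stop = start + timedelta(days=8)
                oral_start = None
            else:  # r1-only, stays on iv past its (weekend) second window
                stop = start + timedelta(days=7)
                oral_start = None

            orders.append(
                MedicationOrder(
                    order_id=oid,
                    patient_id=pid,
                    admission_id=f"{pid}-a1",
                    drug=drug,
                    route=Route.IV,
                    dose_mg_per_day=3000.0,
                    start=start,
                    stop=stop,
                    ward_group=WardGroup.INTERVENTION,
                )
            )
            if oral_start is not None:
                oral_drug = (DEFAULT_PROTOCOL_MAP.get(drug) or [drug])[0]
                orders.append(
                    MedicationOrder(
                        order_id=f"{oid}-PO",
                        patient_id=pid,
                        admission_id=f"{pid}-a1",
                        drug=oral_drug,
                        route=Route.ORAL,
                        dose_mg_per_day=1500.0,
                        start=oral_start,
                        stop=oral_start + timedelta(days=5),
                        ward_group=WardGroup.INTERVENTION,
                    )
                )
            # falling CRP and normal counts: no exclusion rule fires
            labs.append(LabObservation(pid, Analyte.CRP, 180.0, start + timedelta(hours=4)))
            labs.append(LabObservation(pid, Analyte.CRP, 110.0, start + timedelta(hours=28)))
            labs.append(LabObservation(pid, Analyte.NEUTROPHILS, 3.2, start + timedelta(hours=4)))
            labs.append(LabObservation(pid, Analyte.LEUKOCYTES, 8.4, start + timedelta(hours=4)))
            if role == "r1_discharged":
                intake.append(
                    IntakeStatus(pid, reminder_day, discharged_on=reminder_day)
                )

            eligible = role in ("r1_switch", "r1_not_switched", "r2_switch", "r2_not_switched")
            switched = role in ("r1_switch", "r2_switch")
            criteria = SwitchCriteria(
                no_prolonged_iv_indication=eligible or idx % 3 != 0,
                improving_vitals=eligible or idx % 3 == 0,
                organism_oral_susceptible_or_not_cultured=True,
                functional_gi_tract=True,
            )
            impeding = None
            if role in ("r1_not_switched", "r2_not_switched"):
                impeding = next(impeding_iter)
            elif role in ("r1_not_eligible", "r2_not_eligible"):
                impeding = (
                    ImpedingReason.CLINICAL_INSTABILITY
                    if idx % 3 == 0
                    else ImpedingReason.SEVERE_INFECTION
                )
            forms.append(
                SwitchForm(
                    order_id=oid,
                    reminder_number=2 if second_round else 1,
                    criteria=criteria,
                    switched=switched,
                    impeding_reason=impeding,
                    returned=role != "r1_unevaluable",
                    generated_on_weekend=False,
                    discharged_on_switch_day=role == "r1_discharged",
                )
            )

    cohort = Cohort(
        orders=orders, labs=labs, intake=intake, observation_window=FIXTURE_WINDOW
    )
    return cohort, forms
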