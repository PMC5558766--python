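from __future__ import annotations

import random
from datetime import date, datetime, timedelta

import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from ivswitch import (
    Analyte,
    Cohort,
    IntakeStatus,
    LabObservation,
    MedicationOrder,
    Route,
    RuleConfig,
    WardGroup,
)
from ivswitch.fixture import FIXTURE_WINDOW, build_fig2_fixture


@pytest.fixture(scope="session")
def fig2():
    """The packaged detailed-evaluation fixture (cohort, forms)."""
    return build_fig2_fixture()


@pytest.fixture(scope="session")
def fig2_window():
    return FIXTURE_WINDOW


def make_order(
    order_id="O1",
    patient_id="P1",
    drug="cefotaxim",
    route=Route.IV,
    start=datetime(2015, 3, 2, 8, 0),  # a Monday
    stop=None,
    high_dose=False,
    ward=WardGroup.INTERVENTION,
    dose=3000.0,
):
    return MedicationOrder(
        order_id=order_id,
        patient_id=patient_id,
        admission_id=f"{patient_id}-a1",
        drug=drug,
        route=route,
        dose_mg_per_day=dose,
        start=start,
        stop=stop,
        ward_group=ward,
        high_dose_flag=high_dose,
    )


def random_mini_cohort(seed: int, n_orders: int = 12) -> Cohort:
    """Small randomized cohort for rule-engine property tests.

    Covers open/closed orders, both routes, labs around the thresholds,
    intake flags, and severe agents — the full exclusion surface.
    """
    rnd = random.Random(seed)
    base = datetime(2015, 3, 2, 0, 0)  # Monday
    drugs = ["cefotaxim", "ciprofloxacin", "amoxicillin", "meropenem", "cefazolin"]
    orders, labs, intake = [], [], []
    for i in range(n_orders):
        pid = f"P{i % max(1, n_orders // 2):02d}"
        start = base + timedelta(hours=rnd.randrange(0, 24 * 20))
        dur = rnd.randrange(12, 24 * 9)
        stop = None if rnd.random() < 0.15 else start + timedelta(hours=dur)
        route = Route.IV if rnd.random() < 0.8 else Route.ORAL
        orders.append(
            make_order(
                order_id=f"O{i:03d}",
                patient_id=pid,
                drug=rnd.choice(drugs),
                route=route,
                start=start,
                stop=stop,
                high_dose=rnd.random() < 0.15,
            )
        )
        if rnd.random() < 0.7:
            for k in range(rnd.randrange(1, 4)):
                labs.append(
                    LabObservation(
                        pid, Analyte.CRP,
                        round(rnd.uniform(5, 300), 1),
                        start + timedelta(hours=4 + 24 * k),
                    )
                )
        if rnd.random() < 0.5:
            labs.append(
                LabObservation(pid, Analyte.NEUTROPHILS,
                               round(rnd.uniform(0.1, 4.0), 2),
                               start + timedelta(hours=20)))
            labs.append(
                LabObservation(pid, Analyte.LEUKOCYTES,
                               round(rnd.uniform(0.3, 12.0), 2),
                               start + timedelta(hours=20)))
        if rnd.random() < 0.3:
            intake.append(
                IntakeStatus(pid, (start + timedelta(days=rnd.randrange(0, 4))).date(),
                             parenteral_only=rnd.random() < 0.5,
                             tpn=rnd.random() < 0.3))
    # dedupe intake on (patient, day)
    seen, uniq = set(), []
    for rec in intake:
        if (rec.patient_id, rec.date) not in seen:
            seen.add((rec.patient_id, rec.date))
            uniq.append(rec)
    return Cohort(orders=orders, labs=labs, intake=uniq,
                  observation_window=(date(2015, 3, 1), date(2015, 4, 30)))
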