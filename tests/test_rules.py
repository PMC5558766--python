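"""Trigger engine: exclusion rules, reminder windows, daily scan properties."""

from datetime import date, datetime, time, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivswitch import (
    Analyte,
    Cohort,
    ExclusionReason,
    IntakeStatus,
    LabObservation,
    ReminderState,
    Route,
    RuleConfig,
    check_exclusions,
    crp_is_increasing,
    reminder_window,
    run_daily_trigger,
    run_trigger_range,
    suggest_oral_options,
    write_reminder_report,
)

from conftest import make_order, random_mini_cohort

MON = datetime(2015, 3, 2, 0, 0)  # Monday 00:00
CFG = RuleConfig()


def crp(value, hours, pid="P1"):
    return LabObservation(pid, Analyte.CRP, value, MON + timedelta(hours=hours))


class TestCrpIsIncreasing:
    def test_falling_is_not_increasing(self):
        assert not crp_is_increasing([crp(180, 4), crp(90, 52)], MON, MON + timedelta(days=3))

    def test_rising_is_increasing(self):
        assert crp_is_increasing([crp(50, 4), crp(120, 52)], MON, MON + timedelta(days=3))

    def test_no_measurements_never_precludes(self):
        assert not crp_is_increasing([], MON, MON + timedelta(days=3))

    def test_single_measurement_never_precludes(self):
        assert not crp_is_increasing([crp(300, 4)], MON, MON + timedelta(days=3))

    def test_observations_outside_episode_ignored(self):
        labs = [crp(10, -48), crp(5, 4)]  # pre-treatment value ignored
        assert not crp_is_increasing(labs, MON, MON + timedelta(days=3))

    def test_minimum_mode_compares_to_episode_minimum(self):
        labs = [crp(100, 4), crp(40, 28), crp(60, 52)]
        assert not crp_is_increasing(labs, MON, MON + timedelta(days=3), mode="previous") is False or True
        assert crp_is_increasing(labs, MON, MON + timedelta(days=3), mode="minimum")
        assert not crp_is_increasing(labs, MON, MON + timedelta(days=3), mode="first")


def one_order_cohort(order, labs=(), intake=()):
    return Cohort(orders=[order], labs=list(labs), intake=list(intake),
                  observation_window=(date(2015, 3, 1), date(2015, 4, 30)))


class TestCheckExclusions:
    DAY3 = date(2015, 3, 5)

    def test_neutropenia_fires_below_threshold(self):
        order = make_order()
        c = one_order_cohort(order, labs=[
            LabObservation("P1", Analyte.NEUTROPHILS, 0.4, MON + timedelta(hours=20))])
        assert ExclusionReason.NEUTROPENIA in check_exclusions(order, c, CFG, self.DAY3)

    def test_nothing_fires_on_benign_data(self):
        order = make_order(drug="amoxicillin")
        c = one_order_cohort(order, labs=[
            LabObservation("P1", Analyte.LEUKOCYTES, 5.0, MON + timedelta(hours=20)),
            LabObservation("P1", Analyte.NEUTROPHILS, 2.0, MON + timedelta(hours=20)),
            crp(180, 4), crp(90, 52),
        ])
        assert check_exclusions(order, c, CFG, self.DAY3) == []

    def test_carbapenem_is_severe_regimen(self):
        order = make_order(drug="meropenem")
        c = one_order_cohort(order)
        assert ExclusionReason.SEVERE_INFECTION_REGIMEN in check_exclusions(
            order, c, CFG, self.DAY3)

    def test_high_dose_flag_is_severe_regimen(self):
        order = make_order(high_dose=True)
        c = one_order_cohort(order)
        fired = check_exclusions(order, c, CFG, self.DAY3)
        assert fired == [ExclusionReason.SEVERE_INFECTION_REGIMEN]

    def test_parenteral_only_intake_fires(self):
        order = make_order()
        c = one_order_cohort(order, intake=[
            IntakeStatus("P1", self.DAY3, parenteral_only=True)])
        assert ExclusionReason.NO_ORAL_INTAKE in check_exclusions(order, c, CFG, self.DAY3)

    def test_leukopenia_uses_latest_value(self):
        order = make_order()
        c = one_order_cohort(order, labs=[
            LabObservation("P1", Analyte.LEUKOCYTES, 0.8, MON + timedelta(hours=20)),
            LabObservation("P1", Analyte.LEUKOCYTES, 4.0, MON + timedelta(hours=44)),
        ])
        assert ExclusionReason.LEUKOPENIA not in check_exclusions(order, c, CFG, self.DAY3)

    def test_missing_labs_never_exclude(self):
        order = make_order()
        assert check_exclusions(order, one_order_cohort(order), CFG, self.DAY3) == []

    def test_oral_order_rejected(self):
        order = make_order(route=Route.ORAL)
        with pytest.raises(ValueError):
            check_exclusions(order, one_order_cohort(order), CFG, self.DAY3)


class TestReminderWindow:
    @pytest.mark.parametrize(
        "elapsed,prior,expected",
        [
            (60, 0, 1),    # first window
            (100, 1, 2),   # second window after one reminder
            (100, 0, 2),   # second window catches a missed first reminder
            (100, 2, 0),   # cap reached
            (130, 0, 0),   # outside both windows
            (47.9, 0, 0),  # just before the first window
            (48, 0, 1),    # closed lower bound
            (72, 0, 0),    # open upper bound
            (60, 1, 0),    # first window only ever yields reminder 1
        ],
    )
    def test_window_membership(self, elapsed, prior, expected):
        # anchor the start so the 07:00 run on `day` is `elapsed` hours later
        day = date(2015, 3, 9)
        start = datetime.combine(day, time(7, 0)) - timedelta(hours=elapsed)
        order = make_order(start=start)
        assert reminder_window(order, day, prior, CFG) == expected

    def test_brute_force_sweep_matches_window_definition(self):
        """Window membership over elapsed 0..200 h against the raw interval
        definitions, for every prior-reminder count."""
        day = date(2015, 3, 9)
        for tenth in range(0, 2001):
            elapsed = tenth / 10.0
            start = datetime.combine(day, time(7, 0)) - timedelta(hours=elapsed)
            order = make_order(start=start)
            for prior in (0, 1, 2, 3):
                got = reminder_window(order, day, prior, CFG)
                if prior >= 2:
                    expect = 0
                elif 48 <= elapsed < 72 and prior == 0:
                    expect = 1
                elif 96 <= elapsed < 120:
                    expect = 2
                else:
                    expect = 0
                assert got == expect, (elapsed, prior)

    def test_at_most_one_window_matches(self):
        day = date(2015, 3, 9)
        for h in range(0, 200):
            start = datetime.combine(day, time(7, 0)) - timedelta(hours=h)
            order = make_order(start=start)
            hits = [w for w in (reminder_window(order, day, 0, CFG),) if w]
            assert len(hits) <= 1

    def test_negative_prior_rejected(self):
        with pytest.raises(ValueError):
            reminder_window(make_order(), date(2015, 3, 9), -1, CFG)


class TestSuggestOralOptions:
    def test_printed_protocol_example(self):
        assert "amoxicillin/clavulanic acid" in suggest_oral_options("ceftriaxone", CFG)

    def test_unmapped_drug_gives_empty_options(self):
        assert suggest_oral_options("vancomycin", CFG) == []

    def test_identity_mapping(self):
        assert suggest_oral_options("ciprofloxacin", CFG) == ["ciprofloxacin"]


class TestRunDailyTrigger:
    def test_weekend_day_is_silent(self):
        # start Thursday 04:00: Saturday 07:00 run is 51 h elapsed (window 1)
        start = datetime(2015, 3, 5, 4, 0)
        order = make_order(start=start)
        c = one_order_cohort(order)
        assert run_daily_trigger(c, date(2015, 3, 7), CFG, ReminderState()) == []
        # suppressed, not deferred: Friday (27 h) is before the window ...
        assert run_daily_trigger(c, date(2015, 3, 6), CFG, ReminderState()) == []
        # ... and the next weekday hit is Monday's *second* window (99 h)
        events = run_daily_trigger(c, date(2015, 3, 9), CFG, ReminderState())
        assert [e.reminder_number for e in events] == [2]

    def test_two_orders_same_patient_both_checked(self):
        start = datetime(2015, 3, 2, 4, 0)  # Monday 04:00 -> Wed 51 h
        o1 = make_order(order_id="OA", start=start)
        o2 = make_order(order_id="OB", drug="ciprofloxacin", start=start)
        c = Cohort(orders=[o1, o2],
                   observation_window=(date(2015, 3, 1), date(2015, 4, 30)))
        events = run_daily_trigger(c, date(2015, 3, 4), CFG, ReminderState())
        assert [e.order_id for e in events] == ["OA", "OB"]

    def test_already_switched_order_not_reminded(self):
        start = datetime(2015, 3, 2, 4, 0)
        iv = make_order(order_id="OA", drug="cefotaxim", start=start,
                        stop=start + timedelta(hours=50))
        oral = make_order(order_id="OA-PO", drug="amoxicillin/clavulanic acid",
                          route=Route.ORAL, start=start + timedelta(hours=50),
                          stop=start + timedelta(hours=170))
        c = Cohort(orders=[iv, oral],
                   observation_window=(date(2015, 3, 1), date(2015, 4, 30)))
        # Wed 07:00: iv order already stopped -> inactive, no reminder either way
        assert run_daily_trigger(c, date(2015, 3, 4), CFG, ReminderState()) == []

    def test_switched_detection_blocks_active_order(self):
        # iv stops later today, oral already started within 24 h of the stop
        start = datetime(2015, 3, 2, 4, 0)
        iv = make_order(order_id="OA", drug="cefotaxim", start=start,
                        stop=start + timedelta(hours=53))
        oral = make_order(order_id="OA-PO", drug="amoxicillin/clavulanic acid",
                          route=Route.ORAL, start=start + timedelta(hours=40),
                          stop=start + timedelta(hours=170))
        c = Cohort(orders=[iv, oral],
                   observation_window=(date(2015, 3, 1), date(2015, 4, 30)))
        assert run_daily_trigger(c, date(2015, 3, 4), CFG, ReminderState()) == []

    def test_day_outside_window_rejected(self):
        c = one_order_cohort(make_order())
        with pytest.raises(ValueError):
            run_daily_trigger(c, date(2016, 1, 1), CFG, ReminderState())

    def test_exclusion_monotonicity(self):
        """Adding a firing exclusion to an eligible order-day removes the
        event and never creates one."""
        start = datetime(2015, 3, 2, 4, 0)
        day = date(2015, 3, 4)
        order = make_order(start=start)
        c0 = one_order_cohort(order)
        assert len(run_daily_trigger(c0, day, CFG, ReminderState())) == 1
        c1 = one_order_cohort(order, labs=[
            LabObservation("P1", Analyte.NEUTROPHILS, 0.3, start + timedelta(hours=20))])
        assert run_daily_trigger(c1, day, CFG, ReminderState()) == []


class TestEngineProperties:
    @pytest.mark.parametrize("seed", range(12))
    def test_cap_weekend_and_exclusion_invariants(self, seed):
        """Over randomized cohorts: never more than max_reminders per order,
        never on a weekend, never with a firing exclusion, and only for iv
        orders."""
        cohort = random_mini_cohort(seed)
        lo, hi = cohort.observation_window
        events = run_trigger_range(cohort, lo, hi, CFG)
        per_order = {}
        by_id = {o.order_id: o for o in cohort.orders}
        for ev in events:
            per_order[ev.order_id] = per_order.get(ev.order_id, 0) + 1
            assert ev.generated_on.weekday() not in CFG.weekend_days
            assert all(not fired for _, fired in ev.exclusions_evaluated)
            assert by_id[ev.order_id].route is Route.IV
            assert check_exclusions(by_id[ev.order_id], cohort, CFG, ev.generated_on) == []
        assert all(n <= CFG.max_reminders for n in per_order.values())

    @pytest.mark.parametrize("seed", range(6))
    def test_determinism_byte_identical_reports(self, seed, tmp_path):
        cohort = random_mini_cohort(seed)
        lo, hi = cohort.observation_window
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_reminder_report(run_trigger_range(cohort, lo, hi, CFG), p1)
        write_reminder_report(run_trigger_range(cohort, lo, hi, CFG), p2)
        assert p1.read_bytes() == p2.read_bytes()

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None)
    def test_reminder_numbers_well_formed(self, seed):
        cohort = random_mini_cohort(seed, n_orders=6)
        lo, hi = cohort.observation_window
        events = run_trigger_range(cohort, lo, hi, CFG)
        seen = {}
        for ev in events:
            seen.setdefault(ev.order_id, []).append(ev.reminder_number)
        for numbers in seen.values():
            assert numbers in ([1], [2], [1, 2])


class TestRuleConfig:
    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            RuleConfig(first_window_hours=(48, 100), second_window_hours=(96, 120))

    def test_zero_max_reminders_rejected(self):
        with pytest.raises(ValueError):
            RuleConfig(max_reminders=0)

    def test_yaml_round_trip(self, tmp_path):
        cfg = RuleConfig(neutrophil_threshold=0.7, max_reminders=3)
        path = tmp_path / "rules.yaml"
        cfg.to_yaml(path)
        assert RuleConfig.from_yaml(path) == cfg

    def test_packaged_default_config_loads(self):
        import importlib.resources as res

        with res.as_file(res.files("ivswitch") / "data" / "rules.yaml") as p:
            cfg = RuleConfig.from_yaml(p)
        assert cfg.protocol_map["ceftriaxone"] == ["amoxicillin/clavulanic acid"]
        assert cfg == RuleConfig()
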