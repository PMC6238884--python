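"""Event segmentation, detectors, and the per-event cause rules."""
from datetime import datetime, time, timedelta

import pytest

from conftest import activity, bg, bolus, carb, ctx_of, reg
from diakb import PatientProfile
from diakb import events as ev
from diakb.model import DataType, State


class TestClassifyReading:
    def test_fasting_after_carb_free_night(self, config):
        regs = [carb(0, 22, 0, 30.0), bg(1, 7, 0, 6.0)]
        ctx = ctx_of(regs)
        assert ev.classify_reading(ctx.registrations[-1], ctx, config) == "fasting"

    def test_before_meal_within_window(self, config):
        regs = [carb(0, 8, 0, 30.0), bg(0, 11, 45, 6.0), carb(0, 12, 0, 60.0)]
        ctx = ctx_of(regs)
        reading = [r for r in ctx.registrations if r.data_type == DataType.BLOOD_GLUCOSE][0]
        assert ev.classify_reading(reading, ctx, config) == "before_meal"

    def test_other_when_recently_fed(self, config):
        regs = [carb(0, 13, 30, 40.0), bg(0, 15, 0, 6.0)]
        ctx = ctx_of(regs)
        reading = [r for r in ctx.registrations if r.data_type == DataType.BLOOD_GLUCOSE][0]
        assert ev.classify_reading(reading, ctx, config) == "other"


class TestGlycemicSegmentation:
    def test_single_high_reading_is_event(self, config):
        ctx = ctx_of([carb(0, 12, 0, 40.0), bg(0, 15, 0, 14.0)])
        events = ev.segment_glycemic_events(ctx, config)
        assert [e.kind for e in events] == ["hyperglycemia"]

    def test_threshold_boundary_is_strict(self, config):
        ctx = ctx_of([carb(0, 12, 0, 40.0), bg(0, 15, 0, 13.9)])
        assert ev.segment_glycemic_events(ctx, config) == []

    def test_fasting_reading_uses_lower_threshold(self, config):
        ctx = ctx_of([bg(0, 7, 0, 9.5)])  # no carbs anywhere: fasting, bound 9.0
        assert [e.kind for e in ev.segment_glycemic_events(ctx, config)] == \
            ["hyperglycemia"]

    def test_run_reference_is_extreme_reading(self, config):
        regs = [carb(0, 10, 0, 40.0),
                bg(0, 13, 0, 14.2), bg(0, 14, 0, 15.1), bg(0, 15, 30, 14.0)]
        ctx = ctx_of(regs)
        events = ev.segment_glycemic_events(ctx, config)
        assert len(events) == 1
        assert events[0].reference_time.hour == 14
        assert events[0].extreme_value == 15.1

    def test_in_range_reading_splits_runs(self, config):
        regs = [carb(0, 9, 0, 40.0), bg(0, 12, 0, 14.5), bg(0, 13, 0, 7.0),
                bg(0, 14, 0, 14.8)]
        ctx = ctx_of(regs)
        assert len(ev.segment_glycemic_events(ctx, config)) == 2

    def test_long_run_split_at_max_duration(self, config):
        regs = [carb(0, 7, 0, 40.0)]
        regs += [bg(0, 9 + 2 * i, 0, 14.5 + 0.1 * i) for i in range(5)]  # 9:00..17:00
        ctx = ctx_of(regs)
        events = ev.segment_glycemic_events(ctx, config)
        assert len(events) == 2
        for e in events:
            assert e.end - e.start <= timedelta(hours=config.event_max_duration_hours)

    def test_partition_property(self, config):
        """Every out-of-range reading lies in exactly one event; events hold
        no in-range readings."""
        regs = [carb(0, 8, 0, 40.0)]
        values = [6.0, 14.5, 15.0, 6.2, 3.0, 3.1, 6.0, 14.2]
        regs += [bg(0, 9 + i, 0, v) for i, v in enumerate(values)]
        ctx = ctx_of(regs)
        events = ev.segment_glycemic_events(ctx, config)
        out_of_range = [r for r in ctx.registrations
                        if r.data_type == DataType.BLOOD_GLUCOSE
                        and ev._glycemic_state(r, ctx, config) != "in_range"]
        membership = [sum(r in e.registrations for e in events) for r in out_of_range]
        assert membership == [1] * len(out_of_range)
        for e in events:
            assert all(ev._glycemic_state(r, ctx, config) != "in_range"
                       for r in e.registrations)


class TestBloodPressure:
    @pytest.mark.parametrize("sys_v, dia_v, expect", [
        (141, 80, True),   # systolic alone
        (140, 90, False),  # both exactly on the bound
        (135, 91, True),   # diastolic alone (OR semantics)
        (135, 85, False),
        (141, 91, True),
    ])
    def test_or_semantics_truth_table(self, config, sys_v, dia_v, expect):
        regs = [reg(0, 10, 0, DataType.BLOOD_PRESSURE_SYSTOLIC, float(sys_v)),
                reg(0, 10, 0, DataType.BLOOD_PRESSURE_DIASTOLIC, float(dia_v))]
        events = ev.detect_bp_events(ctx_of(regs), config)
        assert bool(events) is expect


class TestShortSleep:
    def _night(self, bed, wake_h, wake_m):
        regs = [bg(0, 8, 0, 6.0), bg(0, bed[0], bed[1], 6.0),
                bg(1, wake_h, wake_m, 6.0), bg(1, 12, 0, 6.0)]
        return ctx_of(regs)

    def test_short_night_detected(self, config):
        events, results = ev.detect_short_sleep(self._night((23, 30), 6, 0), config)
        assert len(events) == 1
        assert events[0].extreme_value == pytest.approx(6.5)

    def test_long_night_passes(self, config):
        events, results = ev.detect_short_sleep(self._night((22, 0), 6, 30), config)
        assert events == []
        assert [r.state for r in results] == [State.FALSE]

    def test_automatic_registrations_ignored(self, config):
        regs = [bg(0, 21, 0, 6.0), bg(1, 6, 0, 6.0)]  # manual gap 9 h
        regs += [bg(0, 23, h, 6.0, manual=False, source=f"cgm{h}") for h in range(0, 50, 10)]
        regs += [bg(1, 3, 30, 6.0, manual=False, source="cgm-x")]
        events, _ = ev.detect_short_sleep(ctx_of(regs), config)
        assert events == []

    def test_unbracketed_night_is_na(self, config):
        regs = [bg(0, 8, 0, 6.0), bg(0, 12, 0, 6.0), bg(1, 1, 0, 6.0)]  # nothing after 03:00
        events, results = ev.detect_short_sleep(ctx_of(regs), config)
        assert events == []
        assert [r.state for r in results] == [State.NA]


def _hyper_event(ctx, config):
    events = [e for e in ev.segment_glycemic_events(ctx, config)
              if e.kind == "hyperglycemia"]
    assert len(events) == 1
    return events[0]


def _hypo_event(ctx, config):
    events = [e for e in ev.segment_glycemic_events(ctx, config)
              if e.kind == "hypoglycemia"]
    assert len(events) == 1
    return events[0]


class TestHyperCauses:
    def test_last_dose_insufficient_arithmetic(self, config):
        """1 U against (14.0 - 5.5) / 2.5 = 3.4 U required."""
        profile = PatientProfile(reported_isf=2.5)
        ctx = ctx_of([carb(0, 11, 0, 40.0), bolus(0, 12, 0, 1.0), bg(0, 14, 0, 14.0)],
                     profile=profile)
        event = _hyper_event(ctx, config)
        r = ev.rule_hyper_last_dose_insufficient(event, ctx, config)
        assert r.state == State.TRUE
        assert r.numeric_evidence["required_dose"] == pytest.approx(3.4)

    def test_big_meal_flagged(self, config):
        ctx = ctx_of([carb(0, 12, 0, 80.0), bg(0, 14, 0, 15.0)])
        event = _hyper_event(ctx, config)
        r = ev.rule_hyper_intake_above_recommendation(event, ctx, config)
        assert r.state == State.TRUE

    def test_low_carb_diet_skips_recommendation(self, config):
        profile = PatientProfile(low_carb_diet=True)
        ctx = ctx_of([carb(0, 12, 0, 80.0), bg(0, 14, 0, 15.0)], profile=profile)
        event = _hyper_event(ctx, config)
        assert ev.rule_hyper_intake_above_recommendation(event, ctx, config).state \
            == State.NA

    def test_uncovered_meal_detected(self, config):
        ctx = ctx_of([carb(0, 12, 0, 60.0), bg(0, 14, 0, 15.0)])
        event = _hyper_event(ctx, config)
        assert ev.rule_hyper_no_insulin_for_meal(event, ctx, config).state == State.NA
        ctx2 = ctx_of([carb(0, 12, 0, 60.0), bolus(0, 9, 0, 2.0), bg(0, 14, 0, 15.0)])
        event2 = _hyper_event(ctx2, config)
        assert ev.rule_hyper_no_insulin_for_meal(event2, ctx2, config).state == State.TRUE
        ctx3 = ctx_of([carb(0, 12, 0, 60.0), bolus(0, 12, 10, 6.0), bg(0, 14, 0, 15.0)])
        event3 = _hyper_event(ctx3, config)
        assert ev.rule_hyper_no_insulin_for_meal(event3, ctx3, config).state == State.FALSE


class TestHypoCauses:
    def test_moderate_walk_before_event(self, config):
        ctx = ctx_of([activity(0, 13, 0, "minutes", 45.0), carb(0, 11, 0, 40.0),
                      bg(0, 15, 0, 3.0)])
        event = _hypo_event(ctx, config)
        assert ev.rule_hypo_light_moderate_activity(event, ctx, config).state == State.TRUE

    def test_step_bound_is_strict(self, config):
        for steps, expect in [(2999, State.TRUE), (3000, State.FALSE), (3500, State.FALSE)]:
            ctx = ctx_of([activity(0, 13, 0, "steps", float(steps)),
                          carb(0, 11, 0, 40.0), bg(0, 15, 0, 3.0)])
            event = _hypo_event(ctx, config)
            assert ev.rule_hypo_light_moderate_activity(event, ctx, config).state == expect

    def test_heavy_steps_count_as_extreme_in_24h(self, config):
        ctx = ctx_of([activity(0, 13, 0, "steps", 3500.0), carb(0, 11, 0, 40.0),
                      bg(0, 15, 0, 3.0)])
        event = _hypo_event(ctx, config)
        assert ev.rule_hypo_extreme_activity(event, ctx, config).state == State.TRUE

    def test_no_carbs_for_hours_flagged(self, config):
        ctx = ctx_of([carb(0, 9, 0, 40.0), bg(0, 15, 0, 3.0)])
        event = _hypo_event(ctx, config)
        r = ev.rule_hypo_no_carb_intake(event, ctx, config)
        assert r.state == State.TRUE

    def test_small_meal_flagged(self, config):
        ctx = ctx_of([carb(0, 12, 0, 20.0), bg(0, 14, 0, 3.0)])
        event = _hypo_event(ctx, config)
        assert ev.rule_hypo_intake_below_recommendation(event, ctx, config).state \
            == State.TRUE


class TestThresholdSweeps:
    """Sweeping each driving value across its bound flips detection exactly once."""

    def test_hyper_flip_point(self, config):
        flips = []
        prev = None
        for i in range(0, 71):
            v = round(9.0 + 0.1 * i, 1)
            ctx = ctx_of([carb(0, 12, 0, 40.0), bg(0, 15, 0, v)])
            detected = bool(ev.segment_glycemic_events(ctx, config))
            if prev is not None and detected != prev:
                flips.append(v)
            prev = detected
        assert flips == [14.0]

    def test_sleep_flip_point(self, config):
        flips, prev = [], None
        for half_hours in range(8, 21):
            gap = half_hours / 2.0
            wake = datetime(2024, 3, 5, 23, 0) - timedelta(days=1) + timedelta(hours=gap)
            from diakb.model import Registration
            regs = [bg(0, 23, 0, 6.0),
                    Registration(timestamp=wake, data_type=DataType.BLOOD_GLUCOSE,
                                 value=6.0, source="glucometer"),
                    Registration(timestamp=wake + timedelta(hours=4),
                                 data_type=DataType.BLOOD_GLUCOSE, value=6.0,
                                 source="glucometer")]
            events, _ = ev.detect_short_sleep(ctx_of(regs), config)
            detected = bool(events)
            if prev is not None and detected != prev:
                flips.append(gap)
            prev = detected
        assert flips == [7.0]
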