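"""Formula layer checked against independent hand-arithmetic oracles."""
from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bg, bolus, carb, ctx_of
from diakb import calculators as calc
from diakb.model import DataType

T0 = datetime(2024, 3, 4, 12, 0)


class TestHbA1c:
    # Oracle: invert eAG[mg/dL] = 28.7*A1C - 46.7 by hand for chosen means.
    @pytest.mark.parametrize("mean_bg, expected", [
        (154.2 / 18.016, 7.0000),   # eAG 154.2 mg/dL
        (100.4 / 18.016, 5.1254),   # eAG 100.4 mg/dL
        (10.0, (180.16 + 46.7) / 28.7),  # mean 10 mmol/L worked by hand
    ])
    def test_matches_hand_inverted_relation(self, mean_bg, expected):
        assert calc.estimate_hba1c([mean_bg]) == pytest.approx(expected, abs=5e-4)

    def test_empty_series_signals_na(self):
        assert calc.estimate_hba1c([]) is None

    @given(st.lists(st.floats(2.0, 25.0), min_size=1, max_size=20),
           st.floats(0.01, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_mean(self, series, shift):
        lower = calc.estimate_hba1c(series)
        higher = calc.estimate_hba1c([v + shift for v in series])
        assert higher > lower

    @given(st.floats(4.0, 14.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_with_forward_relation(self, a1c):
        mean = calc.eag_from_hba1c(a1c)
        assert calc.estimate_hba1c([mean]) == pytest.approx(a1c, abs=1e-9)


class TestDoseRules:
    def test_isf_1800_rule(self):
        # 1800/40 = 45 mg/dL/U -> 45/18.016 mmol/L/U
        assert calc.isf_rule(40, rapid_acting=True) == pytest.approx(45 / 18.016)

    def test_isf_1500_rule(self):
        assert calc.isf_rule(50, rapid_acting=False) == pytest.approx(30 / 18.016)

    def test_icr_rules(self):
        assert calc.icr_rule(50, rapid_acting=True) == pytest.approx(10.0)
        assert calc.icr_rule(45, rapid_acting=False) == pytest.approx(10.0)

    def test_non_positive_tdd_signals_na(self):
        assert calc.isf_rule(0) is None
        assert calc.icr_rule(-3) is None

    @given(st.floats(5.0, 150.0), st.booleans())
    @settings(max_examples=50, deadline=None)
    def test_homogeneous_degree_minus_one(self, tdd, rapid):
        assert calc.isf_rule(2 * tdd, rapid) == pytest.approx(calc.isf_rule(tdd, rapid) / 2)
        assert calc.icr_rule(2 * tdd, rapid) == pytest.approx(calc.icr_rule(tdd, rapid) / 2)


class TestIobCob:
    def test_no_boluses(self):
        assert calc.iob_at(T0, [], dia=4.0) == 0.0

    def test_linear_midpoint(self):
        boluses = [(T0 - timedelta(hours=2), 4.0)]
        assert calc.iob_at(T0, boluses, dia=4.0) == pytest.approx(2.0)

    def test_expired_bolus(self):
        assert calc.iob_at(T0, [(T0 - timedelta(hours=5), 4.0)], dia=4.0) == 0.0

    @pytest.mark.parametrize("curve", ["linear", "bilinear"])
    def test_decay_contract(self, curve):
        """1 at injection, 0 at DIA, non-increasing, additive over doses."""
        dose_time = T0
        prev = None
        for minutes in range(0, 4 * 60 + 30, 5):
            v = calc.iob_at(dose_time + timedelta(minutes=minutes),
                            [(dose_time, 1.0)], dia=4.0, curve=curve)
            assert 0.0 <= v <= 1.0
            if prev is not None:
                assert v <= prev + 1e-12
            prev = v
        assert calc.iob_at(dose_time, [(dose_time, 1.0)], dia=4.0, curve=curve) == 1.0
        assert calc.iob_at(dose_time + timedelta(hours=4), [(dose_time, 1.0)],
                           dia=4.0, curve=curve) == 0.0
        both = calc.iob_at(T0, [(T0 - timedelta(hours=1), 2.0),
                                (T0 - timedelta(hours=2), 3.0)], dia=4.0, curve=curve)
        single = (calc.iob_at(T0, [(T0 - timedelta(hours=1), 2.0)], dia=4.0, curve=curve)
                  + calc.iob_at(T0, [(T0 - timedelta(hours=2), 3.0)], dia=4.0, curve=curve))
        assert both == pytest.approx(single)

    def test_cob_linear_absorption(self):
        assert calc.cob_at(T0, [(T0 - timedelta(hours=1), 60.0)], 30.0) == pytest.approx(30.0)
        assert calc.cob_at(T0, [(T0 - timedelta(hours=2), 20.0)], 30.0) == 0.0
        assert calc.cob_at(T0, [(T0 - timedelta(hours=1), 60.0)], None) is None


class TestAverages:
    def test_single_bolus_linear_ramp_average(self):
        # 4 U at period start, DIA 4 h over a 4 h period: mean of 4 -> 0 is 2 U
        regs = [bolus(0, 12, 0, 4.0), bg(0, 12, 0, 6.0), bg(0, 16, 0, 6.0)]
        ctx = ctx_of(regs)
        assert calc.average_iob(ctx, grid_minutes=5) == pytest.approx(2.0, rel=1e-6)

    def test_no_insulin_average_zero(self):
        ctx = ctx_of([bg(0, 8, 0, 6.0), bg(0, 12, 0, 6.0)])
        assert calc.average_iob(ctx) == 0.0

    def test_grid_refinement_converges(self):
        regs = [bolus(0, 12, 0, 4.0), bolus(0, 14, 30, 2.0), bg(0, 12, 0, 6.0),
                bg(0, 20, 0, 6.0)]
        ctx = ctx_of(regs)
        coarse = calc.average_iob(ctx, grid_minutes=5)
        fine = calc.average_iob(ctx, grid_minutes=1)
        assert abs(coarse - fine) / fine < 0.01


class TestDailyTotals:
    def test_sums_and_zero_days(self):
        regs = [bolus(0, 8, 0, 4.0), bolus(0, 12, 0, 4.0), bolus(0, 18, 0, 4.0),
                bg(0, 8, 0, 6.0), bg(2, 8, 0, 6.0), carb(0, 12, 0, 50.0)]
        regs.append(bolus(0, 22, 0, 0.0))
        from diakb.model import DataType as DT, Registration
        regs.append(Registration(timestamp=regs[0].timestamp.replace(hour=22),
                                 data_type=DT.INSULIN_BASAL, value=20.0, source="t"))
        totals = calc.daily_totals(ctx_of(regs))
        assert len(totals) == 3  # includes the empty middle day
        day0, day1, day2 = totals
        assert day0.total_rapid_insulin == pytest.approx(12.0)
        assert day0.total_basal_insulin == pytest.approx(20.0)
        assert day0.total_carbs == pytest.approx(50.0)
        assert day1.registration_counts == {}
        assert day2.registration_counts == {DT.BLOOD_GLUCOSE: 1}

    def test_counts_match_brute_force_recount(self):
        regs = [bg(d, 7 + 2 * i, 0, 6.0) for d in range(3) for i in range(4)]
        regs += [carb(1, 12, 0, 40.0), bolus(2, 12, 0, 5.0)]
        ctx = ctx_of(regs)
        totals = {t.date: t for t in calc.daily_totals(ctx)}
        for r in regs:
            day = totals[r.timestamp.date()]
            expected = sum(1 for s in regs if s.timestamp.date() == r.timestamp.date()
                           and s.data_type == r.data_type)
            assert day.registration_counts[r.data_type] == expected
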