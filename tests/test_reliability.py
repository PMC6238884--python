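"""Data-reliability family and trust grading."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import activity, bg, bolus, carb, ctx_of, reg
from diakb import LabContext, PatientProfile, ThresholdConfig
from diakb import calculators as calc
from diakb import reliability as rel
from diakb.model import DataType, HypothesisResult, State


def states(results):
    return {r.hypothesis_id: r.state for r in results}


class TestMissingTypes:
    def test_presence_per_type(self):
        ctx = ctx_of([bg(0, 8, 0, 6.0), bolus(0, 8, 0, 4.0)])
        got = states(rel.check_missing_types(ctx))
        assert got["no_blood_glucose_registered"] == State.FALSE
        assert got["no_insulin_registered"] == State.FALSE
        assert got["no_carbohydrates_registered"] == State.TRUE
        assert got["no_physical_activity_registered"] == State.TRUE

    def test_all_present(self):
        ctx = ctx_of([bg(0, 8, 0, 6.0), bolus(0, 8, 0, 4.0), carb(0, 12, 0, 40.0),
                      activity(0, 16, 0, "minutes", 30.0)])
        assert set(states(rel.check_missing_types(ctx)).values()) == {State.FALSE}

    def test_insulin_na_for_non_insulin_user(self):
        # brute-force the activation predicate table: the insulin check only
        # applies when the profile says insulin is used
        for uses, has, expected in [
            (False, False, State.NA), (False, True, State.NA),
            (True, False, State.TRUE), (True, True, State.FALSE),
        ]:
            regs = [bg(0, 8, 0, 6.0)] + ([bolus(0, 8, 0, 4.0)] if has else [])
            ctx = ctx_of(regs, profile=PatientProfile(uses_insulin=uses))
            assert states(rel.check_missing_types(ctx))["no_insulin_registered"] == expected


class TestErrorValues:
    def test_low_bg_flagged(self, config):
        ctx = ctx_of([bg(0, 8, 0, 1.0), bg(0, 12, 0, 6.0)])
        r = [x for x in rel.check_error_values(ctx, config)
             if x.hypothesis_id == "error_values_blood_glucose"][0]
        assert r.state == State.TRUE
        assert "1" in r.justification

    def test_boundary_value_is_plausible(self, config):
        """1.1 mmol/L sits on the plausible bound; 33.3 likewise."""
        ctx = ctx_of([bg(0, 8, 0, 1.1), bg(0, 12, 0, 33.3)])
        r = states(rel.check_error_values(ctx, config))
        assert r["error_values_blood_glucose"] == State.FALSE

    def test_in_range_series(self, config):
        ctx = ctx_of([bg(0, 8, 0, 4.0), bg(0, 12, 0, 10.0)])
        assert states(rel.check_error_values(ctx, config))[
            "error_values_blood_glucose"] == State.FALSE

    def test_huge_carbs_flagged(self, config):
        ctx = ctx_of([carb(0, 12, 0, 500.0), bg(0, 8, 0, 6.0)])
        got = states(rel.check_error_values(ctx, config))
        assert got["error_values_carbohydrates"] == State.TRUE
        assert got["error_values_insulin"] == State.NA  # nothing to judge


class TestRegistrationCounts:
    def test_five_per_day_passes(self, config):
        regs = [bg(d, 7 + 3 * i, 0, 6.0) for d in range(7) for i in range(5)]
        assert rel.check_registration_counts(ctx_of(regs), config).state == State.FALSE

    def test_one_short_day_flagged(self, config):
        regs = [bg(d, 7 + 3 * i, 0, 6.0) for d in range(7) for i in range(5)]
        regs = [r for r in regs if not (r.timestamp.day == 6 and r.timestamp.hour == 19)]
        r = rel.check_registration_counts(ctx_of(regs), config)
        assert r.state == State.TRUE
        assert "2024-03-06" in r.justification

    def test_empty_diary_na(self, config):
        from diakb import build_context
        ctx = build_context([], PatientProfile(), allow_empty=True)
        assert rel.check_registration_counts(ctx, config).state == State.NA


class TestDistribution:
    def test_uniform_counts_pass(self, config):
        regs = [bg(d, 7 + i, 0, 6.0) for d in range(7) for i in range(14)]
        assert rel.check_day_distribution(ctx_of(regs), config).state == State.FALSE

    def test_narrative_deviation_flagged(self, config):
        """Counts with std near 6 against mean 14 exceed the allowed near 3."""
        pattern = [14, 14, 26, 14, 2, 14, 14]  # mean 14, std 6.2
        regs = [bg(d, 0, 5 * i % 60, 6.0, source=f"s{i}")
                for d, n in enumerate(pattern) for i in range(n)]
        r = rel.check_day_distribution(ctx_of(regs), config)
        assert r.state == State.TRUE
        assert r.numeric_evidence["allowed_dispersion"] == pytest.approx(0.2 * 14)
        assert r.numeric_evidence["observed_dispersion"] == pytest.approx(
            float(np.std(pattern)))

    def test_scale_equivariance(self, config):
        """Doubling every count leaves the relative dispersion unchanged."""
        base = [10, 12, 10, 8, 10, 11, 9]
        for scale in (1, 2):
            regs = [bg(d, 0, (7 * i) % 60, 6.0, source=f"s{i}")
                    for d, n in enumerate(base) for i in range(scale * n)]
            assert rel.check_day_distribution(ctx_of(regs), config).state == State.FALSE

    def test_weekday_needs_two_weekdays(self, config):
        regs = [bg(0, 8, 0, 6.0), bg(0, 12, 0, 6.0)]
        assert rel.check_weekday_distribution(ctx_of(regs), config).state == State.NA


class TestSourceInconsistencies:
    def test_hba1c_mismatch(self, config):
        ctx = ctx_of([bg(0, 8, 0, 6.0)] * 1 + [bg(0, 12, 0, 6.0)],
                     lab=LabContext(hba1c=8.0))
        r = states(rel.check_source_inconsistencies(ctx, config))
        assert r["source_inconsistency_hba1c"] == State.TRUE

    def test_within_tolerance_passes(self, config):
        """A reported ISF within 4.9% of the calculated one is consistent."""
        regs = [bolus(d, 8, 0, 10.0) for d in range(3)] + \
               [reg(d, 22, 0, DataType.INSULIN_BASAL, 20.0) for d in range(3)]
        calculated = calc.calculated_isf(ctx_of(regs))
        profile = PatientProfile(reported_isf=calculated / 1.049)
        ctx = ctx_of(regs, profile=profile)
        r = states(rel.check_source_inconsistencies(ctx, config))
        assert r["source_inconsistency_isf"] == State.FALSE
        profile_bad = PatientProfile(reported_isf=calculated / 1.06)
        ctx = ctx_of(regs, profile=profile_bad)
        assert states(rel.check_source_inconsistencies(ctx, config))[
            "source_inconsistency_isf"] == State.TRUE

    def test_missing_sides_na(self, config):
        ctx = ctx_of([bg(0, 8, 0, 6.0)])
        r = states(rel.check_source_inconsistencies(ctx, config))
        assert r["source_inconsistency_hba1c"] == State.NA
        assert r["source_inconsistency_isf"] == State.NA
        assert r["source_inconsistency_icr"] == State.NA


def _true(hyp):
    return HypothesisResult(hypothesis_id=hyp, state=State.TRUE, justification="x")


class TestGrade:
    def test_clean_run_scores_full_trust(self, config):
        assert rel.grade([], config).trust_level == 50

    def test_hba1c_mismatch_costs_ten(self, config):
        report = rel.grade([_true("source_inconsistency_hba1c")], config)
        assert report.trust_level == 40
        assert report.recommendations

    def test_worst_case_clamps_at_zero(self, config):
        report = rel.grade([_true(h) for h in config.grades], config)
        assert report.trust_level == 0

    @given(st.lists(st.sampled_from(sorted(ThresholdConfig().grades)), max_size=8,
                    unique=True), st.randoms(use_true_random=False))
    @settings(max_examples=40, deadline=None)
    def test_order_independent_and_monotone(self, hyps, rnd):
        config = ThresholdConfig()
        results = [_true(h) for h in hyps]
        shuffled = list(results)
        rnd.shuffle(shuffled)
        assert rel.grade(results, config).trust_level == \
            rel.grade(shuffled, config).trust_level
        if hyps:
            fewer = rel.grade(results[:-1], config).trust_level
            assert rel.grade(results, config).trust_level <= fewer

    def test_every_violation_has_recommendation(self, config):
        report = rel.grade([_true(h) for h in config.grades], config)
        for hyp, _, _ in report.violations:
            assert report.recommendations[hyp].strip()
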