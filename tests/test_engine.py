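"""Engine orchestration: activation, evaluation, plan updates, termination."""
import itertools

import pytest

from conftest import activity, bg, bolus, carb, ctx_of, reg
from diakb import PatientProfile, run
from diakb.engine import PlanCase, PlanEntry, _combine_children, update_plan
from diakb.kb import CAUSE_BRANCHES
from diakb.model import DataType, HypothesisResult, State


class TestRun:
    def test_in_range_bg_only(self, kb):
        ctx = ctx_of([bg(0, 8, 0, 6.0), bg(0, 12, 0, 6.5), bg(0, 18, 0, 5.8)])
        result = run(ctx, kb)
        assert result.events == []
        assert result.result("hyperglycemia").state == State.FALSE
        assert result.result("hypoglycemia").state == State.FALSE
        # the reliability family was evaluated
        assert result.result("no_carbohydrates_registered").state == State.TRUE

    def test_hyper_event_appends_five_cause_branches(self, kb):
        ctx = ctx_of([carb(0, 12, 0, 40.0), bg(0, 14, 30, 14.5)])
        result = run(ctx, kb)
        events = [e for e in result.events if e.kind == "hyperglycemia"]
        assert len(events) == 1
        attached = {r.hypothesis_id for r in result.results_for(events[0].scope)}
        assert set(CAUSE_BRANCHES["hyperglycemia"]) <= attached

    def test_rerun_is_deterministic(self, kb):
        regs = [carb(0, 12, 0, 40.0), bolus(0, 12, 0, 4.0), bg(0, 14, 30, 14.5),
                bg(0, 18, 0, 3.0), activity(0, 13, 0, "steps", 2000.0)]
        first = run(ctx_of(regs), kb)
        second = run(ctx_of(regs), kb)
        assert first.to_dict() == second.to_dict()

    def test_no_bg_detection_is_na(self, kb):
        ctx = ctx_of([carb(0, 12, 0, 40.0)])
        result = run(ctx, kb)
        assert result.result("hyperglycemia").state == State.NA
        assert "blood_glucose" in result.result("hyperglycemia").justification


class TestActivation:
    def test_icr_check_na_without_insulin_or_reports(self, kb):
        ctx = ctx_of([bg(0, 8, 0, 6.0)], profile=PatientProfile())
        result = run(ctx, kb)
        r = result.result("source_inconsistency_icr")
        assert r.state == State.NA
        assert "missing context" in r.justification

    def test_cob_comparison_na_without_absorption_rate(self, kb):
        regs = [carb(0, 12, 0, 40.0), bg(0, 14, 30, 14.5)]
        ctx = ctx_of(regs, profile=PatientProfile())  # no carb_absorption_rate
        result = run(ctx, kb)
        event = [e for e in result.events if e.kind == "hyperglycemia"][0]
        assert result.result("hyper_cob_above_average", event.scope).state == State.NA

    def test_gap_case_names_missing_context(self, kb):
        ctx = ctx_of([bg(0, 14, 0, 3.0), bg(0, 18, 0, 6.0)])
        result = run(ctx, kb)
        event = [e for e in result.events if e.kind == "hypoglycemia"][0]
        r = result.result("hypo_too_few_carbohydrates", event.scope)
        assert r.state == State.NA
        assert "carbohydrate" in r.justification


class TestParentCombination:
    def test_brute_force_all_child_state_combinations(self, kb):
        """Default-TRUE parent is invalidated exactly when all four children
        are FALSE or NA, checked against brute force over all 3^4 combos."""
        parent = kb.hypotheses["hyper_not_enough_insulin"]
        scope = "event:test"
        for combo in itertools.product(list(State), repeat=4):
            pc = PlanCase()
            for child_id, state in zip(parent.children, combo):
                pc.completed.append(HypothesisResult(
                    hypothesis_id=child_id, scope=scope, state=state,
                    justification="x"))
            got = _combine_children(parent, PlanEntry("T", parent.hypothesis_id,
                                                      scope), pc)
            expected = State.TRUE if any(s == State.TRUE for s in combo) else State.FALSE
            assert got.state == expected, combo

    def test_example_false_na_mix_invalidates(self, kb):
        parent = kb.hypotheses["hyper_not_enough_insulin"]
        pc = PlanCase()
        for child_id, state in zip(parent.children,
                                   [State.FALSE, State.NA, State.NA, State.NA]):
            pc.completed.append(HypothesisResult(hypothesis_id=child_id,
                                                 scope="event:x", state=state,
                                                 justification="x"))
        got = _combine_children(parent, PlanEntry("T", parent.hypothesis_id,
                                                  "event:x"), pc)
        assert got.state == State.FALSE


class TestUpdatePlan:
    def test_trigger_appends_scoped_entries_once(self, kb):
        pc = PlanCase()
        result = HypothesisResult(hypothesis_id="hypoglycemia",
                                  scope="event:hypoglycemia:2024-03-04T14:00",
                                  state=State.TRUE, justification="x")
        update_plan(pc, result, kb)
        added = len(pc.pending)
        assert added == len(kb.plans["hypo_causes"].members)
        assert all(e.scope == result.scope for e in pc.pending)
        update_plan(pc, result, kb)  # same result again: idempotent
        assert len(pc.pending) == added

    def test_false_detection_appends_nothing(self, kb):
        pc = PlanCase()
        result = HypothesisResult(hypothesis_id="hyperglycemia", scope="dataset",
                                  state=State.FALSE)
        update_plan(pc, result, kb)
        assert pc.pending == []


class TestGracefulDegradation:
    def test_evaluation_fault_becomes_na(self, kb, monkeypatch):
        from diakb import kb as kb_module

        def boom(ctx, config):
            raise RuntimeError("synthetic fault")

        monkeypatch.setitem(kb_module.RULES, "not_enough_registrations", boom)
        ctx = ctx_of([bg(0, 8, 0, 6.0)])
        result = run(ctx, kb)  # must not raise
        r = result.result("not_enough_registrations")
        assert r.state == State.NA
        assert r.justification == "evaluation failure"

    def test_empty_context_runs_without_crash(self, kb):
        from diakb import build_context
        ctx = build_context([], PatientProfile(), allow_empty=True)
        result = run(ctx, kb)
        assert result.events == []
        assert result.result("no_blood_glucose_registered").state == State.TRUE
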