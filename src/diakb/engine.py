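"""Hypothesize-and-test reasoning engine.

Execution follows the generate / activate / evaluate / store / update loop:
a plan case is generated from the knowledge base's root plan; each pending
hypothesis is activated (flagged NA when its required context is missing),
evaluated through its registered rule, and its result stored; stored results
feed back into plan-case updates — a TRUE event detection appends that
event's cause sub-plan, scoped to the event.  The run ends at a fixpoint,
when no trigger can add further entries.  The engine never aborts a
consultation: an evaluation fault is recorded as an NA result and the run
continues.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from . import events as ev
from . import reliability as rel
from .kb import DETECTORS, RULES, HypothesisDef, KnowledgeBase
from .model import CurrentContext, DataType, HypothesisResult, State
from .reliability import ReliabilityReport

logger = logging.getLogger(__name__)


class EngineError(RuntimeError):
    pass


@dataclass
class PlanEntry:
    task_id: str
    hypothesis_id: str
    scope: str = "dataset"
    event: Optional[ev.NoticeableEvent] = None


@dataclass
class PlanCase:
    """Ordered pending tasks plus the results already obtained."""

    pending: List[PlanEntry] = field(default_factory=list)
    completed: List[HypothesisResult] = field(default_factory=list)
    provenance: List[str] = field(default_factory=list)
    fired: set = field(default_factory=set)

    def state_of(self, hypothesis_id: str, scope: str) -> Optional[State]:
        for r in self.completed:
            if r.hypothesis_id == hypothesis_id and r.scope == scope:
                return r.state
        return None


@dataclass
class RunResult:
    """Everything one consultation run produced."""

    results: List[HypothesisResult]
    trust: ReliabilityReport
    events: List[ev.NoticeableEvent]
    information_gaps: List[str]
    provenance: List[str]

    def results_for(self, scope: str) -> List[HypothesisResult]:
        return [r for r in self.results if r.scope == scope]

    def result(self, hypothesis_id: str, scope: str = "dataset") -> Optional[HypothesisResult]:
        for r in self.results:
            if r.hypothesis_id == hypothesis_id and r.scope == scope:
                return r
        return None

    def event_causes(self, event: ev.NoticeableEvent) -> List[HypothesisResult]:
        """Results attached to one event (detection result included)."""
        if event.kind == "short_sleep":
            night = event.start.date().isoformat()
            return [r for r in self.results
                    if r.hypothesis_id == "short_sleep" and r.scope == f"night:{night}"]
        return self.results_for(event.scope)

    def to_dict(self) -> dict:
        return {
            "trust_level": self.trust.trust_level,
            "violations": [
                {"hypothesis_id": h, "grade": g, "evidence": e}
                for h, g, e in self.trust.violations
            ],
            "results": [
                {"hypothesis_id": r.hypothesis_id, "scope": r.scope,
                 "state": r.state.value, "justification": r.justification,
                 "numeric_evidence": r.numeric_evidence}
                for r in self.results
            ],
            "events": [
                {"kind": e.kind, "start": e.start.isoformat(timespec="minutes"),
                 "end": e.end.isoformat(timespec="minutes"),
                 "reference_time": e.reference_time.isoformat(timespec="minutes"),
                 "extreme_value": e.extreme_value}
                for e in self.events
            ],
            "information_gaps": list(self.information_gaps),
        }


# ---------------------------------------------------------------------------
# activation


def _atom_satisfied(atom: str, ctx: CurrentContext) -> Tuple[bool, str]:
    domain, _, name = atom.partition(":")
    if domain == "data":
        if name == "insulin":
            return ctx.has_insulin(), "insulin registrations"
        if name == "blood_pressure":
            ok = (ctx.has_type(DataType.BLOOD_PRESSURE_SYSTOLIC)
                  or ctx.has_type(DataType.BLOOD_PRESSURE_DIASTOLIC))
            return ok, "blood pressure registrations"
        if name == "manual_pair":
            manual = [r for r in ctx.registrations if r.manual]
            return len(manual) >= 2, "at least two manual registrations"
        try:
            dt = DataType(name)
        except ValueError:
            return False, f"unknown data type {name}"
        return ctx.has_type(dt), f"{name} registrations"
    if domain == "profile":
        value = getattr(ctx.profile, name, None)
        if isinstance(value, bool):
            return value, f"profile flag {name}"
        return value is not None, f"profile field {name}"
    if domain == "lab":
        return getattr(ctx.lab, name, None) is not None, f"laboratory {name}"
    return False, f"unknown context atom {atom}"


def activate(h: HypothesisDef, ctx: CurrentContext) -> Optional[str]:
    """None when the hypothesis can be activated, else the missing context."""
    for atom in h.requires:
        ok, what = _atom_satisfied(atom, ctx)
        if not ok:
            return what
    return None


# ---------------------------------------------------------------------------
# evaluation


def _combine_children(h: HypothesisDef, entry: PlanEntry, pc: PlanCase) -> HypothesisResult:
    """Default-TRUE parent: invalidated only when all children are FALSE or NA."""
    states = [pc.state_of(c, entry.scope) for c in h.children]
    if any(s == State.TRUE for s in states):
        true_children = [c for c, s in zip(h.children, states) if s == State.TRUE]
        return HypothesisResult(
            hypothesis_id=h.hypothesis_id, scope=entry.scope, state=State.TRUE,
            justification="supported by: " + ", ".join(true_children))
    return HypothesisResult(
        hypothesis_id=h.hypothesis_id, scope=entry.scope, state=State.FALSE,
        justification="all sub-hypotheses are false or not applicable")


def _lack_of_evidence(h: HypothesisDef, entry: PlanEntry, pc: PlanCase) -> HypothesisResult:
    states = [pc.state_of(s, entry.scope) for s in h.siblings]
    if any(s == State.TRUE for s in states):
        return HypothesisResult(hypothesis_id=h.hypothesis_id, scope=entry.scope,
                                state=State.FALSE,
                                justification="a potential cause was identified")
    return HypothesisResult(
        hypothesis_id=h.hypothesis_id, scope=entry.scope, state=State.TRUE,
        justification="no hypothesis could explain this event: a potential "
                      "information gap around its time")


def evaluate(h: HypothesisDef, entry: PlanEntry, ctx: CurrentContext,
             kb: KnowledgeBase, pc: PlanCase) -> HypothesisResult:
    """Validate or invalidate one activated hypothesis."""
    if h.children:
        return _combine_children(h, entry, pc)
    if h.siblings:
        return _lack_of_evidence(h, entry, pc)
    rule = RULES[h.evaluation_rule]
    if h.scope == "event":
        if entry.event is None:
            raise EngineError(f"event-scoped hypothesis {h.hypothesis_id} without event")
        return rule(entry.event, ctx, kb.config)
    return rule(ctx, kb.config)


# ---------------------------------------------------------------------------
# detectors


def _run_detector(h: HypothesisDef, ctx: CurrentContext, kb: KnowledgeBase
                  ) -> Tuple[List[ev.NoticeableEvent], List[HypothesisResult]]:
    cfg = kb.config
    rule = h.evaluation_rule
    if rule in ("detect_hyperglycemia", "detect_hypoglycemia"):
        kind = "hyperglycemia" if rule == "detect_hyperglycemia" else "hypoglycemia"
        found = [e for e in ev.segment_glycemic_events(ctx, cfg) if e.kind == kind]
        if not found:
            return [], [HypothesisResult(hypothesis_id=h.hypothesis_id, scope="dataset",
                                         state=State.FALSE)]
        results = [
            HypothesisResult(
                hypothesis_id=h.hypothesis_id, scope=e.scope, state=State.TRUE,
                justification=f"blood glucose reached {e.extreme_value:g} mmol/L at "
                              f"{e.reference_time.isoformat(timespec='minutes')}",
                numeric_evidence={"extreme_value": e.extreme_value})
            for e in found
        ]
        return found, results
    if rule == "detect_high_bp":
        found = ev.detect_bp_events(ctx, cfg)
        if not found:
            return [], [HypothesisResult(hypothesis_id=h.hypothesis_id, scope="dataset",
                                         state=State.FALSE)]
        results = [
            HypothesisResult(
                hypothesis_id=h.hypothesis_id, scope=e.scope, state=State.TRUE,
                justification=f"blood pressure above {cfg.bp_systolic:g}/"
                              f"{cfg.bp_diastolic:g} mmHg at "
                              f"{e.reference_time.isoformat(timespec='minutes')}",
                numeric_evidence={"extreme_value": e.extreme_value})
            for e in found
        ]
        return found, results
    if rule == "detect_short_sleep":
        return ev.detect_short_sleep(ctx, cfg)
    raise EngineError(f"unknown detector {rule}")


# ---------------------------------------------------------------------------
# the run loop


def _expand_plan(kb: KnowledgeBase, plan_id: str, scope: str,
                 event: Optional[ev.NoticeableEvent]) -> List[PlanEntry]:
    entries: List[PlanEntry] = []
    plan = kb.plans[plan_id]
    for kind, member in plan.members:
        if kind == "plan":
            entries.extend(_expand_plan(kb, member, scope, event))
        else:
            task = kb.tasks[member]
            entries.append(PlanEntry(task_id=member, hypothesis_id=task.hypothesis_id,
                                     scope=scope, event=event))
    return entries


def update_plan(pc: PlanCase, result: HypothesisResult, kb: KnowledgeBase,
                event: Optional[ev.NoticeableEvent] = None) -> PlanCase:
    """Append the sub-plan whose trigger matches the new result, once per scope.

    Idempotent: delivering the same result twice leaves the plan unchanged.
    """
    plan_id = kb.triggers.get((result.hypothesis_id, result.state.value))
    if plan_id is None:
        return pc
    key = (plan_id, result.scope)
    if key in pc.fired:
        return pc
    pc.fired.add(key)
    entries = _expand_plan(kb, plan_id, result.scope, event)
    pc.pending.extend(entries)
    pc.provenance.append(
        f"trigger ({result.hypothesis_id}={result.state.value}, {result.scope}) "
        f"added plan {plan_id} ({len(entries)} tasks)")
    return pc


def run(ctx: CurrentContext, kb: KnowledgeBase) -> RunResult:
    """Execute a full consultation: reliability family, detection, cause trees.

    Deterministic for fixed inputs; terminates at a fixpoint.  The trigger
    graph of the default knowledge base is acyclic, so the iteration cap
    (proportional to hypotheses times events) is never reached on
    well-formed inputs; hitting it raises :class:`EngineError`.
    """
    pc = PlanCase()
    pc.pending.extend(_expand_plan(kb, kb.root_plan, "dataset", None))
    pc.provenance.append(f"root plan {kb.root_plan} generated "
                         f"({len(pc.pending)} tasks)")
    all_events: List[ev.NoticeableEvent] = []
    cap = 50 * max(1, len(kb.hypotheses)) * max(1, len(ctx.registrations) + 1)
    iterations = 0
    while pc.pending:
        iterations += 1
        if iterations > cap:
            raise EngineError("iteration cap exceeded; trigger graph may be cyclic")
        entry = pc.pending.pop(0)
        h = kb.hypotheses[entry.hypothesis_id]
        missing = activate(h, ctx)
        if missing is not None:
            results = [HypothesisResult(
                hypothesis_id=h.hypothesis_id, scope=entry.scope, state=State.NA,
                justification=f"missing context: {missing}")]
            new_events: List[ev.NoticeableEvent] = []
        elif h.evaluation_rule in DETECTORS:
            try:
                new_events, results = _run_detector(h, ctx, kb)
            except Exception:
                logger.exception("detector %s failed", h.evaluation_rule)
                new_events, results = [], [HypothesisResult(
                    hypothesis_id=h.hypothesis_id, scope=entry.scope, state=State.NA,
                    justification="evaluation failure")]
        else:
            new_events = []
            try:
                results = [evaluate(h, entry, ctx, kb, pc)]
            except Exception:
                logger.exception("evaluation of %s failed", h.hypothesis_id)
                results = [HypothesisResult(
                    hypothesis_id=h.hypothesis_id, scope=entry.scope, state=State.NA,
                    justification="evaluation failure")]
        all_events.extend(new_events)
        events_by_scope = {e.scope: e for e in new_events}
        for r in results:
            pc.completed.append(r)
            ctx.system_generated.append(r)
            update_plan(pc, r, kb, events_by_scope.get(r.scope))

    trust = rel.grade(pc.completed, kb.config)
    gaps = sorted(r.scope for r in pc.completed
                  if r.hypothesis_id.endswith("lack_of_evidence")
                  and r.state == State.TRUE)
    return RunResult(results=pc.completed, trust=trust, events=all_events,
                     information_gaps=gaps, provenance=pc.provenance)
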