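"""Declarative knowledge base: hypotheses, plans, tasks, rules, explanations.

The knowledge base is data, not code: it names every hypothesis, the plan
structure that orders them, the context each needs (activation rules), the
registered operation that evaluates each (evaluation rules), and the
template text that explains a validated hypothesis to the reader
(explanation relations).  ``default_kb`` ships the full type 1 diabetes
hypothesis tree; the document round-trip (``save_kb`` / ``load_kb``) makes
extensions — say, a medication-adherence hypothesis for type 2 diabetes —
an edit to a YAML file rather than a code change.
"""
from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import yaml
from pydantic import BaseModel, ConfigDict

from . import events as ev
from . import reliability as rel
from .model import CurrentContext, HypothesisResult, State, ThresholdConfig

# ---------------------------------------------------------------------------
# rule registry

RuleFunc = Callable[..., HypothesisResult]


def _reliability_rule(hyp_id: str, batch: Callable) -> RuleFunc:
    def _rule(ctx: CurrentContext, config: ThresholdConfig) -> HypothesisResult:
        out = batch(ctx) if batch is rel.check_missing_types else batch(ctx, config)
        if isinstance(out, HypothesisResult):
            return out
        for r in out:
            if r.hypothesis_id == hyp_id:
                return r
        raise KeyError(f"batch rule produced no result for {hyp_id}")
    return _rule


#: rule_id -> implementation.  Reliability rules take (ctx, config); event
#: cause rules take (event, ctx, config).  Detector rules are dispatched by
#: the engine itself (they produce events, not single results).
RULES: Dict[str, RuleFunc] = {
    "no_blood_glucose_registered": _reliability_rule("no_blood_glucose_registered", rel.check_missing_types),
    "no_carbohydrates_registered": _reliability_rule("no_carbohydrates_registered", rel.check_missing_types),
    "no_insulin_registered": _reliability_rule("no_insulin_registered", rel.check_missing_types),
    "no_physical_activity_registered": _reliability_rule("no_physical_activity_registered", rel.check_missing_types),
    "error_values_blood_glucose": _reliability_rule("error_values_blood_glucose", rel.check_error_values),
    "error_values_carbohydrates": _reliability_rule("error_values_carbohydrates", rel.check_error_values),
    "error_values_insulin": _reliability_rule("error_values_insulin", rel.check_error_values),
    "not_enough_registrations": _reliability_rule("not_enough_registrations", rel.check_registration_counts),
    "unequal_days_distribution": _reliability_rule("unequal_days_distribution", rel.check_day_distribution),
    "unequal_weekdays_distribution": _reliability_rule("unequal_weekdays_distribution", rel.check_weekday_distribution),
    "source_inconsistency_hba1c": _reliability_rule("source_inconsistency_hba1c", rel.check_source_inconsistencies),
    "source_inconsistency_isf": _reliability_rule("source_inconsistency_isf", rel.check_source_inconsistencies),
    "source_inconsistency_icr": _reliability_rule("source_inconsistency_icr", rel.check_source_inconsistencies),
    "hyper_iob_below_average": ev.rule_hyper_iob_below_average,
    "hyper_last_dose_insufficient": ev.rule_hyper_last_dose_insufficient,
    "hyper_icr_too_low": ev.rule_hyper_icr_too_low,
    "hyper_no_insulin_for_meal": ev.rule_hyper_no_insulin_for_meal,
    "hyper_cob_above_average": ev.rule_hyper_cob_above_average,
    "hyper_intake_above_recommendation": ev.rule_hyper_intake_above_recommendation,
    "hyper_external_factors": ev.rule_hyper_external_factors,
    "hyper_no_physical_activity": ev.rule_hyper_no_physical_activity,
    "hypo_iob_above_average": ev.rule_hypo_iob_above_average,
    "hypo_last_dose_excessive": ev.rule_hypo_last_dose_excessive,
    "hypo_iob_above_icr_requirement": ev.rule_hypo_iob_above_icr_requirement,
    "hypo_external_factors": ev.rule_hypo_external_factors,
    "hypo_no_carb_intake": ev.rule_hypo_no_carb_intake,
    "hypo_intake_below_recommendation": ev.rule_hypo_intake_below_recommendation,
    "hypo_light_moderate_activity": ev.rule_hypo_light_moderate_activity,
    "hypo_extreme_activity": ev.rule_hypo_extreme_activity,
    "bp_external_factors": ev.rule_bp_external_factors,
}

#: Detector rule ids understood by the engine.
DETECTORS = ("detect_hyperglycemia", "detect_hypoglycemia",
             "detect_high_bp", "detect_short_sleep")

#: numeric_evidence keys each evaluation rule produces (for template checks).
EVIDENCE_KEYS: Dict[str, Tuple[str, ...]] = {
    "hyper_iob_below_average": ("current_iob", "average_iob"),
    "hyper_last_dose_insufficient": ("last_dose", "required_dose", "isf"),
    "hyper_icr_too_low": ("insulin_given", "insulin_required", "carbs", "icr"),
    "hyper_no_insulin_for_meal": ("uncovered_meals",),
    "hyper_cob_above_average": ("current_cob", "average_cob"),
    "hyper_intake_above_recommendation": ("carbs", "recommended_max"),
    "hyper_external_factors": ("factors_on_day",),
    "hyper_no_physical_activity": ("activities_in_window",),
    "hypo_iob_above_average": ("current_iob", "average_iob"),
    "hypo_last_dose_excessive": ("last_dose", "required_dose", "bg_at_dose", "isf"),
    "hypo_iob_above_icr_requirement": ("current_iob", "required_iob", "carbs_in_window", "icr"),
    "hypo_external_factors": ("factors_on_day",),
    "hypo_no_carb_intake": ("intakes_in_window",),
    "hypo_intake_below_recommendation": ("carbs", "recommended_min"),
    "hypo_light_moderate_activity": ("matching_activities",),
    "hypo_extreme_activity": ("matching_activities",),
    "bp_external_factors": ("factors_on_day",),
    "detect_short_sleep": ("sleep_gap_hours", "recommended_hours"),
}


# ---------------------------------------------------------------------------
# declarative structures


@dataclass(frozen=True)
class HypothesisDef:
    """One claim the engine can test, with its activation requirements.

    ``requires`` lists context atoms that must be satisfiable for the
    hypothesis to be activated (``data:<type>``, ``profile:<field>``,
    ``lab:<field>``); a failed atom yields NA naming the missing context.
    ``children`` marks a default-TRUE parent that is invalidated only when
    every child is FALSE or NA; ``siblings`` marks a lack-of-evidence
    hypothesis that is TRUE exactly when none of its sibling branches is
    TRUE (the information-gap definition).
    """

    hypothesis_id: str
    description: str
    scope: str = "dataset"  # dataset | event | night
    evaluation_rule: Optional[str] = None
    requires: Tuple[str, ...] = ()
    children: Tuple[str, ...] = ()
    siblings: Tuple[str, ...] = ()
    template: Optional[str] = None


@dataclass(frozen=True)
class TaskDef:
    task_id: str
    description: str
    hypothesis_id: str
    required_context: Tuple[str, ...]
    evaluation_rule_id: Optional[str]


@dataclass(frozen=True)
class PlanDef:
    """An ordered sequence of tasks (or nested plans) with an optional trigger.

    ``trigger = (hypothesis_id, state)`` means the plan is appended to the
    plan case, scoped to the triggering result, whenever such a result is
    stored; ``trigger = None`` marks a root plan.
    """

    plan_id: str
    members: Tuple[Tuple[str, str], ...]  # ("task"|"plan", id)
    trigger: Optional[Tuple[str, str]] = None


@dataclass(frozen=True)
class ExplanationRelation:
    parent: str
    children: Tuple[str, ...]
    combination: str  # complementary | all_false_or_na_invalidates_parent
    template: str


@dataclass
class KnowledgeBase:
    config: ThresholdConfig
    hypotheses: Dict[str, HypothesisDef] = field(default_factory=dict)
    plans: Dict[str, PlanDef] = field(default_factory=dict)
    root_plan: str = "consultation"

    @property
    def tasks(self) -> Dict[str, TaskDef]:
        return {
            f"T_{h.hypothesis_id}": TaskDef(
                task_id=f"T_{h.hypothesis_id}",
                description=f"test whether {h.description}",
                hypothesis_id=h.hypothesis_id,
                required_context=h.requires,
                evaluation_rule_id=h.evaluation_rule,
            )
            for h in self.hypotheses.values()
        }

    @property
    def triggers(self) -> Dict[Tuple[str, str], str]:
        return {p.trigger: p.plan_id for p in self.plans.values() if p.trigger}

    def explanation_relations(self) -> List[ExplanationRelation]:
        out = []
        for h in self.hypotheses.values():
            if h.children:
                out.append(ExplanationRelation(
                    parent=h.hypothesis_id, children=h.children,
                    combination="all_false_or_na_invalidates_parent",
                    template=h.template or h.description))
            if h.siblings:
                out.append(ExplanationRelation(
                    parent=h.hypothesis_id, children=h.siblings,
                    combination="complementary",
                    template=h.template or h.description))
        return out


# ---------------------------------------------------------------------------
# the default type 1 diabetes knowledge base


def _hyp(hid: str, desc: str, **kw) -> HypothesisDef:
    kw.setdefault("evaluation_rule", hid if hid in RULES else None)
    return HypothesisDef(hypothesis_id=hid, description=desc, **kw)


def _default_hypotheses() -> List[HypothesisDef]:
    H: List[HypothesisDef] = []
    # -- data reliability family (dataset scope)
    H += [
        _hyp("no_blood_glucose_registered", "no blood glucose was registered"),
        _hyp("no_carbohydrates_registered", "no carbohydrates were registered"),
        _hyp("no_insulin_registered", "no insulin was registered",
             requires=("profile:uses_insulin",)),
        _hyp("no_physical_activity_registered", "no physical activity was registered"),
        _hyp("error_values_blood_glucose", "blood glucose contains implausible values",
             requires=("data:blood_glucose",)),
        _hyp("error_values_carbohydrates", "carbohydrates contain implausible values",
             requires=("data:carbohydrates",)),
        _hyp("error_values_insulin", "insulin contains implausible values",
             requires=("data:insulin",)),
        _hyp("not_enough_registrations", "too few registrations per day"),
        _hyp("unequal_days_distribution",
             "registrations are not distributed equally between days"),
        _hyp("unequal_weekdays_distribution",
             "registrations are not distributed equally between weekdays"),
        _hyp("source_inconsistency_hba1c",
             "estimated HbA1c is inconsistent with the laboratory value",
             requires=("data:blood_glucose", "lab:hba1c"),
             template="Estimated HbA1c {calculated:.2f}% deviates from the laboratory "
                      "value {reference:.2f}% by {deviation:.0%}."),
        _hyp("source_inconsistency_isf",
             "calculated insulin sensitivity is inconsistent with the reported one",
             requires=("data:insulin", "profile:reported_isf"),
             template="Calculated ISF {calculated:.2f} mmol/L/U deviates from the "
                      "reported {reference:.2f} by {deviation:.0%}."),
        _hyp("source_inconsistency_icr",
             "calculated insulin-to-carbohydrate ratio is inconsistent with the reported one",
             requires=("data:insulin", "profile:reported_icr"),
             template="Calculated I:C {calculated:.1f} g/U deviates from the "
                      "reported {reference:.1f} by {deviation:.0%}."),
    ]
    # -- medical problem roots (detectors)
    H += [
        _hyp("hyperglycemia", "the patient had a hyperglycemic event",
             scope="event", evaluation_rule="detect_hyperglycemia",
             requires=("data:blood_glucose",)),
        _hyp("hypoglycemia", "the patient had a hypoglycemic event",
             scope="event", evaluation_rule="detect_hypoglycemia",
             requires=("data:blood_glucose",)),
        _hyp("high_blood_pressure", "the patient had high blood pressure",
             scope="event", evaluation_rule="detect_high_bp",
             requires=("data:blood_pressure",)),
        _hyp("short_sleep", "the patient slept less than the recommended duration",
             scope="night", evaluation_rule="detect_short_sleep",
             requires=("data:manual_pair",),
             template="The longest overnight gap between manual registrations was "
                      "{sleep_gap_hours:.1f} h, below the recommended "
                      "{recommended_hours:.0f} h."),
    ]
    # -- hyperglycemia cause tree (event scope)
    H += [
        _hyp("hyper_iob_below_average",
             "the current active insulin was less than the average active insulin",
             scope="event", requires=("data:insulin",),
             template="Active insulin at the event ({current_iob:.2f} U) was below the "
                      "period average ({average_iob:.2f} U)."),
        _hyp("hyper_last_dose_insufficient",
             "the dose of the last insulin shot was insufficient",
             scope="event", requires=("data:insulin",),
             template="The last dose of {last_dose:.1f} U was below the estimated "
                      "{required_dose:.1f} U needed to reach the glucose target "
                      "(ISF {isf:.2f} mmol/L per U)."),
        _hyp("hyper_icr_too_low", "the insulin-to-carbohydrate ratio was too low",
             scope="event", requires=("data:insulin", "data:carbohydrates"),
             template="Only {insulin_given:.1f} U were given for {carbs:.0f} g of "
                      "carbohydrates, against {insulin_required:.1f} U per the I:C of "
                      "{icr:.1f} g/U."),
        _hyp("hyper_no_insulin_for_meal", "no insulin was taken before or after a meal",
             scope="event", requires=("data:insulin", "data:carbohydrates"),
             template="{uncovered_meals:.0f} meal(s) before the event had no insulin "
                      "registration in the surrounding window."),
        _hyp("hyper_not_enough_insulin", "there was not enough insulin",
             scope="event", requires=("data:insulin",),
             children=("hyper_iob_below_average", "hyper_last_dose_insufficient",
                       "hyper_icr_too_low", "hyper_no_insulin_for_meal")),
        _hyp("hyper_cob_above_average",
             "there were more carbohydrates on board than on average",
             scope="event",
             requires=("data:carbohydrates", "profile:carb_absorption_rate"),
             template="Carbohydrates on board ({current_cob:.0f} g) exceeded the period "
                      "average ({average_cob:.0f} g)."),
        _hyp("hyper_intake_above_recommendation",
             "the last carbohydrate intake was greater than the recommendation",
             scope="event", requires=("data:carbohydrates",),
             template="The last intake of {carbs:.0f} g exceeded the recommended "
                      "maximum of {recommended_max:.0f} g."),
        _hyp("hyper_too_much_carbohydrates", "there were too many carbohydrates",
             scope="event", requires=("data:carbohydrates",),
             children=("hyper_cob_above_average", "hyper_intake_above_recommendation")),
        _hyp("hyper_external_factors", "external factors were present",
             scope="event", requires=("data:external_factor",),
             template="{factors_on_day:.0f} external factor registration(s) on the day "
                      "of the event."),
        _hyp("hyper_no_physical_activity", "there was a lack of physical activity",
             scope="event", requires=("data:physical_activity",),
             template="No physical activity was registered in the 24 h before the "
                      "event."),
        _hyp("hyper_lack_of_evidence", "lack of evidence: a potential information gap",
             scope="event",
             siblings=("hyper_not_enough_insulin", "hyper_too_much_carbohydrates",
                       "hyper_external_factors", "hyper_no_physical_activity")),
    ]
    # -- hypoglycemia cause tree (event scope)
    H += [
        _hyp("hypo_iob_above_average",
             "the current active insulin was greater than the average active insulin",
             scope="event", requires=("data:insulin",),
             template="Active insulin at the event ({current_iob:.2f} U) exceeded the "
                      "period average ({average_iob:.2f} U)."),
        _hyp("hypo_last_dose_excessive", "the last insulin injection was too high",
             scope="event", requires=("data:insulin",),
             template="The last dose of {last_dose:.1f} U exceeded the "
                      "{required_dose:.1f} U required from a blood glucose of "
                      "{bg_at_dose:.1f} mmol/L (ISF {isf:.2f})."),
        _hyp("hypo_iob_above_icr_requirement",
             "the active insulin was greater than required according to the I:C",
             scope="event", requires=("data:insulin",),
             template="Active insulin ({current_iob:.2f} U) exceeded the "
                      "{required_iob:.2f} U covering {carbs_in_window:.0f} g of recent "
                      "carbohydrates per the I:C of {icr:.1f} g/U."),
        _hyp("hypo_too_much_insulin", "there was too much insulin",
             scope="event", requires=("data:insulin",),
             children=("hypo_iob_above_average", "hypo_last_dose_excessive",
                       "hypo_iob_above_icr_requirement")),
        _hyp("hypo_no_carb_intake", "there was no carbohydrate intake up to 4 hours prior",
             scope="event", requires=("data:carbohydrates",),
             template="No carbohydrate intake was registered in the 4 h before the "
                      "event."),
        _hyp("hypo_intake_below_recommendation",
             "the last carbohydrate intake was lower than the recommendation",
             scope="event", requires=("data:carbohydrates",),
             template="The last intake of {carbs:.0f} g was below the recommended "
                      "minimum of {recommended_min:.0f} g."),
        _hyp("hypo_too_few_carbohydrates", "there were too few carbohydrates",
             scope="event", requires=("data:carbohydrates",),
             children=("hypo_no_carb_intake", "hypo_intake_below_recommendation")),
        _hyp("hypo_external_factors", "external factors were present",
             scope="event", requires=("data:external_factor",),
             template="{factors_on_day:.0f} external factor registration(s) on the day "
                      "of the event."),
        _hyp("hypo_light_moderate_activity",
             "there was light to moderate physical activity up to 4 hours prior",
             scope="event", requires=("data:physical_activity",),
             template="{matching_activities:.0f} light-to-moderate activity "
                      "registration(s) in the 4 h before the event."),
        _hyp("hypo_extreme_activity",
             "there was extreme physical activity up to 24 hours prior",
             scope="event", requires=("data:physical_activity",),
             template="{matching_activities:.0f} extreme activity registration(s) in "
                      "the 24 h before the event."),
        _hyp("hypo_physical_activity", "physical activity preceded the event",
             scope="event", requires=("data:physical_activity",),
             children=("hypo_light_moderate_activity", "hypo_extreme_activity")),
        _hyp("hypo_lack_of_evidence", "lack of evidence: a potential information gap",
             scope="event",
             siblings=("hypo_too_much_insulin", "hypo_too_few_carbohydrates",
                       "hypo_external_factors", "hypo_physical_activity")),
    ]
    # -- high blood pressure causes
    H += [
        _hyp("bp_external_factors", "external factors were present",
             scope="event", requires=("data:external_factor",),
             template="{factors_on_day:.0f} external factor registration(s) on the day "
                      "of the reading."),
        _hyp("bp_lack_of_evidence", "lack of evidence: a potential information gap",
             scope="event", siblings=("bp_external_factors",)),
    ]
    return H


#: Top-level cause branches per event kind, in knowledge-base order.
CAUSE_BRANCHES: Dict[str, Tuple[str, ...]] = {
    "hyperglycemia": ("hyper_not_enough_insulin", "hyper_too_much_carbohydrates",
                      "hyper_external_factors", "hyper_no_physical_activity",
                      "hyper_lack_of_evidence"),
    "hypoglycemia": ("hypo_too_much_insulin", "hypo_too_few_carbohydrates",
                     "hypo_external_factors", "hypo_physical_activity",
                     "hypo_lack_of_evidence"),
    "high_bp": ("bp_external_factors", "bp_lack_of_evidence"),
}


def default_kb(config: Optional[ThresholdConfig] = None) -> KnowledgeBase:
    """The shipped type 1 diabetes knowledge base.

    Thirteen data-reliability sub-hypotheses, four noticeable-event
    detectors, and the per-event cause trees: five branches for
    hyperglycemia (insulin, carbohydrates, external factors, activity, lack
    of evidence) with their children, the mirrored five for hypoglycemia,
    and the external-factor check for high blood pressure.
    """
    config = config if config is not None else ThresholdConfig()
    config.model_validate(config.model_dump())  # refuse construction on invalid config
    kb = KnowledgeBase(config=config)
    for h in _default_hypotheses():
        kb.hypotheses[h.hypothesis_id] = h

    def task_members(ids: Sequence[str]) -> Tuple[Tuple[str, str], ...]:
        return tuple(("task", f"T_{h}") for h in ids)

    reliability_ids = [h for h in kb.hypotheses
                       if kb.hypotheses[h].scope == "dataset"]
    kb.plans["reliability"] = PlanDef("reliability", task_members(reliability_ids))
    kb.plans["detection"] = PlanDef(
        "detection",
        task_members(["hyperglycemia", "hypoglycemia", "high_blood_pressure",
                      "short_sleep"]))
    kb.plans["consultation"] = PlanDef(
        "consultation", (("plan", "reliability"), ("plan", "detection")))
    kb.plans["hyper_causes"] = PlanDef(
        "hyper_causes",
        task_members(["hyper_iob_below_average", "hyper_last_dose_insufficient",
                      "hyper_icr_too_low", "hyper_no_insulin_for_meal",
                      "hyper_not_enough_insulin", "hyper_cob_above_average",
                      "hyper_intake_above_recommendation",
                      "hyper_too_much_carbohydrates", "hyper_external_factors",
                      "hyper_no_physical_activity", "hyper_lack_of_evidence"]),
        trigger=("hyperglycemia", State.TRUE.value))
    kb.plans["hypo_causes"] = PlanDef(
        "hypo_causes",
        task_members(["hypo_iob_above_average", "hypo_last_dose_excessive",
                      "hypo_iob_above_icr_requirement", "hypo_too_much_insulin",
                      "hypo_no_carb_intake", "hypo_intake_below_recommendation",
                      "hypo_too_few_carbohydrates", "hypo_external_factors",
                      "hypo_light_moderate_activity", "hypo_extreme_activity",
                      "hypo_physical_activity", "hypo_lack_of_evidence"]),
        trigger=("hypoglycemia", State.TRUE.value))
    kb.plans["bp_causes"] = PlanDef(
        "bp_causes", task_members(["bp_external_factors", "bp_lack_of_evidence"]),
        trigger=("high_blood_pressure", State.TRUE.value))
    return kb


# ---------------------------------------------------------------------------
# validation


def _template_fields(template: str) -> List[str]:
    return [f for _, f, _, _ in string.Formatter().parse(template) if f]


def validate(kb: KnowledgeBase) -> List[str]:
    """Self-consistency diagnostics; an empty list means well-formed."""
    diags: List[str] = []
    hyp_ids = set(kb.hypotheses)
    for h in kb.hypotheses.values():
        rule = h.evaluation_rule
        if rule is not None and rule not in RULES and rule not in DETECTORS:
            diags.append(f"hypothesis {h.hypothesis_id}: unknown evaluation rule {rule}")
        if rule is None and not h.children and not h.siblings:
            diags.append(f"hypothesis {h.hypothesis_id}: no way to evaluate it")
        for c in h.children + h.siblings:
            if c not in hyp_ids:
                diags.append(f"hypothesis {h.hypothesis_id}: dangling reference {c}")
        if h.template:
            allowed = set(EVIDENCE_KEYS.get(rule or "", ()))
            for f in _template_fields(h.template):
                if allowed and f not in allowed:
                    diags.append(
                        f"hypothesis {h.hypothesis_id}: template placeholder {f} not "
                        f"among the evidence keys of rule {rule}")
    task_ids = set(kb.tasks)
    for p in kb.plans.values():
        for kind, member in p.members:
            if kind == "task" and member not in task_ids:
                diags.append(f"plan {p.plan_id}: dangling task {member}")
            if kind == "plan" and member not in kb.plans:
                diags.append(f"plan {p.plan_id}: dangling plan {member}")
        if p.trigger and p.trigger[0] not in hyp_ids:
            diags.append(f"plan {p.plan_id}: trigger references unknown hypothesis "
                         f"{p.trigger[0]}")
    # plan membership cycles
    state: Dict[str, int] = {}

    def visit(pid: str, stack: Tuple[str, ...]) -> None:
        if state.get(pid) == 2:
            return
        if pid in stack:
            diags.append(f"plan membership cycle: {' -> '.join(stack + (pid,))}")
            return
        for kind, member in kb.plans.get(pid, PlanDef(pid, ())).members:
            if kind == "plan":
                visit(member, stack + (pid,))
        state[pid] = 2

    for pid in kb.plans:
        visit(pid, ())
    # reachability from the root plan and triggers
    reachable: set = set()

    def collect(pid: str, seen: set) -> None:
        if pid in seen or pid not in kb.plans:
            return
        seen.add(pid)
        for kind, member in kb.plans[pid].members:
            if kind == "task":
                task = kb.tasks.get(member)
                if task:
                    reachable.add(task.hypothesis_id)
            else:
                collect(member, seen)

    seen: set = set()
    collect(kb.root_plan, seen)
    for p in kb.plans.values():
        if p.trigger:
            collect(p.plan_id, seen)
    for h in hyp_ids - reachable:
        diags.append(f"hypothesis {h} unreachable from the root plan or any trigger")
    return diags


# ---------------------------------------------------------------------------
# document round-trip


class _HypDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hypothesis_id: str
    description: str
    scope: str = "dataset"
    evaluation_rule: Optional[str] = None
    requires: List[str] = []
    children: List[str] = []
    siblings: List[str] = []
    template: Optional[str] = None


class _PlanDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    plan_id: str
    members: List[Tuple[str, str]]
    trigger: Optional[Tuple[str, str]] = None


class _KBDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    version: int = 1
    config: dict = {}
    root_plan: str = "consultation"
    hypotheses: List[_HypDoc]
    plans: List[_PlanDoc]


class KBSchemaError(ValueError):
    """The document does not match the knowledge-base schema."""


def kb_to_document(kb: KnowledgeBase) -> dict:
    return {
        "version": 1,
        "config": kb.config.model_dump(mode="json"),
        "root_plan": kb.root_plan,
        "hypotheses": [
            {
                "hypothesis_id": h.hypothesis_id,
                "description": h.description,
                "scope": h.scope,
                "evaluation_rule": h.evaluation_rule,
                "requires": list(h.requires),
                "children": list(h.children),
                "siblings": list(h.siblings),
                "template": h.template,
            }
            for h in kb.hypotheses.values()
        ],
        "plans": [
            {"plan_id": p.plan_id, "members": [list(m) for m in p.members],
             "trigger": list(p.trigger) if p.trigger else None}
            for p in kb.plans.values()
        ],
    }


def kb_from_document(doc: dict) -> KnowledgeBase:
    try:
        parsed = _KBDoc.model_validate(doc)
    except Exception as exc:
        raise KBSchemaError(str(exc)) from exc
    config = ThresholdConfig.model_validate(parsed.config) if parsed.config else ThresholdConfig()
    kb = KnowledgeBase(config=config, root_plan=parsed.root_plan)
    for h in parsed.hypotheses:
        kb.hypotheses[h.hypothesis_id] = HypothesisDef(
            hypothesis_id=h.hypothesis_id, description=h.description, scope=h.scope,
            evaluation_rule=h.evaluation_rule, requires=tuple(h.requires),
            children=tuple(h.children), siblings=tuple(h.siblings),
            template=h.template)
    for p in parsed.plans:
        kb.plans[p.plan_id] = PlanDef(
            plan_id=p.plan_id, members=tuple(tuple(m) for m in p.members),
            trigger=tuple(p.trigger) if p.trigger else None)
    return kb


def save_kb(kb: KnowledgeBase, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(kb_to_document(kb), fh, sort_keys=False)


def load_kb(path) -> KnowledgeBase:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise KBSchemaError("knowledge-base document must be a mapping")
    return kb_from_document(doc)
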