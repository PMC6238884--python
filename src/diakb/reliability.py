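"""Data-reliability hypothesis family and the 0-50 trust grading.

Each sub-hypothesis flags one way a self-collected diary can be untrustworthy:
a missing data type, implausible values, too few registrations, unevenly
distributed registrations, or disagreement between the module's own
calculations and an independent reference (laboratory HbA1c, patient-reported
ISF or I:C).  Trust starts at 50 (full trust) and each TRUE sub-hypothesis
deducts its configured grade, clamped at 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from . import calculators as calc
from .model import (
    CurrentContext,
    DataType,
    HypothesisResult,
    State,
    ThresholdConfig,
    strictly_greater,
)

#: Recommendation texts shown to patients when a reliability finding is TRUE.
RECOMMENDATIONS: Dict[str, str] = {
    "no_blood_glucose_registered": (
        "Registering blood glucose values is the foundation for every other "
        "analysis; please measure and record your blood glucose."),
    "no_carbohydrates_registered": (
        "Registering carbohydrate intakes will permit a better estimation of "
        "your insulin correction dosage and could help you reduce variation, "
        "i.e. highs and lows of your blood glucose values."),
    "no_insulin_registered": (
        "Registering your insulin doses allows the module to judge whether "
        "doses matched your meals and glucose levels."),
    "no_physical_activity_registered": (
        "Registering physical activity helps explain glucose excursions up to "
        "a day after the activity."),
    "error_values_blood_glucose": (
        "Some blood glucose values lie outside the physiologically plausible "
        "range; please verify whether they were entered correctly."),
    "error_values_carbohydrates": (
        "Some carbohydrate values look implausibly large or non-positive; "
        "please verify them."),
    "error_values_insulin": (
        "Some insulin doses look implausibly large or non-positive; please "
        "verify them."),
    "not_enough_registrations": (
        "Registering more often (at least 5 blood glucose measurements a day) "
        "lets the module compute reliable trends."),
    "unequal_days_distribution": (
        "Registrations are unevenly spread across days; registering regularly "
        "every day makes the analyses more reliable."),
    "unequal_weekdays_distribution": (
        "Registrations differ considerably between weekdays; try to register "
        "as regularly during the weekend as during the week."),
    "source_inconsistency_hba1c": (
        "The HbA1c estimated from your self-measured glucose deviates from "
        "the laboratory value; your meter may be miscalibrated or the diary "
        "may not reflect your typical days."),
    "source_inconsistency_isf": (
        "Your reported insulin sensitivity factor disagrees with the one "
        "calculated from your total daily dose; please review it with your "
        "clinician."),
    "source_inconsistency_icr": (
        "Your reported insulin-to-carbohydrate ratio disagrees with the one "
        "calculated from your diary; please review it with your clinician."),
}


def _res(hyp: str, state: State, justification: str = "",
         evidence: Optional[Dict[str, float]] = None) -> HypothesisResult:
    return HypothesisResult(hypothesis_id=hyp, scope="dataset", state=state,
                            justification=justification,
                            numeric_evidence=evidence or {})


def _na(hyp: str, missing: str) -> HypothesisResult:
    return _res(hyp, State.NA, justification=f"missing context: {missing}")


# ---------------------------------------------------------------------------


def check_missing_types(ctx: CurrentContext) -> List[HypothesisResult]:
    """One result per core data type; TRUE when none of it was registered.

    The insulin variant is not applicable for patients who do not use
    insulin.
    """
    results = []
    results.append(_res(
        "no_blood_glucose_registered",
        State.TRUE if not ctx.has_type(DataType.BLOOD_GLUCOSE) else State.FALSE,
        justification="" if ctx.has_type(DataType.BLOOD_GLUCOSE)
        else "no blood glucose registered in the period"))
    results.append(_res(
        "no_carbohydrates_registered",
        State.TRUE if not ctx.has_type(DataType.CARBOHYDRATES) else State.FALSE,
        justification="" if ctx.has_type(DataType.CARBOHYDRATES)
        else "no carbohydrates registered in the period"))
    if not ctx.profile.uses_insulin:
        results.append(_na("no_insulin_registered", "patient does not use insulin"))
    else:
        results.append(_res(
            "no_insulin_registered",
            State.TRUE if not ctx.has_insulin() else State.FALSE,
            justification="" if ctx.has_insulin()
            else "no insulin registered in the period"))
    results.append(_res(
        "no_physical_activity_registered",
        State.TRUE if not ctx.has_type(DataType.PHYSICAL_ACTIVITY) else State.FALSE,
        justification="" if ctx.has_type(DataType.PHYSICAL_ACTIVITY)
        else "no physical activity registered in the period"))
    return results


_ERROR_SPECS = (
    ("error_values_blood_glucose", (DataType.BLOOD_GLUCOSE,), "bg_plausible_range"),
    ("error_values_carbohydrates", (DataType.CARBOHYDRATES,), "carbs_plausible_range"),
    ("error_values_insulin", (DataType.INSULIN_BOLUS, DataType.INSULIN_BASAL),
     "insulin_plausible_range"),
)


def check_error_values(ctx: CurrentContext, config: ThresholdConfig) -> List[HypothesisResult]:
    """TRUE when any value of the type falls outside its plausibility range.

    The blood-glucose range is closed below at 1.1 mmol/L (values beneath it
    are near-certain registration or measurement errors); carbohydrate and
    insulin ranges exclude non-positive values and implausibly large ones.
    A type with no registrations at all yields NA — its absence is the
    missing-type hypothesis' claim, not this one's.
    """
    results = []
    for hyp, types, range_name in _ERROR_SPECS:
        regs = [r for t in types for r in ctx.by_type(t)]
        if not regs:
            results.append(_na(hyp, f"{types[0].value} registrations"))
            continue
        low, high = getattr(config, range_name)
        if hyp == "error_values_blood_glucose":
            flagged = [r for r in regs if r.value < low or r.value > high]
        else:  # open below: zero or negative intakes/doses are errors
            flagged = [r for r in regs if r.value <= low or r.value > high]
        if flagged:
            listing = "; ".join(
                f"{r.value:g} at {r.timestamp.isoformat(timespec='minutes')}"
                for r in flagged[:5])
            results.append(_res(
                hyp, State.TRUE,
                justification=f"implausible values, please validate them: {listing}",
                evidence={"flagged_count": float(len(flagged)),
                          "range_low": low, "range_high": high}))
        else:
            results.append(_res(hyp, State.FALSE))
    return results


def _daily_counts(ctx: CurrentContext) -> Dict[DataType, List[int]]:
    """Per-day registration counts for each type present in the context."""
    days = [d.date() for d in ctx.period_dates()]
    index = {d: i for i, d in enumerate(days)}
    counts: Dict[DataType, List[int]] = {}
    for r in ctx.registrations:
        counts.setdefault(r.data_type, [0] * len(days))
        i = index.get(r.timestamp.date())
        if i is not None:
            counts[r.data_type][i] += 1
    return counts


def _min_per_day(ctx: CurrentContext, config: ThresholdConfig) -> Dict[DataType, int]:
    mins = {
        DataType.BLOOD_GLUCOSE: config.min_bg_per_day,
        DataType.CARBOHYDRATES: config.min_carbs_per_day,
        DataType.PHYSICAL_ACTIVITY: config.min_activity_per_day,
    }
    if ctx.profile.uses_insulin:
        mins[DataType.INSULIN_BOLUS] = config.min_insulin_per_day
    return mins


def check_registration_counts(ctx: CurrentContext, config: ThresholdConfig) -> HypothesisResult:
    """TRUE when a present type falls below its per-day minimum on any day.

    Only types with at least one registration in the period are judged: a
    wholly absent type is the missing-type hypothesis' finding.  Insulin is
    judged on bolus registrations and only for insulin users.
    """
    hyp = "not_enough_registrations"
    counts = _daily_counts(ctx)
    mins = _min_per_day(ctx, config)
    days = [d.date() for d in ctx.period_dates()]
    shortfalls: List[Tuple[str, str, int, int]] = []
    judged = 0
    for dt, minimum in mins.items():
        if dt not in counts or minimum <= 0:
            continue
        judged += 1
        for day, n in zip(days, counts[dt]):
            if n < minimum:
                shortfalls.append((day.isoformat(), dt.value, n, minimum))
    if judged == 0:
        return _na(hyp, "registrations to judge")
    if shortfalls:
        listing = "; ".join(f"{day}: {n} {dt} (minimum {m})"
                            for day, dt, n, m in shortfalls[:5])
        return _res(hyp, State.TRUE,
                    justification=f"days below the registration minimum: {listing}",
                    evidence={"shortfall_days": float(len(shortfalls))})
    return _res(hyp, State.FALSE)


def _dispersion(per_group: np.ndarray, config: ThresholdConfig) -> float:
    if config.dispersion_statistic == "std":
        return float(np.std(per_group))
    return float(np.max(np.abs(per_group - np.mean(per_group))))


def _distribution_check(hyp: str, groups: Dict[DataType, np.ndarray],
                        config: ThresholdConfig, grouping: str) -> HypothesisResult:
    worst: Optional[Tuple[str, float, float]] = None
    for dt, counts in groups.items():
        mean = float(np.mean(counts))
        if mean == 0:
            continue
        observed = _dispersion(counts, config)
        allowed = config.distribution_tolerance * mean
        if strictly_greater(observed, allowed) and (worst is None or observed > worst[1]):
            worst = (dt.value, observed, allowed)
    if worst is not None:
        dt, observed, allowed = worst
        return _res(
            hyp, State.TRUE,
            justification=(f"{dt} registrations deviate by {observed:.1f} per {grouping} "
                           f"while the rules allow a deviation of {allowed:.1f}"),
            evidence={"observed_dispersion": observed, "allowed_dispersion": allowed})
    return _res(hyp, State.FALSE)


def check_day_distribution(ctx: CurrentContext, config: ThresholdConfig) -> HypothesisResult:
    """Per-day counts of each present type must not disperse beyond 20% of mean."""
    hyp = "unequal_days_distribution"
    days = ctx.period_dates()
    if len(days) < 2:
        return _na(hyp, "at least two days of data")
    groups = {dt: np.asarray(c, dtype=float) for dt, c in _daily_counts(ctx).items()}
    return _distribution_check(hyp, groups, config, "day")


def check_weekday_distribution(ctx: CurrentContext, config: ThresholdConfig) -> HypothesisResult:
    """Totals per weekday (Mon..Sun) must not disperse beyond 20% of mean."""
    hyp = "unequal_weekdays_distribution"
    weekdays_present = {d.weekday() for d in ctx.period_dates()}
    if len(weekdays_present) < 2:
        return _na(hyp, "at least two distinct weekdays of data")
    days = [d.date() for d in ctx.period_dates()]
    groups: Dict[DataType, np.ndarray] = {}
    for dt, counts in _daily_counts(ctx).items():
        per_weekday = np.zeros(7)
        for day, n in zip(days, counts):
            per_weekday[day.weekday()] += n
        wk = sorted(weekdays_present)
        groups[dt] = per_weekday[wk]
    return _distribution_check(hyp, groups, config, "weekday")


def _deviation_check(hyp: str, calculated: Optional[float], reference: Optional[float],
                     tolerance: float, missing: str, label: str) -> HypothesisResult:
    if calculated is None or reference is None or reference == 0:
        return _na(hyp, missing)
    deviation = abs(calculated - reference) / abs(reference)
    evidence = {"calculated": calculated, "reference": reference, "deviation": deviation}
    if strictly_greater(deviation, tolerance):
        return _res(hyp, State.TRUE,
                    justification=(f"calculated {label} {calculated:.2f} deviates "
                                   f"{deviation * 100:.1f}% from the reference "
                                   f"{reference:.2f} (allowed {tolerance * 100:.0f}%)"),
                    evidence=evidence)
    return _res(hyp, State.FALSE, evidence=evidence)


def check_source_inconsistencies(ctx: CurrentContext,
                                 config: ThresholdConfig) -> List[HypothesisResult]:
    """Compare module-calculated values against their independent references.

    HbA1c: the Nathan-inverse estimate from self-measured glucose against the
    laboratory value.  ISF: the 1500/1800-rule value against the reported
    one.  I:C: the 500/450-rule value against the reported one.  Each allows
    the configured relative deviation (default 5%) and is NA when either side
    is unavailable.
    """
    bg = [r.value for r in ctx.by_type(DataType.BLOOD_GLUCOSE)]
    est = calc.estimate_hba1c(bg)
    results = [
        _deviation_check("source_inconsistency_hba1c", est, ctx.lab.hba1c,
                         config.hba1c_tolerance,
                         "laboratory HbA1c or blood glucose registrations", "HbA1c"),
        _deviation_check("source_inconsistency_isf", calc.calculated_isf(ctx),
                         ctx.profile.reported_isf, config.source_tolerance,
                         "reported ISF or insulin registrations", "ISF"),
        _deviation_check("source_inconsistency_icr", calc.calculated_icr(ctx),
                         ctx.profile.reported_icr, config.source_tolerance,
                         "reported I:C or insulin registrations", "I:C"),
    ]
    return results


def evaluate_all(ctx: CurrentContext, config: ThresholdConfig) -> List[HypothesisResult]:
    """The whole reliability family in knowledge-base order."""
    out = check_missing_types(ctx)
    out += check_error_values(ctx, config)
    out.append(check_registration_counts(ctx, config))
    out.append(check_day_distribution(ctx, config))
    out.append(check_weekday_distribution(ctx, config))
    out += check_source_inconsistencies(ctx, config)
    return out


# ---------------------------------------------------------------------------


@dataclass
class ReliabilityReport:
    """Trust level with its violations and patient-facing recommendations."""

    trust_level: int
    violations: List[Tuple[str, int, Dict[str, float]]] = field(default_factory=list)
    recommendations: Dict[str, str] = field(default_factory=dict)


def grade(results: Iterable[HypothesisResult], config: ThresholdConfig) -> ReliabilityReport:
    """Trust = trust_max minus the grades of all TRUE sub-hypotheses, clamped.

    Order-independent in its inputs; results outside the reliability family
    (no grade configured) are ignored.
    """
    violations = []
    recommendations = {}
    deducted = 0
    for r in results:
        g = config.grades.get(r.hypothesis_id)
        if g is None or r.state != State.TRUE:
            continue
        deducted += g
        violations.append((r.hypothesis_id, g, dict(r.numeric_evidence)))
        recommendations[r.hypothesis_id] = RECOMMENDATIONS.get(
            r.hypothesis_id, "Please review this data-quality issue.")
    trust = max(0, min(config.trust_max, config.trust_max - deducted))
    violations.sort(key=lambda v: v[0])
    return ReliabilityReport(trust_level=trust, violations=violations,
                             recommendations=recommendations)
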