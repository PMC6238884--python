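"""Noticeable-event detection and the per-event causal hypothesis rules.

A *noticeable event* is a medical occurrence worth clinician feedback:
a continuous hyper- or hypoglycemic episode, a high blood-pressure reading,
or a short night's sleep inferred from the gap between manual registrations.
For the glycemic kinds the time of the extreme reading inside the episode is
the *reference time* around which all causal rules look for context.

Every rule here returns a :class:`~diakb.model.HypothesisResult`; a rule
whose required context is absent reports NA, never an exception.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Dict, List, Optional, Tuple

from . import calculators as calc
from .model import (
    CurrentContext,
    DataType,
    HypothesisResult,
    Registration,
    State,
    ThresholdConfig,
    slice_window,
    strictly_greater,
    strictly_less,
)


@dataclass
class NoticeableEvent:
    """A segmented medical event with its reference time."""

    kind: str  # hyperglycemia | hypoglycemia | high_bp | short_sleep
    start: datetime
    end: datetime
    reference_time: datetime
    extreme_value: float
    registrations: List[Registration] = field(default_factory=list)

    @property
    def event_id(self) -> str:
        return f"{self.kind}:{self.reference_time.strftime('%Y-%m-%dT%H:%M')}"

    @property
    def scope(self) -> str:
        return f"event:{self.event_id}"


# ---------------------------------------------------------------------------
# reading classification and glycemic segmentation


def meal_or_snack(ts: datetime, ctx: CurrentContext) -> str:
    """'meal' when the clock time falls in a mealtime window, else 'snack'."""
    t = ts.time()
    for start, end in ctx.profile.mealtime_windows.values():
        if start <= t <= end:
            return "meal"
    return "snack"


def classify_reading(r: Registration, ctx: CurrentContext, config: ThresholdConfig) -> str:
    """Classify a blood-glucose reading as fasting, before_meal or other.

    Fasting is inferred conservatively: no carbohydrate registration in the
    preceding ``fasting_carb_free_hours`` (default 8 h).  Before-meal means a
    carb intake classed as a meal follows the reading within the
    insulin-meal window (default 30 min).
    """
    recent_carbs = slice_window(
        ctx, DataType.CARBOHYDRATES, r.timestamp,
        timedelta(hours=config.fasting_carb_free_hours),
    )
    if not recent_carbs:
        return "fasting"
    window_end = r.timestamp + timedelta(minutes=config.insulin_meal_window_minutes)
    for c in ctx.by_type(DataType.CARBOHYDRATES):
        if r.timestamp < c.timestamp <= window_end and meal_or_snack(c.timestamp, ctx) == "meal":
            return "before_meal"
    return "other"


def _glycemic_state(r: Registration, ctx: CurrentContext, config: ThresholdConfig) -> str:
    """'hyper', 'hypo' or 'in_range' for one BG reading, class-dependent."""
    cls = classify_reading(r, ctx, config)
    hyper_bound = config.hyper_fasting if cls in ("fasting", "before_meal") else config.hyper_other
    hypo_bound = config.hypo_fasting if cls == "fasting" else config.hypo_other
    if strictly_greater(r.value, hyper_bound):
        return "hyper"
    if strictly_less(r.value, hypo_bound):
        return "hypo"
    return "in_range"


def segment_glycemic_events(ctx: CurrentContext, config: ThresholdConfig) -> List[NoticeableEvent]:
    """Maximal runs of consecutive out-of-range readings.

    A single event is a continuous excursion without readings returning to
    the normal range in between; runs longer than the maximum event duration
    (default 6 h) are split.  The reference time is the extreme reading of
    the run (max for hyper, min for hypo).
    """
    events: List[NoticeableEvent] = []
    run: List[Registration] = []
    run_kind: Optional[str] = None

    def close_run() -> None:
        nonlocal run, run_kind
        if not run:
            return
        if run_kind == "hyper":
            extreme = max(run, key=lambda r: r.value)
            kind = "hyperglycemia"
        else:
            extreme = min(run, key=lambda r: r.value)
            kind = "hypoglycemia"
        events.append(NoticeableEvent(
            kind=kind,
            start=run[0].timestamp,
            end=run[-1].timestamp,
            reference_time=extreme.timestamp,
            extreme_value=extreme.value,
            registrations=list(run),
        ))
        run, run_kind = [], None

    max_span = timedelta(hours=config.event_max_duration_hours)
    for r in ctx.by_type(DataType.BLOOD_GLUCOSE):
        state = _glycemic_state(r, ctx, config)
        if state == "in_range":
            close_run()
            continue
        if run and (state != run_kind or r.timestamp - run[0].timestamp > max_span):
            close_run()
        if not run:
            run_kind = state
        run.append(r)
    close_run()
    return events


# ---------------------------------------------------------------------------
# blood pressure and sleep


def detect_bp_events(ctx: CurrentContext, config: ThresholdConfig) -> List[NoticeableEvent]:
    """One event per reading exceeding 140 systolic or 90 diastolic (strict).

    Systolic and diastolic registrations sharing a timestamp are treated as
    one measurement; unpaired readings are judged on their own component.
    """
    by_time: Dict[datetime, Dict[str, Registration]] = {}
    for r in ctx.by_type(DataType.BLOOD_PRESSURE_SYSTOLIC):
        by_time.setdefault(r.timestamp, {})["sys"] = r
    for r in ctx.by_type(DataType.BLOOD_PRESSURE_DIASTOLIC):
        by_time.setdefault(r.timestamp, {})["dia"] = r

    events = []
    for ts in sorted(by_time):
        pair = by_time[ts]
        sys_r, dia_r = pair.get("sys"), pair.get("dia")
        high_sys = sys_r is not None and strictly_greater(sys_r.value, config.bp_systolic)
        high_dia = dia_r is not None and strictly_greater(dia_r.value, config.bp_diastolic)
        if high_sys or high_dia:
            extreme = sys_r.value if high_sys else dia_r.value  # type: ignore[union-attr]
            events.append(NoticeableEvent(
                kind="high_bp", start=ts, end=ts, reference_time=ts,
                extreme_value=extreme,
                registrations=[r for r in (sys_r, dia_r) if r is not None],
            ))
    return events


def detect_short_sleep(
    ctx: CurrentContext, config: ThresholdConfig
) -> Tuple[List[NoticeableEvent], List[HypothesisResult]]:
    """Per-night short-sleep detection from gaps between manual registrations.

    The night of day *d* spans ``night_start`` on *d* to ``night_end`` on
    *d+1*; the sleep gap is the interval between the consecutive manual
    registrations that brackets the night anchor (03:00).  Sensor-automatic
    registrations are ignored.  A night with no bracketing pair yields an NA
    result; a gap shorter than the recommended sleep duration yields an event
    with a TRUE result, otherwise FALSE.
    """
    manual = sorted(
        (r for r in ctx.registrations if r.manual), key=lambda r: r.timestamp
    )
    events: List[NoticeableEvent] = []
    results: List[HypothesisResult] = []
    dates = [d.date() for d in ctx.period_dates()]
    for night_date in dates[:-1] if len(dates) > 1 else []:
        anchor = datetime.combine(night_date + timedelta(days=1), config.night_anchor)
        gap: Optional[Tuple[datetime, datetime]] = None
        for a, b in zip(manual, manual[1:]):
            if a.timestamp <= anchor <= b.timestamp:
                gap = (a.timestamp, b.timestamp)
                break
        scope = f"night:{night_date.isoformat()}"
        if gap is None:
            results.append(HypothesisResult(
                hypothesis_id="short_sleep", scope=scope, state=State.NA,
                justification="no pair of manual registrations brackets the night",
            ))
            continue
        hours = (gap[1] - gap[0]).total_seconds() / 3600.0
        evidence = {"sleep_gap_hours": hours, "recommended_hours": config.sleep_min_hours}
        if strictly_less(hours, config.sleep_min_hours):
            ref = gap[0] + (gap[1] - gap[0]) / 2
            events.append(NoticeableEvent(
                kind="short_sleep", start=gap[0], end=gap[1],
                reference_time=ref, extreme_value=hours,
            ))
            results.append(HypothesisResult(
                hypothesis_id="short_sleep", scope=scope, state=State.TRUE,
                justification=f"longest overnight gap {hours:.1f} h is below the "
                              f"recommended {config.sleep_min_hours:.0f} h",
                numeric_evidence=evidence,
            ))
        else:
            results.append(HypothesisResult(
                hypothesis_id="short_sleep", scope=scope, state=State.FALSE,
                numeric_evidence=evidence,
            ))
    return events, results


# ---------------------------------------------------------------------------
# shared cause-rule helpers


def _isf_for(ctx: CurrentContext) -> Tuple[Optional[float], str]:
    """Patient-reported ISF, falling back to the 1500/1800 rule."""
    if ctx.profile.reported_isf is not None:
        return ctx.profile.reported_isf, "reported"
    return calc.calculated_isf(ctx), "1500/1800 rule"


def _icr_for(ctx: CurrentContext, on: date) -> Tuple[Optional[float], str]:
    """Reported I:C, then same-day totals, then the 500/450 rule."""
    if ctx.profile.reported_icr is not None:
        return ctx.profile.reported_icr, "reported"
    day = calc.daily_icr(ctx, on)
    if day is not None:
        return day, "same-day totals"
    return calc.calculated_icr(ctx), "500/450 rule"


def _result(hyp: str, event: NoticeableEvent, state: State,
            justification: str = "", evidence: Optional[Dict[str, float]] = None
            ) -> HypothesisResult:
    return HypothesisResult(
        hypothesis_id=hyp, scope=event.scope, state=state,
        justification=justification, numeric_evidence=evidence or {},
    )


def _na(hyp: str, event: NoticeableEvent, missing: str) -> HypothesisResult:
    return _result(hyp, event, State.NA, justification=f"missing context: {missing}")


def _last_bolus_before(ctx: CurrentContext, t: datetime,
                       within_hours: float = 24.0) -> Optional[Registration]:
    window = slice_window(ctx, DataType.INSULIN_BOLUS, t, timedelta(hours=within_hours))
    return window[-1] if window else None


def _iob_now(ctx: CurrentContext, t: datetime) -> float:
    cfg = ctx.config
    boluses = [(r.timestamp, r.value) for r in ctx.by_type(DataType.INSULIN_BOLUS)]
    return calc.iob_at(t, boluses, ctx.profile.dia, cfg.iob_curve, cfg.iob_peak_minutes)


def activity_intensity(r: Registration, config: ThresholdConfig) -> str:
    """'light_moderate' or 'extreme' for one activity registration.

    An explicit intensity tag wins; otherwise a quantity strictly below the
    light-moderate bound for its unit (60 min, 3000 steps, 6 METs) is
    light-to-moderate and anything at or above it is treated as extreme.
    """
    q = r.activity_quantity
    if q is None:
        return "light_moderate"
    if q.kind == "intensity":
        return "light_moderate" if q.tag in ("light", "moderate") else "extreme"
    bounds = {
        "minutes": config.activity_light_minutes,
        "steps": config.activity_light_steps,
        "mets": config.activity_light_mets,
    }
    amount = q.amount if q.amount is not None else 0.0
    return "light_moderate" if strictly_less(amount, bounds[q.kind]) else "extreme"


# ---------------------------------------------------------------------------
# hyperglycemia cause leaves


def rule_hyper_iob_below_average(event: NoticeableEvent, ctx: CurrentContext,
                                 config: ThresholdConfig) -> HypothesisResult:
    """Current active insulin lower than the period-average active insulin."""
    hyp = "hyper_iob_below_average"
    if not ctx.by_type(DataType.INSULIN_BOLUS):
        return _na(hyp, event, "insulin bolus registrations")
    current = _iob_now(ctx, event.reference_time)
    avg = calc.average_iob(ctx, config.iob_grid_minutes)
    if avg is None:
        return _na(hyp, event, "insulin registrations")
    state = State.TRUE if strictly_less(current, avg) else State.FALSE
    return _result(hyp, event, state,
                   justification=f"active insulin {current:.2f} U vs average {avg:.2f} U",
                   evidence={"current_iob": current, "average_iob": avg})


def rule_hyper_last_dose_insufficient(event: NoticeableEvent, ctx: CurrentContext,
                                      config: ThresholdConfig) -> HypothesisResult:
    """Last bolus below the dose needed to bring BG back to target via ISF."""
    hyp = "hyper_last_dose_insufficient"
    last = _last_bolus_before(ctx, event.reference_time)
    if last is None:
        return _na(hyp, event, "an insulin bolus before the event")
    isf, isf_src = _isf_for(ctx)
    if isf is None or isf <= 0:
        return _na(hyp, event, "insulin sensitivity factor")
    required = (event.extreme_value - config.bg_target) / isf
    state = State.TRUE if strictly_less(last.value, required) else State.FALSE
    return _result(
        hyp, event, state,
        justification=f"last dose {last.value:.1f} U vs {required:.1f} U required "
                      f"to reach {config.bg_target:.1f} mmol/L (ISF {isf:.2f}, {isf_src})",
        evidence={"last_dose": last.value, "required_dose": required, "isf": isf},
    )


def rule_hyper_icr_too_low(event: NoticeableEvent, ctx: CurrentContext,
                           config: ThresholdConfig) -> HypothesisResult:
    """Insulin given for the last pre-event intake did not cover its carbs."""
    hyp = "hyper_icr_too_low"
    intakes = slice_window(ctx, DataType.CARBOHYDRATES, event.reference_time,
                           timedelta(hours=config.meal_lookback_hours))
    if not intakes:
        return _na(hyp, event, "a carbohydrate intake in the meal lookback window")
    intake = intakes[-1]
    icr, icr_src = _icr_for(ctx, intake.timestamp.date())
    if icr is None or icr <= 0:
        return _na(hyp, event, "insulin-to-carbohydrate ratio")
    half = timedelta(minutes=config.insulin_meal_window_minutes)
    covering = [
        r.value for r in ctx.by_type(DataType.INSULIN_BOLUS)
        if intake.timestamp - half <= r.timestamp <= intake.timestamp + half
    ]
    given = sum(covering)
    required = intake.value / icr
    state = State.TRUE if strictly_less(given, required) else State.FALSE
    return _result(
        hyp, event, state,
        justification=f"{given:.1f} U given for {intake.value:.0f} g vs {required:.1f} U "
                      f"per I:C {icr:.1f} g/U ({icr_src})",
        evidence={"insulin_given": given, "insulin_required": required,
                  "carbs": intake.value, "icr": icr},
    )


def rule_hyper_no_insulin_for_meal(event: NoticeableEvent, ctx: CurrentContext,
                                   config: ThresholdConfig) -> HypothesisResult:
    """A pre-event meal had no bolus in the 30-minute window around it."""
    hyp = "hyper_no_insulin_for_meal"
    if not ctx.has_insulin():
        return _na(hyp, event, "insulin registrations")
    intakes = slice_window(ctx, DataType.CARBOHYDRATES, event.reference_time,
                           timedelta(hours=config.meal_lookback_hours))
    meals = [c for c in intakes if meal_or_snack(c.timestamp, ctx) == "meal"]
    if not meals:
        return _na(hyp, event, "a meal in the meal lookback window")
    half = timedelta(minutes=config.insulin_meal_window_minutes)
    uncovered = []
    for m in meals:
        has_bolus = any(
            m.timestamp - half <= r.timestamp <= m.timestamp + half
            for r in ctx.by_type(DataType.INSULIN_BOLUS)
        )
        if not has_bolus:
            uncovered.append(m)
    state = State.TRUE if uncovered else State.FALSE
    just = ""
    if uncovered:
        just = "no insulin within {:.0f} min of the meal at {}".format(
            config.insulin_meal_window_minutes, uncovered[0].timestamp.strftime("%H:%M"))
    return _result(hyp, event, state, justification=just,
                   evidence={"uncovered_meals": float(len(uncovered))})


def rule_hyper_cob_above_average(event: NoticeableEvent, ctx: CurrentContext,
                                 config: ThresholdConfig) -> HypothesisResult:
    """More carbohydrates on board than the period average."""
    hyp = "hyper_cob_above_average"
    rate = ctx.profile.carb_absorption_rate
    if rate is None:
        return _na(hyp, event, "carbohydrate absorption rate")
    intakes = [(r.timestamp, r.value) for r in ctx.by_type(DataType.CARBOHYDRATES)]
    current = calc.cob_at(event.reference_time, intakes, rate)
    avg = calc.average_cob(ctx, config.iob_grid_minutes)
    if current is None or avg is None:
        return _na(hyp, event, "carbohydrate registrations")
    state = State.TRUE if strictly_greater(current, avg) else State.FALSE
    return _result(hyp, event, state,
                   justification=f"carbs on board {current:.0f} g vs average {avg:.0f} g",
                   evidence={"current_cob": current, "average_cob": avg})


def rule_hyper_intake_above_recommendation(event: NoticeableEvent, ctx: CurrentContext,
                                           config: ThresholdConfig) -> HypothesisResult:
    """Last pre-event intake above 75 g for a meal / 30 g for a snack."""
    hyp = "hyper_intake_above_recommendation"
    if ctx.profile.low_carb_diet:
        return _na(hyp, event, "not applicable on a low-carb diet")
    intakes = slice_window(ctx, DataType.CARBOHYDRATES, event.reference_time,
                           timedelta(hours=config.meal_lookback_hours))
    if not intakes:
        return _na(hyp, event, "a carbohydrate intake in the meal lookback window")
    intake = intakes[-1]
    cls = meal_or_snack(intake.timestamp, ctx)
    bound = config.meal_carbs_high if cls == "meal" else config.snack_carbs_high
    state = State.TRUE if strictly_greater(intake.value, bound) else State.FALSE
    return _result(
        hyp, event, state,
        justification=f"last {cls} of {intake.value:.0f} g vs recommended at most {bound:.0f} g",
        evidence={"carbs": intake.value, "recommended_max": bound},
    )


def rule_external_factors(hyp: str):
    """Factory: external factor present on the calendar day of the event."""
    def _rule(event: NoticeableEvent, ctx: CurrentContext,
              config: ThresholdConfig) -> HypothesisResult:
        factors = ctx.by_type(DataType.EXTERNAL_FACTOR)
        if not factors:
            return _na(hyp, event, "external factor registrations")
        same_day = [r for r in factors if r.timestamp.date() == event.reference_time.date()]
        state = State.TRUE if same_day else State.FALSE
        just = ""
        if same_day:
            tags = sorted({r.factor_tag or "unspecified" for r in same_day})
            just = "external factor present: " + ", ".join(tags)
        return _result(hyp, event, state, justification=just,
                       evidence={"factors_on_day": float(len(same_day))})
    return _rule


rule_hyper_external_factors = rule_external_factors("hyper_external_factors")
rule_hypo_external_factors = rule_external_factors("hypo_external_factors")
rule_bp_external_factors = rule_external_factors("bp_external_factors")


def rule_hyper_no_physical_activity(event: NoticeableEvent, ctx: CurrentContext,
                                    config: ThresholdConfig) -> HypothesisResult:
    """No physical activity in the 24 h preceding the event."""
    hyp = "hyper_no_physical_activity"
    if not ctx.by_type(DataType.PHYSICAL_ACTIVITY):
        return _na(hyp, event, "physical activity registrations")
    window = slice_window(ctx, DataType.PHYSICAL_ACTIVITY, event.reference_time,
                          timedelta(hours=config.activity_lookback_extreme_hours))
    state = State.FALSE if window else State.TRUE
    just = "" if window else (
        f"no physical activity in the {config.activity_lookback_extreme_hours:.0f} h "
        "before the event")
    return _result(hyp, event, state, justification=just,
                   evidence={"activities_in_window": float(len(window))})


# ---------------------------------------------------------------------------
# hypoglycemia cause leaves


def rule_hypo_iob_above_average(event: NoticeableEvent, ctx: CurrentContext,
                                config: ThresholdConfig) -> HypothesisResult:
    """Current active insulin greater than the period average."""
    hyp = "hypo_iob_above_average"
    if not ctx.by_type(DataType.INSULIN_BOLUS):
        return _na(hyp, event, "insulin bolus registrations")
    current = _iob_now(ctx, event.reference_time)
    avg = calc.average_iob(ctx, config.iob_grid_minutes)
    if avg is None:
        return _na(hyp, event, "insulin registrations")
    state = State.TRUE if strictly_greater(current, avg) else State.FALSE
    return _result(hyp, event, state,
                   justification=f"active insulin {current:.2f} U vs average {avg:.2f} U",
                   evidence={"current_iob": current, "average_iob": avg})


def rule_hypo_last_dose_excessive(event: NoticeableEvent, ctx: CurrentContext,
                                  config: ThresholdConfig) -> HypothesisResult:
    """Last bolus above what the BG at injection time required via ISF.

    The requirement is judged against the most recent blood-glucose reading
    at or before the injection (what the patient could have known), floored
    at zero: any positive dose with BG already at or below target is excess.
    """
    hyp = "hypo_last_dose_excessive"
    last = _last_bolus_before(ctx, event.reference_time)
    if last is None:
        return _na(hyp, event, "an insulin bolus before the event")
    isf, isf_src = _isf_for(ctx)
    if isf is None or isf <= 0:
        return _na(hyp, event, "insulin sensitivity factor")
    bgs = [r for r in ctx.by_type(DataType.BLOOD_GLUCOSE) if r.timestamp <= last.timestamp]
    if not bgs:
        return _na(hyp, event, "a blood glucose reading before the last bolus")
    bg_then = bgs[-1].value
    required = max(0.0, (bg_then - config.bg_target) / isf)
    state = State.TRUE if strictly_greater(last.value, required) else State.FALSE
    return _result(
        hyp, event, state,
        justification=f"last dose {last.value:.1f} U vs {required:.1f} U required from "
                      f"BG {bg_then:.1f} mmol/L (ISF {isf:.2f}, {isf_src})",
        evidence={"last_dose": last.value, "required_dose": required,
                  "bg_at_dose": bg_then, "isf": isf},
    )


def rule_hypo_iob_above_icr_requirement(event: NoticeableEvent, ctx: CurrentContext,
                                        config: ThresholdConfig) -> HypothesisResult:
    """Active insulin exceeds what the recent carbohydrates warrant per I:C."""
    hyp = "hypo_iob_above_icr_requirement"
    if not ctx.by_type(DataType.INSULIN_BOLUS):
        return _na(hyp, event, "insulin bolus registrations")
    icr, icr_src = _icr_for(ctx, event.reference_time.date())
    if icr is None or icr <= 0:
        return _na(hyp, event, "insulin-to-carbohydrate ratio")
    carbs = sum(r.value for r in slice_window(
        ctx, DataType.CARBOHYDRATES, event.reference_time,
        timedelta(hours=config.meal_lookback_hours)))
    required = carbs / icr
    current = _iob_now(ctx, event.reference_time)
    state = State.TRUE if strictly_greater(current, required) else State.FALSE
    return _result(
        hyp, event, state,
        justification=f"active insulin {current:.2f} U vs {required:.2f} U covering "
                      f"{carbs:.0f} g per I:C {icr:.1f} g/U ({icr_src})",
        evidence={"current_iob": current, "required_iob": required,
                  "carbs_in_window": carbs, "icr": icr},
    )


def rule_hypo_no_carb_intake(event: NoticeableEvent, ctx: CurrentContext,
                             config: ThresholdConfig) -> HypothesisResult:
    """No carbohydrate intake up to 4 h prior to the event."""
    hyp = "hypo_no_carb_intake"
    if not ctx.by_type(DataType.CARBOHYDRATES):
        return _na(hyp, event, "carbohydrate registrations")
    intakes = slice_window(ctx, DataType.CARBOHYDRATES, event.reference_time,
                           timedelta(hours=config.meal_lookback_hours))
    state = State.FALSE if intakes else State.TRUE
    just = "" if intakes else (
        f"no carbohydrate intake in the {config.meal_lookback_hours:.0f} h before the event")
    return _result(hyp, event, state, justification=just,
                   evidence={"intakes_in_window": float(len(intakes))})


def rule_hypo_intake_below_recommendation(event: NoticeableEvent, ctx: CurrentContext,
                                          config: ThresholdConfig) -> HypothesisResult:
    """Last pre-event intake below 30 g for a meal / 15 g for a snack."""
    hyp = "hypo_intake_below_recommendation"
    if ctx.profile.low_carb_diet:
        return _na(hyp, event, "not applicable on a low-carb diet")
    intakes = slice_window(ctx, DataType.CARBOHYDRATES, event.reference_time,
                           timedelta(hours=config.meal_lookback_hours))
    if not intakes:
        return _na(hyp, event, "a carbohydrate intake in the meal lookback window")
    intake = intakes[-1]
    cls = meal_or_snack(intake.timestamp, ctx)
    bound = config.meal_carbs_low if cls == "meal" else config.snack_carbs_low
    state = State.TRUE if strictly_less(intake.value, bound) else State.FALSE
    return _result(
        hyp, event, state,
        justification=f"last {cls} of {intake.value:.0f} g vs recommended at least {bound:.0f} g",
        evidence={"carbs": intake.value, "recommended_min": bound},
    )


def rule_hypo_light_moderate_activity(event: NoticeableEvent, ctx: CurrentContext,
                                      config: ThresholdConfig) -> HypothesisResult:
    """Light-to-moderate activity within 4 h before the event."""
    hyp = "hypo_light_moderate_activity"
    if not ctx.by_type(DataType.PHYSICAL_ACTIVITY):
        return _na(hyp, event, "physical activity registrations")
    window = slice_window(ctx, DataType.PHYSICAL_ACTIVITY, event.reference_time,
                          timedelta(hours=config.activity_lookback_moderate_hours))
    hits = [r for r in window if activity_intensity(r, config) == "light_moderate"]
    state = State.TRUE if hits else State.FALSE
    just = ""
    if hits:
        just = (f"light-to-moderate activity at "
                f"{hits[-1].timestamp.strftime('%H:%M')} within "
                f"{config.activity_lookback_moderate_hours:.0f} h of the event")
    return _result(hyp, event, state, justification=just,
                   evidence={"matching_activities": float(len(hits))})


def rule_hypo_extreme_activity(event: NoticeableEvent, ctx: CurrentContext,
                               config: ThresholdConfig) -> HypothesisResult:
    """Extreme activity within 24 h before the event."""
    hyp = "hypo_extreme_activity"
    if not ctx.by_type(DataType.PHYSICAL_ACTIVITY):
        return _na(hyp, event, "physical activity registrations")
    window = slice_window(ctx, DataType.PHYSICAL_ACTIVITY, event.reference_time,
                          timedelta(hours=config.activity_lookback_extreme_hours))
    hits = [r for r in window if activity_intensity(r, config) == "extreme"]
    state = State.TRUE if hits else State.FALSE
    just = ""
    if hits:
        just = (f"extreme activity at {hits[-1].timestamp.strftime('%H:%M')} within "
                f"{config.activity_lookback_extreme_hours:.0f} h of the event")
    return _result(hyp, event, state, justification=just,
                   evidence={"matching_activities": float(len(hits))})
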