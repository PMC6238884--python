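"""Medical formula layer.

Implements the arithmetic the rules depend on: the Nathan linear
HbA1c/estimated-average-glucose translation, the 1500/1800 rule for insulin
sensitivity, the 500/450 rule for the insulin-to-carbohydrate ratio,
insulin-on-board and carbs-on-board decay models, and per-day totals.

Operations that cannot be computed from the available context return
``None`` rather than raising; the reasoning engine turns that signal into a
not-applicable (NA) hypothesis result.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import (
    MGDL_PER_MMOL,
    CurrentContext,
    DataType,
    Registration,
)

# Nathan linear relation: eAG [mg/dL] = 28.7 * A1C [%] - 46.7
NATHAN_SLOPE = 28.7
NATHAN_INTERCEPT = -46.7


def estimate_hba1c(bg_series: Sequence[float]) -> Optional[float]:
    """Estimated HbA1c (%) from self-measured blood glucose (mmol/L).

    Inverts the linear estimated-average-glucose relation
    ``eAG = 28.7 * A1C - 46.7`` (mg/dL), so
    ``A1C = (mean_BG * 18.016 + 46.7) / 28.7``.
    Returns None for an empty series.
    """
    values = list(bg_series)
    if not values:
        return None
    mean_mgdl = (sum(values) / len(values)) * MGDL_PER_MMOL
    return (mean_mgdl - NATHAN_INTERCEPT) / NATHAN_SLOPE


def eag_from_hba1c(a1c: float) -> float:
    """Forward Nathan relation: estimated average glucose in mmol/L."""
    return (NATHAN_SLOPE * a1c + NATHAN_INTERCEPT) / MGDL_PER_MMOL


def isf_rule(tdd: float, rapid_acting: bool = True) -> Optional[float]:
    """Insulin sensitivity factor via the 1500/1800 rule, in mmol/L per U.

    1800 for rapid-acting insulin, 1500 for regular; the mg/dL-per-U result
    is converted to canonical mmol/L per U.  None for non-positive TDD.
    """
    if tdd is None or tdd <= 0:
        return None
    numerator = 1800.0 if rapid_acting else 1500.0
    return (numerator / tdd) / MGDL_PER_MMOL


def icr_rule(tdd: float, rapid_acting: bool = True) -> Optional[float]:
    """Insulin-to-carbohydrate ratio via the 500/450 rule, in g per U."""
    if tdd is None or tdd <= 0:
        return None
    numerator = 500.0 if rapid_acting else 450.0
    return numerator / tdd


def _remaining_fraction(elapsed_h: float, dia_h: float, curve: str, peak_min: float) -> float:
    if elapsed_h <= 0:
        return 1.0
    if elapsed_h >= dia_h:
        return 0.0
    if curve == "linear":
        return 1.0 - elapsed_h / dia_h
    if curve == "bilinear":
        # Triangular activity profile peaking at `peak_min`; remaining
        # insulin is one minus the cumulative activity.  Monotone from 1 to 0.
        p = min(peak_min / 60.0, dia_h * 0.999)
        if elapsed_h <= p:
            absorbed = elapsed_h * elapsed_h / (p * dia_h)
        else:
            absorbed = 1.0 - (dia_h - elapsed_h) ** 2 / ((dia_h - p) * dia_h)
        return 1.0 - absorbed
    raise ValueError(f"unknown IOB curve: {curve!r}")


def iob_at(
    t: datetime,
    boluses: Iterable[Tuple[datetime, float]],
    dia: float,
    curve: str = "linear",
    peak_minutes: float = 75.0,
) -> float:
    """Insulin on board at time ``t`` (U).

    Sums, over past boluses, dose times the remaining fraction of its decay
    curve.  The fraction is 1 at injection, 0 at or beyond the duration of
    insulin action (DIA), and non-increasing in between; boluses after ``t``
    contribute nothing.
    """
    if dia <= 0:
        raise ValueError("dia must be positive")
    total = 0.0
    for when, dose in boluses:
        if dose < 0:
            raise ValueError("bolus doses must be non-negative")
        elapsed_h = (t - when).total_seconds() / 3600.0
        if elapsed_h < 0:
            continue
        total += dose * _remaining_fraction(elapsed_h, dia, curve, peak_minutes)
    return total


def cob_at(
    t: datetime,
    intakes: Iterable[Tuple[datetime, float]],
    absorption_rate: Optional[float],
) -> Optional[float]:
    """Carbohydrates on board at ``t`` (g): the unabsorbed remainder.

    Linear absorption at the patient-reported rate (g/h); None when no
    rate is available.
    """
    if absorption_rate is None:
        return None
    if absorption_rate <= 0:
        raise ValueError("absorption rate must be positive")
    total = 0.0
    for when, grams in intakes:
        elapsed_h = (t - when).total_seconds() / 3600.0
        if elapsed_h < 0:
            continue
        total += max(0.0, grams - absorption_rate * elapsed_h)
    return total


def _bolus_pairs(ctx: CurrentContext) -> List[Tuple[datetime, float]]:
    return [(r.timestamp, r.value) for r in ctx.by_type(DataType.INSULIN_BOLUS)]


def _carb_pairs(ctx: CurrentContext) -> List[Tuple[datetime, float]]:
    return [(r.timestamp, r.value) for r in ctx.by_type(DataType.CARBOHYDRATES)]


def _grid(ctx: CurrentContext, grid_minutes: int) -> List[datetime]:
    step = timedelta(minutes=grid_minutes)
    out = []
    t = ctx.period_start
    while t <= ctx.period_end:
        out.append(t)
        t += step
    return out or [ctx.period_start]


def average_iob(ctx: CurrentContext, grid_minutes: int = 5) -> Optional[float]:
    """Mean insulin on board sampled on a regular grid over the period."""
    if ctx.period_end < ctx.period_start:
        return None
    boluses = _bolus_pairs(ctx)
    cfg = ctx.config
    samples = [
        iob_at(t, boluses, ctx.profile.dia, cfg.iob_curve, cfg.iob_peak_minutes)
        for t in _grid(ctx, grid_minutes)
    ]
    return sum(samples) / len(samples)


def average_cob(ctx: CurrentContext, grid_minutes: int = 5) -> Optional[float]:
    """Mean carbs on board over the period; None without an absorption rate."""
    rate = ctx.profile.carb_absorption_rate
    if rate is None or ctx.period_end < ctx.period_start:
        return None
    intakes = _carb_pairs(ctx)
    samples = [cob_at(t, intakes, rate) for t in _grid(ctx, grid_minutes)]
    return sum(samples) / len(samples)  # type: ignore[arg-type]


@dataclass
class DailyTotals:
    """Per-calendar-day insulin and carbohydrate totals and record counts."""

    date: date
    total_rapid_insulin: float = 0.0
    total_basal_insulin: float = 0.0
    total_carbs: float = 0.0
    registration_counts: Dict[DataType, int] = field(default_factory=dict)


def daily_totals(ctx: CurrentContext) -> List[DailyTotals]:
    """One totals record per calendar day of the period, zero days included."""
    by_day: Dict[date, DailyTotals] = {
        d.date(): DailyTotals(date=d.date()) for d in ctx.period_dates()
    }
    for r in ctx.registrations:
        day = by_day.get(r.timestamp.date())
        if day is None:  # registration outside an explicitly set period
            continue
        day.registration_counts[r.data_type] = day.registration_counts.get(r.data_type, 0) + 1
        if r.data_type == DataType.INSULIN_BOLUS:
            day.total_rapid_insulin += r.value
        elif r.data_type == DataType.INSULIN_BASAL:
            day.total_basal_insulin += r.value
        elif r.data_type == DataType.CARBOHYDRATES:
            day.total_carbs += r.value
    return [by_day[k] for k in sorted(by_day)]


def mean_daily_insulin(ctx: CurrentContext, include_basal: bool = True) -> Optional[float]:
    """Average total daily insulin dose over days with any insulin registered."""
    totals = []
    for day in daily_totals(ctx):
        dose = day.total_rapid_insulin + (day.total_basal_insulin if include_basal else 0.0)
        if dose > 0:
            totals.append(dose)
    if not totals:
        return None
    return sum(totals) / len(totals)


def calculated_isf(ctx: CurrentContext) -> Optional[float]:
    """Module-calculated ISF (mmol/L per U) from mean TDD via 1500/1800."""
    tdd = mean_daily_insulin(ctx)
    if tdd is None:
        return None
    return isf_rule(tdd, ctx.config.isf_rapid_acting)


def calculated_icr(ctx: CurrentContext) -> Optional[float]:
    """Module-calculated I:C (g per U) from mean TDD via 500/450."""
    tdd = mean_daily_insulin(ctx)
    if tdd is None:
        return None
    return icr_rule(tdd, ctx.config.isf_rapid_acting)


def daily_icr(ctx: CurrentContext, on: date) -> Optional[float]:
    """Same-day I:C: total carbohydrates over total rapid-acting insulin."""
    for day in daily_totals(ctx):
        if day.date == on:
            if day.total_rapid_insulin > 0 and day.total_carbs > 0:
                return day.total_carbs / day.total_rapid_insulin
            return None
    return None
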