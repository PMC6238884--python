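"""Threshold flip-point sweeps: recover every printed rule constant end to end.

Each function here builds small diaries, runs the full consultation engine
on each, and locates the boundary at which a detector or reliability
sub-hypothesis flips.  Nothing reads the constants back from the
configuration: the reported numbers are the flip points actually observed,
so they double as an end-to-end check of the whole pipeline.
"""
from __future__ import annotations

from datetime import date, datetime, time, timedelta
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import calculators as calc
from .engine import RunResult, run
from .kb import KnowledgeBase, default_kb
from .model import (
    ActivityQuantity,
    DataType,
    LabContext,
    PatientProfile,
    Registration,
    State,
    build_context,
)
from .synth import ScenarioSpec, generate

D0 = date(2024, 3, 4)  # a Monday


def _run(registrations, profile, lab=None, kb: Optional[KnowledgeBase] = None) -> RunResult:
    kb = kb or default_kb()
    ctx = build_context(registrations, profile, lab, kb.config, allow_empty=True)
    return run(ctx, kb)


def _bg(d: date, t: time, v: float, manual: bool = True) -> Registration:
    return Registration(timestamp=datetime.combine(d, t),
                        data_type=DataType.BLOOD_GLUCOSE, value=v, manual=manual,
                        source="glucometer")


def _carb(d: date, t: time, g: float) -> Registration:
    return Registration(timestamp=datetime.combine(d, t),
                        data_type=DataType.CARBOHYDRATES, value=g, source="diary-app")


# ---------------------------------------------------------------------------


def compliant_diary(seed: int) -> Tuple[List[Registration], PatientProfile]:
    """The fully compliant 14-day diary (5 BG/day, all four types, no anomalies)."""
    diary = generate(ScenarioSpec(seed=seed))
    return diary.registrations, diary.profile


def hba1c_trust_drop(seed: int) -> Tuple[float, int]:
    """Trust difference between a matching and a 2-point-lower laboratory HbA1c."""
    regs, profile = compliant_diary(seed)
    bg = [r.value for r in regs if r.data_type == DataType.BLOOD_GLUCOSE]
    est = calc.estimate_hba1c(bg)
    assert est is not None
    matched = _run(regs, profile, LabContext(hba1c=est)).trust.trust_level
    lowered = _run(regs, profile, LabContext(hba1c=est - 2.0)).trust.trust_level
    return float(matched - lowered), len(regs)


def hba1c_tolerance_sweep(seed: int) -> Tuple[float, int]:
    """Largest relative lab deviation (percent, 0.1 steps) not flagged."""
    regs, profile = compliant_diary(seed)
    bg = [r.value for r in regs if r.data_type == DataType.BLOOD_GLUCOSE]
    est = calc.estimate_hba1c(bg)
    assert est is not None
    kb = default_kb()
    largest = 0.0
    steps = [round(0.1 * i, 1) for i in range(0, 101)]
    for pct in steps:
        lab = LabContext(hba1c=est / (1.0 + pct / 100.0))
        result = _run(regs, profile, lab, kb)
        r = result.result("source_inconsistency_hba1c")
        if r is not None and r.state == State.FALSE:
            largest = max(largest, pct)
    return largest, len(steps)


def hyper_threshold_sweep(seed: int) -> Tuple[float, int]:
    """Largest non-fasting BG (0.1 grid) producing zero hyperglycemia events."""
    profile = PatientProfile()
    values = [round(9.0 + 0.1 * i, 1) for i in range(0, 71)]
    largest = None
    for v in values:
        regs = [_carb(D0, time(12, 0), 50.0), _bg(D0, time(15, 0), v)]
        result = _run(regs, profile)
        if not any(e.kind == "hyperglycemia" for e in result.events):
            largest = v
    return float(largest), len(values)


def hypo_threshold_sweep(seed: int) -> Tuple[float, int]:
    """Smallest non-fasting BG (0.1 grid) producing zero hypoglycemia events."""
    profile = PatientProfile()
    values = [round(2.0 + 0.1 * i, 1) for i in range(0, 31)]
    smallest = None
    for v in values:
        regs = [_carb(D0, time(12, 0), 50.0), _bg(D0, time(15, 0), v)]
        result = _run(regs, profile)
        if not any(e.kind == "hypoglycemia" for e in result.events):
            smallest = v if smallest is None else min(smallest, v)
    return float(smallest), len(values)


def bp_threshold_sweep(seed: int) -> Tuple[float, int]:
    """Largest systolic (diastolic 80) producing zero high-BP events."""
    profile = PatientProfile()
    largest = None
    values = list(range(120, 161))
    for sys_v in values:
        ts = datetime.combine(D0, time(9, 0))
        regs = [
            Registration(timestamp=ts, data_type=DataType.BLOOD_PRESSURE_SYSTOLIC,
                         value=float(sys_v), source="bp-cuff"),
            Registration(timestamp=ts, data_type=DataType.BLOOD_PRESSURE_DIASTOLIC,
                         value=80.0, source="bp-cuff"),
        ]
        result = _run(regs, profile)
        if not any(e.kind == "high_bp" for e in result.events):
            largest = sys_v
    return float(largest), len(values)


def sleep_gap_sweep(seed: int) -> Tuple[float, int]:
    """Smallest overnight gap (hours, 0.5 steps) with no short-sleep event."""
    profile = PatientProfile()
    gaps = [4.0 + 0.5 * i for i in range(0, 13)]
    smallest = None
    for gap in gaps:
        bedtime = datetime.combine(D0, time(23, 0))
        wake = bedtime + timedelta(hours=gap)
        regs = [
            _bg(D0, time(8, 0), 6.0), _bg(D0, time(13, 0), 6.0),
            _bg(D0, time(18, 0), 6.0), _bg(D0, time(23, 0), 6.0),
            Registration(timestamp=wake, data_type=DataType.BLOOD_GLUCOSE,
                         value=6.0, source="glucometer"),
            Registration(timestamp=wake + timedelta(hours=5),
                         data_type=DataType.BLOOD_GLUCOSE, value=6.0,
                         source="glucometer"),
        ]
        result = _run(regs, profile)
        if not any(e.kind == "short_sleep" for e in result.events):
            smallest = gap if smallest is None else min(smallest, gap)
    return float(smallest), len(gaps)


def _counts_with_dispersion(target_pct: int, days: int = 14, mean: int = 10) -> List[int]:
    """Integer per-day counts whose std/mean best approximates target_pct %.

    Deviations come in +a/-a pairs so the mean stays exact; the sum of
    squared deviations closest to ``days * (target_pct * mean / 100)^2`` is
    realized greedily.
    """
    target_ssq = days * (target_pct * mean / 100.0) ** 2
    remaining = int(round(target_ssq / 2.0))  # per pair: 2*a^2 counts double
    deltas = []
    slots = days // 2
    while remaining > 0 and len(deltas) < slots:
        a = int(np.floor(np.sqrt(remaining)))
        a = min(a, mean)  # counts must stay non-negative
        if a == 0:
            break
        deltas.append(a)
        remaining -= a * a
    counts = [mean] * days
    for i, a in enumerate(deltas):
        counts[2 * i] += a
        counts[2 * i + 1] -= a
    return counts


def day_distribution_sweep(seed: int) -> Tuple[float, int]:
    """Largest per-day count dispersion (% of mean) not flagged as unequal."""
    profile = PatientProfile()
    kb = default_kb()
    largest = 0.0
    targets = list(range(0, 41))
    for pct in targets:
        counts = _counts_with_dispersion(pct)
        regs = []
        for day, n in enumerate(counts):
            d = D0 + timedelta(days=day)
            for i in range(n):
                minutes = 7 * 60 + int(i * (14 * 60) / max(1, n))
                regs.append(_bg(d, time(minutes // 60, minutes % 60), 6.0))
        arr = np.asarray(counts, dtype=float)
        measured = 100.0 * float(np.std(arr) / np.mean(arr))
        result = _run(regs, profile, kb=kb)
        r = result.result("unequal_days_distribution")
        if r is not None and r.state == State.FALSE:
            largest = max(largest, measured)
    return round(largest, 6), len(targets)


def isf_tolerance_sweep(seed: int) -> Tuple[float, int]:
    """Largest reported-ISF deviation (percent, 0.1 steps) not flagged."""
    diary = generate(ScenarioSpec(seed=seed, include_activity=False,
                                  include_meals=True))
    ctx = build_context(diary.registrations, diary.profile, allow_empty=True)
    calculated = calc.calculated_isf(ctx)
    assert calculated is not None
    largest = 0.0
    steps = [round(0.1 * i, 1) for i in range(0, 101)]
    for pct in steps:
        profile = diary.profile.model_copy(
            update={"reported_isf": calculated / (1.0 + pct / 100.0)})
        result = _run(diary.registrations, profile)
        r = result.result("source_inconsistency_isf")
        if r is not None and r.state == State.FALSE:
            largest = max(largest, pct)
    return largest, len(steps)


def registrations_per_day_sweep(seed: int) -> Tuple[float, int]:
    """Smallest BG count per day making not-enough-registrations FALSE."""
    profile = PatientProfile()
    smallest = None
    ks = list(range(1, 11))
    for k in ks:
        regs = []
        for day in range(7):
            d = D0 + timedelta(days=day)
            if k == 1:
                times = [time(12, 0)]
            else:
                times = []
                for i in range(k):
                    minutes = 7 * 60 + int(round(i * (14 * 60) / (k - 1)))
                    times.append(time(minutes // 60, minutes % 60))
            regs.extend(_bg(d, t, 6.0) for t in times)
        result = _run(regs, profile)
        r = result.result("not_enough_registrations")
        if r is not None and r.state == State.FALSE and smallest is None:
            smallest = k
    return float(smallest), len(ks)


def meal_carbs_sweep(seed: int) -> Tuple[float, int]:
    """Largest lunch intake (g) with the above-recommendation child FALSE."""
    profile = PatientProfile()
    largest = None
    grams = list(range(40, 121))
    for g in grams:
        regs = [_carb(D0, time(12, 0), float(g)), _bg(D0, time(14, 0), 15.0)]
        result = _run(regs, profile)
        events = [e for e in result.events if e.kind == "hyperglycemia"]
        assert len(events) == 1
        r = result.result("hyper_intake_above_recommendation", events[0].scope)
        if r is not None and r.state == State.FALSE:
            largest = g
    return float(largest), len(grams)


def steps_bound_sweep(seed: int) -> Tuple[float, int]:
    """Supremum of the step counts classified light-to-moderate before a hypo.

    The bound is strict (strictly fewer steps than the threshold counts as
    light-to-moderate), so the supremum of the TRUE region equals the
    smallest swept value evaluating FALSE.
    """
    profile = PatientProfile()
    sweep = list(range(1000, 5001, 50))
    smallest_false = None
    for steps in sweep:
        regs = [
            _bg(D0, time(9, 0), 6.0),
            Registration(timestamp=datetime.combine(D0, time(13, 0)),
                         data_type=DataType.PHYSICAL_ACTIVITY, value=float(steps),
                         activity_quantity=ActivityQuantity(kind="steps",
                                                            amount=float(steps)),
                         source="fitness-band"),
            _bg(D0, time(15, 0), 3.0),
        ]
        result = _run(regs, profile)
        events = [e for e in result.events if e.kind == "hypoglycemia"]
        assert len(events) == 1
        r = result.result("hypo_light_moderate_activity", events[0].scope)
        if r is not None and r.state == State.FALSE and smallest_false is None:
            smallest_false = steps
    return float(smallest_false), len(sweep)


#: target id -> callable(seed) -> (value, n)
TARGETS = {
    "t1": hba1c_trust_drop,
    "t3": hba1c_tolerance_sweep,
    "t4": hyper_threshold_sweep,
    "t5": hypo_threshold_sweep,
    "t6": bp_threshold_sweep,
    "t7": sleep_gap_sweep,
    "t8": day_distribution_sweep,
    "t9": isf_tolerance_sweep,
    "t10": registrations_per_day_sweep,
    "t11": meal_carbs_sweep,
    "t12": steps_bound_sweep,
}


def compute_all(seed: int) -> Dict[str, Dict[str, float]]:
    out: Dict[str, Dict[str, float]] = {}
    for target_id, fn in TARGETS.items():
        value, n = fn(seed)
        out[target_id] = {"value": value, "n": n}
    return out
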