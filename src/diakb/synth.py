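"""Seeded synthetic type 1 diabetes diary generator.

The generator emulates the registration behaviour the rules reason about —
regular self-measured glucose, carbohydrate intakes at mealtimes, per-meal
boluses, a nightly basal dose, daily light activity — and supports injecting
the error taxonomy of real self-collected data (forgotten registrations,
unit mistakes, fabricated values, conflicting reported parameters) together
with a machine-readable ground-truth log for recovery tests.

The glucose process is deliberately simple: a baseline with additive meal
excursions and Gaussian noise.  It is *not* a physiological simulator; it
exists to drive threshold rules, and its default parameters are chosen so
that the anomaly-free diary is fully compliant (trust 50, zero events).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .model import (
    ActivityQuantity,
    DataType,
    LabContext,
    PatientProfile,
    Registration,
)


class Anomaly(BaseModel):
    """One injectable data defect and where to inject it."""

    model_config = ConfigDict(frozen=True)

    kind: Literal[
        "missed_bolus", "fabricated_smoothing", "missing_day", "wrong_unit",
        "extreme_value", "hypo_injection", "hyper_injection", "source_conflict",
    ]
    day: int = 0
    clock: time = time(14, 0)
    meal_index: int = 0
    data_type: DataType = DataType.BLOOD_GLUCOSE
    value: float = 0.9          # extreme_value payload
    depth: float = 3.0          # hypo_injection BG, mmol/L
    height: float = 15.0        # hyper_injection BG, mmol/L
    offset: float = 0.2         # source_conflict relative ISF offset


#: Reliability / medical hypothesis each anomaly kind is expected to flip.
ANOMALY_TARGET: Dict[str, str] = {
    "missed_bolus": "hyper_no_insulin_for_meal",
    "fabricated_smoothing": "source_inconsistency_hba1c",
    "missing_day": "unequal_days_distribution",
    "wrong_unit": "error_values_blood_glucose",
    "extreme_value": "error_values_blood_glucose",
    "hypo_injection": "hypoglycemia",
    "hyper_injection": "hyperglycemia",
    "source_conflict": "source_inconsistency_isf",
}

_ERROR_FAMILY = {
    DataType.BLOOD_GLUCOSE: "error_values_blood_glucose",
    DataType.CARBOHYDRATES: "error_values_carbohydrates",
    DataType.INSULIN_BOLUS: "error_values_insulin",
    DataType.INSULIN_BASAL: "error_values_insulin",
}


def anomaly_target(a: "Anomaly") -> str:
    """The hypothesis an anomaly is expected to flip on the injected diary."""
    if a.kind == "extreme_value":
        return _ERROR_FAMILY.get(a.data_type, "error_values_blood_glucose")
    return ANOMALY_TARGET[a.kind]


class ScenarioSpec(BaseModel):
    """A reproducible diary plan: same (spec, seed) always yields the same diary."""

    model_config = ConfigDict(frozen=True)

    days: int = 14
    start: date = date(2024, 3, 4)  # a Monday; 14 days cover each weekday twice
    bg_per_day: int = 5
    bg_first: time = time(7, 0)
    bg_last: time = time(21, 0)
    bg_baseline: float = 6.0
    bg_noise_sd: float = 0.3
    meal_excursion: float = 2.0
    excursion_hours: float = 3.0
    jitter_minutes: int = 0
    meals: Tuple[Tuple[time, float], ...] = (
        (time(7, 30), 40.0), (time(12, 0), 60.0), (time(18, 30), 60.0))
    bolus_doses: Tuple[float, ...] = (4.0, 6.0, 6.0)
    basal_dose: float = 20.0
    basal_time: time = time(22, 0)
    activity_time: time = time(16, 0)
    activity_minutes: float = 30.0
    include_meals: bool = True
    include_insulin: bool = True
    include_activity: bool = True
    anomalies: Tuple[Anomaly, ...] = ()
    seed: int = 0


@dataclass
class GroundTruth:
    """What was injected, for recovery tests."""

    injected_events: List[Tuple[str, datetime]] = field(default_factory=list)
    expected_hypotheses: List[str] = field(default_factory=list)


@dataclass
class GeneratedDiary:
    registrations: List[Registration]
    profile: PatientProfile
    ground_truth: GroundTruth


class ScenarioError(ValueError):
    """Contradictory scenario (e.g. an injection on a removed day)."""


def default_profile() -> PatientProfile:
    return PatientProfile(carb_absorption_rate=30.0, dia=4.0)


def _bg_times(spec: ScenarioSpec) -> List[time]:
    if spec.bg_per_day == 1:
        return [time(12, 0)]
    first = spec.bg_first.hour * 60 + spec.bg_first.minute
    last = spec.bg_last.hour * 60 + spec.bg_last.minute
    step = (last - first) / (spec.bg_per_day - 1)
    out = []
    for i in range(spec.bg_per_day):
        minutes = int(round(first + i * step))
        out.append(time(minutes // 60, minutes % 60))
    return out


def generate(spec: ScenarioSpec, profile: Optional[PatientProfile] = None) -> GeneratedDiary:
    """Produce the diary, the (possibly adjusted) profile and a ground-truth log."""
    profile = (profile or default_profile()).model_copy(deep=True)
    rng = np.random.default_rng(spec.seed)
    truth = GroundTruth()

    smoothing = any(a.kind == "fabricated_smoothing" for a in spec.anomalies)
    missing_days = {a.day for a in spec.anomalies if a.kind == "missing_day"}
    for a in spec.anomalies:
        if a.kind in ("hypo_injection", "hyper_injection", "extreme_value") \
                and a.day in missing_days:
            raise ScenarioError(
                f"anomaly {a.kind} on day {a.day} contradicts missing_day({a.day})")

    missed = {(a.day, a.meal_index) for a in spec.anomalies if a.kind == "missed_bolus"}
    wrong_unit_days = {a.day for a in spec.anomalies if a.kind == "wrong_unit"}

    def jitter() -> timedelta:
        if spec.jitter_minutes <= 0:
            return timedelta(0)
        return timedelta(minutes=int(rng.integers(-spec.jitter_minutes,
                                                  spec.jitter_minutes + 1)))

    regs: List[Registration] = []
    bg_times = _bg_times(spec)
    for day in range(spec.days):
        d = spec.start + timedelta(days=day)
        if day in missing_days:
            continue
        for t in bg_times:
            ts = datetime.combine(d, t) + jitter()
            value = spec.bg_baseline
            if not smoothing:
                for meal_t, _ in (spec.meals if spec.include_meals else ()):
                    delta_h = (datetime.combine(d, t)
                               - datetime.combine(d, meal_t)).total_seconds() / 3600.0
                    if 0 <= delta_h <= spec.excursion_hours:
                        value += spec.meal_excursion
                value += float(rng.normal(0.0, spec.bg_noise_sd))
            value = round(value, 1)
            if day in wrong_unit_days:
                regs.append(Registration(
                    timestamp=ts, data_type=DataType.BLOOD_GLUCOSE,
                    value=round(value * 18.016, 1), source="mgdl-meter"))
            else:
                regs.append(Registration(
                    timestamp=ts, data_type=DataType.BLOOD_GLUCOSE, value=value,
                    source="glucometer"))
        if spec.include_meals:
            for i, (meal_t, grams) in enumerate(spec.meals):
                regs.append(Registration(
                    timestamp=datetime.combine(d, meal_t) + jitter(),
                    data_type=DataType.CARBOHYDRATES, value=grams, source="diary-app"))
                if spec.include_insulin and (day, i) not in missed:
                    dose = spec.bolus_doses[i % len(spec.bolus_doses)]
                    regs.append(Registration(
                        timestamp=datetime.combine(d, meal_t) + jitter(),
                        data_type=DataType.INSULIN_BOLUS, value=dose, source="pen"))
        if spec.include_insulin:
            regs.append(Registration(
                timestamp=datetime.combine(d, spec.basal_time),
                data_type=DataType.INSULIN_BASAL, value=spec.basal_dose, source="pen"))
        if spec.include_activity:
            regs.append(Registration(
                timestamp=datetime.combine(d, spec.activity_time),
                data_type=DataType.PHYSICAL_ACTIVITY, value=spec.activity_minutes,
                activity_quantity=ActivityQuantity(kind="minutes",
                                                   amount=spec.activity_minutes),
                source="fitness-band", manual=False))

    # point injections
    for a in spec.anomalies:
        d = spec.start + timedelta(days=a.day)
        ts = datetime.combine(d, a.clock)
        if a.kind == "hypo_injection":
            regs.append(Registration(timestamp=ts, data_type=DataType.BLOOD_GLUCOSE,
                                     value=a.depth, source="glucometer"))
            truth.injected_events.append(("hypoglycemia", ts))
        elif a.kind == "hyper_injection":
            regs.append(Registration(timestamp=ts, data_type=DataType.BLOOD_GLUCOSE,
                                     value=a.height, source="glucometer"))
            truth.injected_events.append(("hyperglycemia", ts))
        elif a.kind == "extreme_value":
            regs.append(Registration(timestamp=ts, data_type=a.data_type,
                                     value=a.value, source="glucometer"))
        truth.expected_hypotheses.append(anomaly_target(a))

    # conflicting reported ISF: offset relative to the module's own calculation
    conflict = [a for a in spec.anomalies if a.kind == "source_conflict"]
    if conflict:
        from . import calculators as calc
        from .model import build_context
        ctx = build_context(regs, profile, allow_empty=True)
        calculated = calc.calculated_isf(ctx)
        if calculated is not None:
            profile.reported_isf = calculated * (1.0 + conflict[-1].offset)

    regs.sort(key=lambda r: (r.timestamp, r.data_type.value, r.source))
    return GeneratedDiary(registrations=regs, profile=profile, ground_truth=truth)


# ---------------------------------------------------------------------------
# golden fixtures


@dataclass
class GoldenFixture:
    name: str
    description: str
    registrations: List[Registration]
    profile: PatientProfile
    lab: LabContext


def _bg(d: date, t: time, v: float, manual: bool = True) -> Registration:
    return Registration(timestamp=datetime.combine(d, t),
                        data_type=DataType.BLOOD_GLUCOSE, value=v,
                        source="glucometer", manual=manual)


def _carb(d: date, t: time, g: float) -> Registration:
    return Registration(timestamp=datetime.combine(d, t),
                        data_type=DataType.CARBOHYDRATES, value=g, source="diary-app")


def _bolus(d: date, t: time, u: float) -> Registration:
    return Registration(timestamp=datetime.combine(d, t),
                        data_type=DataType.INSULIN_BOLUS, value=u, source="pen")


def golden_fixtures() -> Dict[str, GoldenFixture]:
    """Hand-sized diaries exercising each hypothesis family.

    All are built programmatically and deterministically; the CLI can write
    any of them to disk (``diakb generate --fixture NAME``).
    """
    from . import calculators as calc

    fixtures: Dict[str, GoldenFixture] = {}
    d1, d2, d3 = date(2024, 3, 4), date(2024, 3, 5), date(2024, 3, 6)

    fixtures["empty"] = GoldenFixture(
        "empty", "zero registrations: reliability family degrades to NA/TRUE",
        [], default_profile(), LabContext())

    regs = []
    for d in (d1, d2):
        for t in (time(7), time(10), time(13), time(17), time(21)):
            regs.append(_bg(d, t, 6.0))
    regs.append(_bg(d2, time(14), 3.0))
    fixtures["gap_case"] = GoldenFixture(
        "gap_case",
        "hypoglycemic event with no insulin/carb/activity context: every cause "
        "branch is NA, so lack-of-evidence flags an information gap",
        regs, PatientProfile(), LabContext())

    regs = []
    for d in (d1, d2):
        for t in (time(7), time(10), time(13), time(17), time(21)):
            regs.append(_bg(d, t, 6.0))
        for t, g, u in ((time(7, 30), 40, 4), (time(12), 60, 6), (time(18, 30), 60, 6)):
            regs.append(_carb(d, t, g))
            regs.append(_bolus(d, t, u))
        regs.append(Registration(timestamp=datetime.combine(d, time(22)),
                                 data_type=DataType.INSULIN_BASAL, value=20.0,
                                 source="pen"))
        regs.append(Registration(
            timestamp=datetime.combine(d, time(16)),
            data_type=DataType.PHYSICAL_ACTIVITY, value=30.0,
            activity_quantity=ActivityQuantity(kind="minutes", amount=30.0),
            source="fitness-band"))
    est = calc.estimate_hba1c([6.0]) or 5.0
    fixtures["hba1c_mismatch"] = GoldenFixture(
        "hba1c_mismatch",
        "compliant two-day diary whose laboratory HbA1c deviates >5% from the "
        "estimate: trust drops by exactly the 10-point HbA1c grade",
        regs, default_profile(), LabContext(hba1c=round(est * 1.2, 2)))

    regs = [
        _bg(d1, time(8), 6.0),
        _carb(d1, time(12), 60.0),
        _bolus(d1, time(12), 2.0),
        _bg(d1, time(14), 15.0),
        _bg(d1, time(17), 7.0),
    ]
    fixtures["hyper_simple"] = GoldenFixture(
        "hyper_simple",
        "single hyperglycemic event with an undersized meal bolus",
        regs, PatientProfile(reported_isf=2.0, reported_icr=10.0,
                             carb_absorption_rate=30.0), LabContext())

    regs = [
        _bg(d1, time(8), 6.0),
        _carb(d1, time(7, 45), 40.0),
        _bolus(d1, time(7, 45), 4.0),
        Registration(timestamp=datetime.combine(d1, time(13)),
                     data_type=DataType.PHYSICAL_ACTIVITY, value=2500.0,
                     activity_quantity=ActivityQuantity(kind="steps", amount=2500.0),
                     source="fitness-band"),
        _bg(d1, time(15), 3.0),
    ]
    fixtures["hypo_activity"] = GoldenFixture(
        "hypo_activity",
        "hypoglycemic event preceded by light-to-moderate activity",
        regs, default_profile(), LabContext())

    regs = [
        _bg(d1, time(8), 6.0),
        Registration(timestamp=datetime.combine(d1, time(10)),
                     data_type=DataType.BLOOD_PRESSURE_SYSTOLIC, value=150.0,
                     source="bp-cuff"),
        Registration(timestamp=datetime.combine(d1, time(10)),
                     data_type=DataType.BLOOD_PRESSURE_DIASTOLIC, value=95.0,
                     source="bp-cuff"),
        Registration(timestamp=datetime.combine(d1, time(9)),
                     data_type=DataType.EXTERNAL_FACTOR, factor_tag="sickness",
                     source="diary-app"),
    ]
    fixtures["high_bp"] = GoldenFixture(
        "high_bp", "high blood pressure reading with a same-day external factor",
        regs, PatientProfile(), LabContext())

    regs = []
    for t in (time(8), time(12), time(18), time(23, 30)):
        regs.append(_bg(d1, t, 6.0))
    for t in (time(6), time(12), time(18)):
        regs.append(_bg(d2, t, 6.0))
    fixtures["short_sleep"] = GoldenFixture(
        "short_sleep",
        "manual registrations 23:30 to 06:00: a 6.5 h night, below 7 h",
        regs, PatientProfile(), LabContext())

    regs = [_bg(d1, time(8), 6.0), _bg(d1, time(12), 0.9), _bg(d1, time(18), 6.5)]
    fixtures["error_values"] = GoldenFixture(
        "error_values", "blood glucose of 0.9 mmol/L: below the plausible range",
        regs, PatientProfile(), LabContext())

    regs = []
    for d, n in ((d1, 10), (d2, 2), (d3, 6)):
        for i in range(n):
            minutes = 7 * 60 + i * 90
            regs.append(_bg(d, time(minutes // 60, minutes % 60), 6.0))
    fixtures["unequal_days"] = GoldenFixture(
        "unequal_days",
        "per-day counts 10/2/6: dispersion far beyond 20% of the mean",
        regs, PatientProfile(), LabContext())

    return fixtures
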