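"""Core domain model: registrations, patient profile, thresholds and the current context.

The *current context* is the complete, in-memory picture of one consultation:
the patient's time-stamped diary registrations, their profile parameters,
any laboratory values, and the hypothesis results the reasoning engine
accumulates while it runs.  All rule modules operate on this object.

Canonical internal units: mmol/L for glucose, U for insulin, g for
carbohydrates, mmHg for blood pressure, kg for weight.  Timestamps are
timezone-naive local clock time at minute resolution — a diary is a single
patient's local log and no timezone arithmetic is ever warranted.
"""
from __future__ import annotations

import logging
import math
from datetime import datetime, time, timedelta
from enum import Enum
from typing import Dict, List, Literal, Optional, Sequence, Tuple

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

logger = logging.getLogger(__name__)

#: mg/dL per mmol/L for glucose (molar mass of glucose / 10).
MGDL_PER_MMOL = 18.016


class DataType(str, Enum):
    """Kinds of registration a diary may contain."""

    BLOOD_GLUCOSE = "blood_glucose"
    INSULIN_BOLUS = "insulin_bolus"
    INSULIN_BASAL = "insulin_basal"
    CARBOHYDRATES = "carbohydrates"
    PHYSICAL_ACTIVITY = "physical_activity"
    BLOOD_PRESSURE_SYSTOLIC = "blood_pressure_systolic"
    BLOOD_PRESSURE_DIASTOLIC = "blood_pressure_diastolic"
    WEIGHT = "weight"
    EXTERNAL_FACTOR = "external_factor"


class State(str, Enum):
    """Outcome of testing a hypothesis.

    ``NA`` (not applicable) means the context required to test the claim is
    missing — the claim is neither validated nor refuted.
    """

    TRUE = "TRUE"
    FALSE = "FALSE"
    NA = "NA"


class ActivityQuantity(BaseModel):
    """How a physical-activity registration is quantified.

    ``kind`` selects the unit; for ``intensity`` the magnitude is the
    categorical ``tag`` (light / moderate / extreme) and ``amount`` is unused.
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["minutes", "steps", "mets", "intensity"]
    amount: Optional[float] = None
    tag: Optional[Literal["light", "moderate", "extreme"]] = None

    @model_validator(mode="after")
    def _check_fields(self) -> "ActivityQuantity":
        if self.kind == "intensity":
            if self.tag is None:
                raise ValueError("intensity quantity requires a tag")
        else:
            if self.amount is None or not math.isfinite(self.amount) or self.amount < 0:
                raise ValueError(f"{self.kind} quantity requires a finite non-negative amount")
        return self


class Registration(BaseModel):
    """One time-stamped, typed measurement with its source.

    ``value`` is in canonical units for the data type (mmol/L, U, g, mmHg,
    kg); for physical activity the magnitude lives in ``activity_quantity``
    and ``value`` mirrors its numeric amount (0 for tag-only registrations).
    """

    model_config = ConfigDict(frozen=True)

    timestamp: datetime
    data_type: DataType
    value: float = 0.0
    activity_quantity: Optional[ActivityQuantity] = None
    factor_tag: Optional[str] = None
    source: str = "manual-entry"
    manual: bool = True

    @field_validator("timestamp")
    @classmethod
    def _minute_resolution(cls, v: datetime) -> datetime:
        if v.tzinfo is not None:
            raise ValueError("timestamps are timezone-naive local clock time")
        return v.replace(second=0, microsecond=0)

    @field_validator("value")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("registration value must be finite")
        return v

    @model_validator(mode="after")
    def _check_optionals(self) -> "Registration":
        if self.activity_quantity is not None and self.data_type != DataType.PHYSICAL_ACTIVITY:
            raise ValueError("activity_quantity only valid for physical_activity registrations")
        if self.factor_tag is not None and self.data_type != DataType.EXTERNAL_FACTOR:
            raise ValueError("factor_tag only valid for external_factor registrations")
        return self


#: Default mealtime windows (clock time, inclusive bounds).  Lunch 11:00-13:00
#: is the convention the knowledge base was co-designed around; breakfast and
#: dinner are module defaults.  Patients can override all of them.
DEFAULT_MEALTIMES: Dict[str, Tuple[time, time]] = {
    "breakfast": (time(6, 0), time(10, 0)),
    "lunch": (time(11, 0), time(13, 0)),
    "dinner": (time(17, 0), time(20, 0)),
}


class PatientProfile(BaseModel):
    """Per-patient parameters feeding the rules.

    ``reported_isf`` is in mmol/L per U, ``reported_icr`` in g per U,
    ``carb_absorption_rate`` in g per hour, ``dia`` (duration of insulin
    action) in hours.
    """

    diabetes_type: Literal[1, 2] = 1
    uses_insulin: bool = True
    age: Optional[float] = None
    sex: Optional[str] = None
    reported_isf: Optional[float] = None
    reported_icr: Optional[float] = None
    carb_absorption_rate: Optional[float] = None
    low_carb_diet: bool = False
    mealtime_windows: Dict[str, Tuple[time, time]] = Field(
        default_factory=lambda: dict(DEFAULT_MEALTIMES)
    )
    dia: float = 4.0

    @field_validator("dia")
    @classmethod
    def _dia_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("dia must be positive")
        return v

    @model_validator(mode="after")
    def _windows_disjoint(self) -> "PatientProfile":
        spans = sorted(self.mealtime_windows.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("mealtime windows must not overlap")
        for s, e in spans:
            if e <= s:
                raise ValueError("mealtime window end must be after its start")
        return self


class LabContext(BaseModel):
    """Laboratory-generated context: the HbA1c determined by a lab test."""

    hba1c: Optional[float] = None
    hba1c_date: Optional[datetime] = None

    @field_validator("hba1c")
    @classmethod
    def _plausible(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not (3.0 < v < 20.0):
            raise ValueError("laboratory HbA1c must lie in (3, 20) percent")
        return v


class ThresholdConfig(BaseModel):
    """Every numeric constant of the knowledge base, with its default value.

    Glycemic thresholds are strict bounds (a reading must *exceed* 13.9
    mmol/L, fall *below* 3.5 mmol/L, ...).  Tolerances are fractions in
    [0, 1].  The grade table maps reliability hypothesis identifiers to the
    number of trust points deducted when that hypothesis is TRUE; only the
    10-point HbA1c deduction is fixed by the underlying guideline material,
    the others are module defaults surfaced here precisely so they can be
    re-weighted without touching code.
    """

    hyper_fasting: float = 9.0
    hyper_other: float = 13.9
    hypo_fasting: float = 4.0
    hypo_other: float = 3.5
    event_max_duration_hours: float = 6.0
    bg_target: float = 5.5
    meal_lookback_hours: float = 4.0
    insulin_meal_window_minutes: float = 30.0
    fasting_carb_free_hours: float = 8.0
    activity_lookback_moderate_hours: float = 4.0
    activity_lookback_extreme_hours: float = 24.0
    activity_light_minutes: float = 60.0
    activity_light_steps: float = 3000.0
    activity_light_mets: float = 6.0
    meal_carbs_high: float = 75.0
    snack_carbs_high: float = 30.0
    meal_carbs_low: float = 30.0
    snack_carbs_low: float = 15.0
    bp_systolic: float = 140.0
    bp_diastolic: float = 90.0
    sleep_min_hours: float = 7.0
    night_start: time = time(20, 0)
    night_end: time = time(12, 0)
    night_anchor: time = time(3, 0)
    min_bg_per_day: int = 5
    min_insulin_per_day: int = 1
    min_carbs_per_day: int = 1
    min_activity_per_day: int = 0
    distribution_tolerance: float = 0.20
    dispersion_statistic: Literal["std", "max_abs_dev"] = "std"
    source_tolerance: float = 0.05
    hba1c_tolerance: float = 0.05
    trust_max: int = 50
    grades: Dict[str, int] = Field(default_factory=lambda: dict(DEFAULT_GRADES))
    bg_plausible_range: Tuple[float, float] = (1.1, 33.3)
    carbs_plausible_range: Tuple[float, float] = (0.0, 300.0)
    insulin_plausible_range: Tuple[float, float] = (0.0, 100.0)
    mgdl_per_mmol: float = MGDL_PER_MMOL
    dia_default_hours: float = 4.0
    iob_curve: Literal["linear", "bilinear"] = "linear"
    iob_peak_minutes: float = 75.0
    isf_rapid_acting: bool = True
    iob_grid_minutes: int = 5

    @model_validator(mode="after")
    def _check(self) -> "ThresholdConfig":
        for name in ("distribution_tolerance", "source_tolerance", "hba1c_tolerance"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "hyper_fasting", "hyper_other", "hypo_fasting", "hypo_other",
            "event_max_duration_hours", "bg_target", "meal_lookback_hours",
            "insulin_meal_window_minutes", "fasting_carb_free_hours",
            "activity_lookback_moderate_hours", "activity_lookback_extreme_hours",
            "activity_light_minutes", "activity_light_steps", "activity_light_mets",
            "meal_carbs_high", "snack_carbs_high", "meal_carbs_low", "snack_carbs_low",
            "bp_systolic", "bp_diastolic", "sleep_min_hours", "mgdl_per_mmol",
            "dia_default_hours", "iob_peak_minutes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for hyp, g in self.grades.items():
            if not (0 <= g <= self.trust_max):
                raise ValueError(f"grade for {hyp} must lie in [0, {self.trust_max}]")
        return self


#: Trust-point deductions per reliability sub-hypothesis.  The HbA1c
#: source-inconsistency deduction of 10 points is the anchored value; the
#: remaining weights are module defaults chosen so that the all-violations
#: worst case still reaches the bottom of the 0-50 scale.
DEFAULT_GRADES: Dict[str, int] = {
    "no_blood_glucose_registered": 5,
    "no_carbohydrates_registered": 5,
    "no_insulin_registered": 5,
    "no_physical_activity_registered": 5,
    "error_values_blood_glucose": 10,
    "error_values_carbohydrates": 10,
    "error_values_insulin": 10,
    "not_enough_registrations": 5,
    "unequal_days_distribution": 5,
    "unequal_weekdays_distribution": 5,
    "source_inconsistency_hba1c": 10,
    "source_inconsistency_isf": 10,
    "source_inconsistency_icr": 10,
}


class HypothesisResult(BaseModel):
    """A tested claim: identifier, scope, outcome and supporting numbers."""

    hypothesis_id: str
    scope: str = "dataset"
    state: State
    justification: str = ""
    numeric_evidence: Dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _na_needs_reason(self) -> "HypothesisResult":
        if self.state == State.NA and not self.justification:
            raise ValueError("NA results must name the missing context")
        return self


class CurrentContext:
    """The dynamic context of one consultation run.

    Registrations are kept sorted by timestamp; ``system_generated`` grows
    as the reasoning engine stores hypothesis results.
    """

    def __init__(
        self,
        registrations: Sequence[Registration],
        profile: PatientProfile,
        lab: Optional[LabContext] = None,
        config: Optional[ThresholdConfig] = None,
        period: Optional[Tuple[datetime, datetime]] = None,
    ) -> None:
        self.registrations: List[Registration] = list(registrations)
        self.profile = profile
        self.lab = lab if lab is not None else LabContext()
        self.config = config if config is not None else ThresholdConfig()
        if period is not None:
            self.period_start, self.period_end = period
        elif self.registrations:
            self.period_start = min(r.timestamp for r in self.registrations)
            self.period_end = max(r.timestamp for r in self.registrations)
        else:
            self.period_start = self.period_end = datetime(1970, 1, 1)
        self.system_generated: List[HypothesisResult] = []
        self._by_type: Dict[DataType, List[Registration]] = {}
        for r in self.registrations:
            self._by_type.setdefault(r.data_type, []).append(r)

    def by_type(self, data_type: DataType) -> List[Registration]:
        """All registrations of one type, in timestamp order."""
        return self._by_type.get(data_type, [])

    def has_type(self, data_type: DataType) -> bool:
        return bool(self._by_type.get(data_type))

    def has_insulin(self) -> bool:
        return self.has_type(DataType.INSULIN_BOLUS) or self.has_type(DataType.INSULIN_BASAL)

    def period_dates(self) -> List[datetime]:
        """Every calendar day of the period, as midnight datetimes."""
        start = self.period_start.date()
        end = self.period_end.date()
        n = (end - start).days + 1
        return [datetime.combine(start, time()) + timedelta(days=i) for i in range(n)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CurrentContext):
            return NotImplemented
        return (
            self.registrations == other.registrations
            and self.profile == other.profile
            and self.lab == other.lab
            and self.period_start == other.period_start
            and self.period_end == other.period_end
        )


class ContextError(ValueError):
    """Raised when a context cannot be built from the supplied records."""


def build_context(
    registrations: Sequence[Registration],
    profile: PatientProfile,
    lab: Optional[LabContext] = None,
    config: Optional[ThresholdConfig] = None,
    allow_empty: bool = False,
) -> CurrentContext:
    """Instantiate the current context from raw registrations.

    Sorts by timestamp, computes the period bounds from the min/max
    timestamps, and collapses duplicate ``(timestamp, data_type, source)``
    entries to a single registration with a logged warning (real exports
    contain re-syncs; erroring on them would block every consultation).

    Raises :class:`ContextError` for an empty collection unless
    ``allow_empty`` is set.  Non-finite values and unknown data types are
    rejected by :class:`Registration` validation before this point; when raw
    mappings are passed they are validated here and the offending record
    index is reported.
    """
    records: List[Registration] = []
    for i, r in enumerate(registrations):
        if isinstance(r, Registration):
            records.append(r)
        else:
            try:
                records.append(Registration.model_validate(r))
            except Exception as exc:
                raise ContextError(f"invalid registration at index {i}: {exc}") from exc
    if not records and not allow_empty:
        raise ContextError("no registrations supplied (pass allow_empty=True to permit)")

    records.sort(key=lambda r: (r.timestamp, r.data_type.value, r.source))
    seen = set()
    unique: List[Registration] = []
    for r in records:
        key = (r.timestamp, r.data_type, r.source)
        if key in seen:
            logger.warning(
                "duplicate registration collapsed: %s %s from %s",
                r.timestamp.isoformat(), r.data_type.value, r.source,
            )
            continue
        seen.add(key)
        unique.append(r)
    return CurrentContext(unique, profile, lab, config)


def slice_window(
    ctx: CurrentContext,
    data_type: DataType,
    end: datetime,
    lookback: timedelta,
) -> List[Registration]:
    """Registrations of ``data_type`` with ``end - lookback < t <= end``.

    Windows are half-open on the old side everywhere in the knowledge base:
    a registration exactly the lookback before ``end`` is excluded.
    """
    if lookback <= timedelta(0):
        raise ValueError("lookback must be positive")
    start = end - lookback
    return [r for r in ctx.by_type(data_type) if start < r.timestamp <= end]


def strictly_greater(value: float, bound: float) -> bool:
    """``value > bound`` with an exact-tie guard.

    A quantity constructed to sit exactly on a printed threshold (for
    example a relative deviation of exactly 5%) must not flip the strict
    comparison through floating-point round-off, so near-equality at
    relative 1e-9 counts as equal.
    """
    if math.isclose(value, bound, rel_tol=1e-9, abs_tol=1e-12):
        return False
    return value > bound


def strictly_less(value: float, bound: float) -> bool:
    """``value < bound`` with the same exact-tie guard as :func:`strictly_greater`."""
    if math.isclose(value, bound, rel_tol=1e-9, abs_tol=1e-12):
        return False
    return value < bound
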