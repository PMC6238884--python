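"""Diary, profile and configuration readers/writers.

The diary dialect is one row (CSV) or object (JSON) per registration:

``timestamp, data_type, value, unit, source, manual,
activity_quantity_kind, activity_quantity_value, factor_tag``

Timestamps are ISO-8601 at minute precision.  The unit column drives
conversion: blood glucose in mg/dL is divided by 18.016 into the canonical
mmol/L; unknown units are rejected with the 1-based line number of the
offending row.
"""
from __future__ import annotations

import csv
import json
import logging
from datetime import datetime
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple

import yaml

from .model import (
    MGDL_PER_MMOL,
    ActivityQuantity,
    DataType,
    LabContext,
    PatientProfile,
    Registration,
    ThresholdConfig,
)

logger = logging.getLogger(__name__)

COLUMNS = ["timestamp", "data_type", "value", "unit", "source", "manual",
           "activity_quantity_kind", "activity_quantity_value", "factor_tag"]

#: Accepted units per data type; first entry is canonical.
UNITS: Dict[DataType, Tuple[str, ...]] = {
    DataType.BLOOD_GLUCOSE: ("mmol/L", "mg/dL"),
    DataType.INSULIN_BOLUS: ("U",),
    DataType.INSULIN_BASAL: ("U",),
    DataType.CARBOHYDRATES: ("g",),
    DataType.PHYSICAL_ACTIVITY: ("", "min", "steps", "METs"),
    DataType.BLOOD_PRESSURE_SYSTOLIC: ("mmHg",),
    DataType.BLOOD_PRESSURE_DIASTOLIC: ("mmHg",),
    DataType.WEIGHT: ("kg",),
    DataType.EXTERNAL_FACTOR: ("",),
}


class DiaryFormatError(ValueError):
    """One or more rows of a diary file could not be parsed."""

    def __init__(self, errors: List[Tuple[int, str]]):
        self.errors = errors
        listing = "; ".join(f"line {n}: {msg}" for n, msg in errors[:10])
        super().__init__(f"{len(errors)} invalid diary row(s): {listing}")


def _row_to_registration(row: Dict[str, Any]) -> Registration:
    raw_type = (row.get("data_type") or "").strip()
    try:
        dt = DataType(raw_type)
    except ValueError:
        raise ValueError(f"unknown data_type {raw_type!r}")
    ts = datetime.fromisoformat(str(row["timestamp"]).strip())
    unit = (row.get("unit") or "").strip()
    if unit and unit not in UNITS[dt]:
        raise ValueError(f"unknown unit {unit!r} for {dt.value}")
    value = float(row.get("value") or 0.0)
    if dt == DataType.BLOOD_GLUCOSE and unit == "mg/dL":
        value = value / MGDL_PER_MMOL
    manual_raw = row.get("manual", True)
    manual = str(manual_raw).strip().lower() not in ("false", "0", "no")
    aq = None
    kind = (row.get("activity_quantity_kind") or "").strip()
    if kind:
        if kind == "intensity":
            aq = ActivityQuantity(kind="intensity",
                                  tag=str(row.get("activity_quantity_value")).strip())
        else:
            aq = ActivityQuantity(kind=kind,
                                  amount=float(row.get("activity_quantity_value") or 0.0))
    factor = (row.get("factor_tag") or "").strip() or None
    return Registration(timestamp=ts, data_type=dt, value=value,
                        activity_quantity=aq, factor_tag=factor,
                        source=(row.get("source") or "unknown").strip() or "unknown",
                        manual=manual)


def _registration_to_row(r: Registration) -> Dict[str, Any]:
    unit = UNITS[r.data_type][0]
    aq_kind, aq_value = "", ""
    if r.activity_quantity is not None:
        aq_kind = r.activity_quantity.kind
        if aq_kind == "intensity":
            aq_value = r.activity_quantity.tag or ""
        else:
            aq_value = f"{r.activity_quantity.amount:g}"
        unit = {"minutes": "min", "steps": "steps", "mets": "METs",
                "intensity": ""}[aq_kind]
    return {
        "timestamp": r.timestamp.isoformat(timespec="minutes"),
        "data_type": r.data_type.value,
        "value": f"{r.value:g}",
        "unit": unit,
        "source": r.source,
        "manual": str(r.manual).lower(),
        "activity_quantity_kind": aq_kind,
        "activity_quantity_value": aq_value,
        "factor_tag": r.factor_tag or "",
    }


def read_diary(path, partial: bool = False) -> List[Registration]:
    """Load a CSV or JSON diary; dialect inferred from the file suffix.

    Row-level errors are collected with their 1-based line numbers.  By
    default any bad row raises :class:`DiaryFormatError`; with
    ``partial=True`` bad rows are skipped with a logged warning, but a diary
    in which *every* row is bad still raises.
    """
    path = Path(path)
    rows: List[Tuple[int, Dict[str, Any]]] = []
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise DiaryFormatError([(1, "JSON diary must be a list of objects")])
        rows = [(i + 1, obj) for i, obj in enumerate(data)]
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            rows = [(i + 2, row) for i, row in enumerate(reader)]  # header is line 1

    registrations: List[Registration] = []
    errors: List[Tuple[int, str]] = []
    for line_no, row in rows:
        try:
            registrations.append(_row_to_registration(row))
        except Exception as exc:
            errors.append((line_no, str(exc)))
    if errors and (not partial or not registrations):
        raise DiaryFormatError(errors)
    for line_no, msg in errors:
        logger.warning("skipped diary row at line %d: %s", line_no, msg)
    return registrations


def write_diary(registrations: List[Registration], path) -> None:
    """Write a diary in the dialect implied by the file suffix (.csv/.json)."""
    path = Path(path)
    rows = [_registration_to_row(r) for r in registrations]
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=COLUMNS)
            writer.writeheader()
            writer.writerows(rows)


def read_profile(path) -> Tuple[PatientProfile, LabContext]:
    """Load a patient profile JSON; an optional ``lab`` object supplies HbA1c."""
    with open(path) as fh:
        data = json.load(fh)
    lab = LabContext.model_validate(data.pop("lab", {}) or {})
    profile = PatientProfile.model_validate(data)
    return profile, lab


def write_profile(profile: PatientProfile, lab: Optional[LabContext], path) -> None:
    doc = json.loads(profile.model_dump_json())
    if lab is not None:
        doc["lab"] = json.loads(lab.model_dump_json())
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_config(path) -> ThresholdConfig:
    """Load a threshold configuration from a YAML mapping."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return ThresholdConfig.model_validate(doc)
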