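"""Derived anthropometric indices carried by BioSCOOP records.

Three standard body-composition indices are computed from raw measurements:

* WHR — waist-to-hip ratio, waist / hip (dimensionless);
* BMI — body mass index, weight / height^2 (kg/m^2);
* CI  — corpulence (Rohrer's/ponderal) index, weight / height^3 (kg/m^3).

Heights are stored in centimetres but the indices use metres, so
``ci(w, h) * (h/100) == bmi(w, h)`` exactly in real arithmetic.  Values are
never rounded here; rounding happens only at serialization.
"""

from __future__ import annotations

import math
from typing import Any

from .schema_model import (
    InvalidRecordError,
    ValidationReport,
    Violation,
    derived_agrees,
    as_doc,
    validate_records,
)

__all__ = ["bmi", "whr", "corpulence_index", "enrich_record"]


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ValueError(f"{name} must be a number, got {type(value).__name__}")
        if not math.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be a positive finite number, got {value!r}")


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index in kg/m^2: weight divided by squared height in metres."""
    _require_positive(weight_kg=weight_kg, height_cm=height_cm)
    return weight_kg / (height_cm / 100.0) ** 2


def whr(waist_cm: float, hip_cm: float) -> float:
    """Waist-to-hip ratio (dimensionless); any common length unit cancels."""
    _require_positive(waist_cm=waist_cm, hip_cm=hip_cm)
    return waist_cm / hip_cm


def corpulence_index(weight_kg: float, height_cm: float) -> float:
    """Corpulence (Rohrer's) index in kg/m^3: weight over cubed height in metres."""
    _require_positive(weight_kg=weight_kg, height_cm=height_cm)
    return weight_kg / (height_cm / 100.0) ** 3


def enrich_record(record: Any) -> tuple[dict[str, Any], list[Violation]]:
    """Fill absent WHR/BMI/CI from raw measurements on a valid record.

    Returns the enriched document plus any ``derived_inconsistent``
    violations for stored indices that disagree with recomputation beyond
    the relative tolerance.  Stored values are flagged, never overwritten;
    indices whose raw inputs are absent are left untouched.  Idempotent on
    already-enriched consistent records.
    """
    doc = as_doc(record)
    report = validate_records([doc])
    # derived inconsistency is precisely what this function reports back as
    # flags, so only *other* violations disqualify the record
    blocking = [v for v in report.violations if v.rule_id != "derived_inconsistent"]
    if blocking:
        raise InvalidRecordError(ValidationReport(tuple(blocking)))

    anth = doc.get("anthropometry")
    if not anth:
        return doc, []

    anth = dict(anth)
    doc = dict(doc)
    doc["anthropometry"] = anth
    flags: list[Violation] = []

    recipes = (
        ("bmi", ("weightKg", "heightCm"), bmi),
        ("ci", ("weightKg", "heightCm"), corpulence_index),
        ("whr", ("waistCm", "hipCm"), whr),
    )
    for key, inputs, fn in recipes:
        raws = [anth.get(name) for name in inputs]
        if any(r is None for r in raws):
            continue
        expected = fn(*raws)
        stored = anth.get(key)
        if stored is None:
            anth[key] = expected
        elif not derived_agrees(stored, expected):
            flags.append(Violation(
                0, f"anthropometry.{key}", "derived_inconsistent",
                f"stored {key} {stored} disagrees with recomputed {expected:.6f}"))
    return doc, flags
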