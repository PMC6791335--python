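"""Record data model and validation for the BioSCOOP exchange format.

BioSCOOP documents describe one biobank sample together with its donor:
identifiers, a donor phenotype block (birth date, places, sex, pigmentation,
blood group), optional anthropometry with the derived indices WHR/BMI/CI,
a list of ICD-10 coded medical events, the sample material form, a record
timestamp and a data-source provenance tag.

Two representations coexist:

* **documents** — plain dicts with lowerCamelCase keys, exactly the JSON
  objects exchanged on disk.  Validation and canonicalization operate on
  documents, because arbitrary incoming JSON may violate the schema.
* **dataclasses** (:class:`BioscoopRecord` and friends) — a typed in-memory
  convenience layer with ``to_doc``/``from_doc`` converters.

Validation never raises on *content* errors; it returns a
:class:`ValidationReport` listing one :class:`Violation` per broken rule,
ordered deterministically by ``(record_index, path, rule_id)``.  Only a
structurally unusable input (not an array of objects) raises
:class:`StructuralError`.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
import re
from importlib import resources
from typing import Any, Mapping

# ---------------------------------------------------------------------------
# Catalogues

DATA_SOURCES = ("donor_questionnaire", "medical_record", "physical_measurement")
SEXES = ("male", "female", "other", "unknown")
SKIN_TONES = ("I", "II", "III", "IV", "V", "VI")  # Fitzpatrick-style ordinal
HAIR_COLOURS = ("black", "brown", "blond", "red", "grey", "other")
EYE_COLOURS = ("brown", "blue", "green", "grey", "other")
BLOOD_GROUPS = ("A+", "A-", "B+", "B-", "AB+", "AB-", "O+", "O-", "unknown")
EVENT_TYPES = ("disease", "procedure")
MATERIAL_FORMS = (
    "whole_blood", "serum", "plasma", "dna", "rna",
    "saliva", "tissue", "urine", "other",
)

ICD10_PATTERN = r"^[A-Z][0-9]{2}(\.[0-9]{1,2})?$"
ICD10_RE = re.compile(ICD10_PATTERN)

#: Relative tolerance for stored-vs-recomputed WHR/BMI/CI agreement.
DERIVED_REL_TOL = 1e-6

#: Optional hook: a set of admissible ICD-10 codes.  Ships empty, meaning
#: codes are checked against the pattern only; install a code list here to
#: additionally validate membership.
ICD10_CODE_LIST: set[str] = set()

ENUM_CATALOGUES: dict[str, tuple[str, ...]] = {
    "dataSource": DATA_SOURCES,
    "donor.sex": SEXES,
    "donor.skinTone": SKIN_TONES,
    "donor.hairColour": HAIR_COLOURS,
    "donor.eyeColour": EYE_COLOURS,
    "donor.bloodGroup": BLOOD_GROUPS,
    "medicalEvents[].eventType": EVENT_TYPES,
    "sample.materialForm": MATERIAL_FORMS,
}

#: Every addressable field path (list indices normalized to ``[]``) and its
#: scalar kind.  The CSV mapping layer validates target paths against this.
FIELD_TYPES: dict[str, str] = {
    "donorId": "string",
    "collectionId": "string",
    "sampleId": "string",
    "timestamp": "date",
    "dataSource": "enum",
    "donor.birthDate": "date",
    "donor.birthPlace": "string",
    "donor.residencePlace": "string",
    "donor.sex": "enum",
    "donor.ethnicOrigin": "string",
    "donor.skinTone": "enum",
    "donor.hairColour": "enum",
    "donor.eyeColour": "enum",
    "donor.bloodGroup": "enum",
    "anthropometry.heightCm": "number",
    "anthropometry.weightKg": "number",
    "anthropometry.waistCm": "number",
    "anthropometry.hipCm": "number",
    "anthropometry.whr": "number",
    "anthropometry.bmi": "number",
    "anthropometry.ci": "number",
    "medicalEvents[].icd10Code": "string",
    "medicalEvents[].eventType": "enum",
    "medicalEvents[].eventDate": "date",
    "sample.materialForm": "enum",
}

_MEASUREMENT_KEYS = ("heightCm", "weightKg", "waistCm", "hipCm", "whr", "bmi", "ci")


class StructuralError(ValueError):
    """Input is not usable at all (e.g. top level is not an array of objects)."""


class InvalidRecordError(ValueError):
    """An operation requiring a valid record received an invalid one."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        first = report.violations[0]
        super().__init__(
            f"record is invalid ({len(report.violations)} violation(s); "
            f"first: {first.path}: {first.rule_id})"
        )


# ---------------------------------------------------------------------------
# Dates

def parse_iso_date(text: str) -> datetime.date:
    """Parse an ISO 8601 calendar date, tolerating unpadded month/day.

    Accepts ``YYYY-MM-DD`` and variants like ``2019-1-5``; rejects anything
    else, including impossible dates (Feb 31).
    """
    parts = text.strip().split("-")
    if len(parts) != 3 or not all(p.isdigit() and p for p in parts):
        raise ValueError(f"not an ISO date: {text!r}")
    year, month, day = (int(p) for p in parts)
    return datetime.date(year, month, day)  # raises ValueError on bad calendar


# ---------------------------------------------------------------------------
# Report types

@dataclasses.dataclass(frozen=True)
class Violation:
    record_index: int
    path: str
    rule_id: str
    message: str


@dataclasses.dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...]

    @property
    def valid(self) -> bool:
        return not self.violations

    def to_json(self) -> dict[str, Any]:
        return {
            "valid": self.valid,
            "violations": [dataclasses.asdict(v) for v in self.violations],
        }


# ---------------------------------------------------------------------------
# Typed record layer

@dataclasses.dataclass
class MedicalEvent:
    """One ICD-10 coded disease or procedure, optionally dated."""

    icd10_code: str
    event_type: str
    event_date: datetime.date | None = None

    def to_doc(self) -> dict[str, Any]:
        doc: dict[str, Any] = {
            "icd10Code": self.icd10_code,
            "eventType": self.event_type,
        }
        if self.event_date is not None:
            doc["eventDate"] = self.event_date.isoformat()
        return doc

    @classmethod
    def from_doc(cls, doc: Mapping[str, Any]) -> "MedicalEvent":
        date = doc.get("eventDate")
        return cls(
            icd10_code=doc["icd10Code"],
            event_type=doc["eventType"],
            event_date=parse_iso_date(date) if date is not None else None,
        )


@dataclasses.dataclass
class AnthropometricProfile:
    """Raw body measurements plus the derived indices they determine.

    Units: centimetres for lengths, kilograms for weight; WHR dimensionless,
    BMI kg/m^2, CI kg/m^3.  ``extras`` is an open map for additional named
    measurements (always positive reals).
    """

    height_cm: float | None = None
    weight_kg: float | None = None
    waist_cm: float | None = None
    hip_cm: float | None = None
    extras: dict[str, float] = dataclasses.field(default_factory=dict)
    whr: float | None = None
    bmi: float | None = None
    ci: float | None = None

    def to_doc(self) -> dict[str, Any]:
        doc: dict[str, Any] = {}
        for attr, key in (
            ("height_cm", "heightCm"), ("weight_kg", "weightKg"),
            ("waist_cm", "waistCm"), ("hip_cm", "hipCm"),
            ("whr", "whr"), ("bmi", "bmi"), ("ci", "ci"),
        ):
            value = getattr(self, attr)
            if value is not None:
                doc[key] = float(value)
        if self.extras:
            doc["extras"] = {k: float(v) for k, v in self.extras.items()}
        return doc

    @classmethod
    def from_doc(cls, doc: Mapping[str, Any]) -> "AnthropometricProfile":
        return cls(
            height_cm=doc.get("heightCm"),
            weight_kg=doc.get("weightKg"),
            waist_cm=doc.get("waistCm"),
            hip_cm=doc.get("hipCm"),
            extras=dict(doc.get("extras", {})),
            whr=doc.get("whr"),
            bmi=doc.get("bmi"),
            ci=doc.get("ci"),
        )


@dataclasses.dataclass
class DonorProfile:
    birth_date: datetime.date
    sex: str
    birth_place: str | None = None
    residence_place: str | None = None
    ethnic_origin: str | None = None
    skin_tone: str | None = None
    hair_colour: str | None = None
    eye_colour: str | None = None
    blood_group: str | None = None

    def to_doc(self) -> dict[str, Any]:
        doc: dict[str, Any] = {
            "birthDate": self.birth_date.isoformat(),
            "sex": self.sex,
        }
        for attr, key in (
            ("birth_place", "birthPlace"), ("residence_place", "residencePlace"),
            ("ethnic_origin", "ethnicOrigin"), ("skin_tone", "skinTone"),
            ("hair_colour", "hairColour"), ("eye_colour", "eyeColour"),
            ("blood_group", "bloodGroup"),
        ):
            value = getattr(self, attr)
            if value is not None:
                doc[key] = value
        return doc

    @classmethod
    def from_doc(cls, doc: Mapping[str, Any]) -> "DonorProfile":
        return cls(
            birth_date=parse_iso_date(doc["birthDate"]),
            sex=doc["sex"],
            birth_place=doc.get("birthPlace"),
            residence_place=doc.get("residencePlace"),
            ethnic_origin=doc.get("ethnicOrigin"),
            skin_tone=doc.get("skinTone"),
            hair_colour=doc.get("hairColour"),
            eye_colour=doc.get("eyeColour"),
            blood_group=doc.get("bloodGroup"),
        )


@dataclasses.dataclass
class SampleBlock:
    material_form: str

    def to_doc(self) -> dict[str, Any]:
        return {"materialForm": self.material_form}

    @classmethod
    def from_doc(cls, doc: Mapping[str, Any]) -> "SampleBlock":
        return cls(material_form=doc["materialForm"])


@dataclasses.dataclass
class BioscoopRecord:
    """One sample-donor document — the unit of exchange."""

    donor_id: str
    collection_id: str
    sample_id: str
    timestamp: datetime.date
    data_source: str
    donor: DonorProfile
    sample: SampleBlock
    anthropometry: AnthropometricProfile | None = None
    medical_events: list[MedicalEvent] = dataclasses.field(default_factory=list)

    def to_doc(self) -> dict[str, Any]:
        doc: dict[str, Any] = {
            "donorId": self.donor_id,
            "collectionId": self.collection_id,
            "sampleId": self.sample_id,
            "timestamp": self.timestamp.isoformat(),
            "dataSource": self.data_source,
            "donor": self.donor.to_doc(),
            "sample": self.sample.to_doc(),
            "medicalEvents": [e.to_doc() for e in self.medical_events],
        }
        if self.anthropometry is not None:
            anth = self.anthropometry.to_doc()
            if anth:
                doc["anthropometry"] = anth
        return doc

    @classmethod
    def from_doc(cls, doc: Mapping[str, Any]) -> "BioscoopRecord":
        anth = doc.get("anthropometry")
        return cls(
            donor_id=doc["donorId"],
            collection_id=doc["collectionId"],
            sample_id=doc["sampleId"],
            timestamp=parse_iso_date(doc["timestamp"]),
            data_source=doc["dataSource"],
            donor=DonorProfile.from_doc(doc["donor"]),
            sample=SampleBlock.from_doc(doc["sample"]),
            anthropometry=AnthropometricProfile.from_doc(anth) if anth else None,
            medical_events=[
                MedicalEvent.from_doc(e) for e in doc.get("medicalEvents", [])
            ],
        )


def as_doc(record: Any) -> dict[str, Any]:
    """Coerce a record (dataclass or document dict) to its document form."""
    if isinstance(record, BioscoopRecord):
        return record.to_doc()
    if isinstance(record, Mapping):
        return dict(record)
    raise TypeError(f"not a record: {type(record).__name__}")


# ---------------------------------------------------------------------------
# Validation

def _match_enum(value: str, catalogue: tuple[str, ...]) -> str | None:
    """Return the catalogued spelling matching ``value`` case-insensitively."""
    needle = value.strip().lower()
    for entry in catalogue:
        if needle == entry.lower():
            return entry
    return None


def derived_agrees(stored: float, recomputed: float, tol: float = DERIVED_REL_TOL) -> bool:
    """Stored and recomputed index agree within relative ``tol`` after
    canonicalization (canonical numbers carry 6 decimals, so values that
    round to the same canonical form always agree)."""
    if abs(stored - recomputed) <= tol * max(abs(stored), abs(recomputed)):
        return True
    return round(stored, 6) == round(recomputed, 6)


def _check_number(add, path: str, value: Any) -> float | None:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        add(path, "wrong_type", f"expected a number, got {type(value).__name__}")
        return None
    if not math.isfinite(value) or value <= 0:
        add(path, "positive_measurement", f"measurement must be a positive finite number, got {value!r}")
        return None
    return float(value)


def _validate_doc(doc: Mapping[str, Any]) -> list[tuple[str, str, str]]:
    """Per-record rule checks; returns (path, rule_id, message) triples."""
    out: list[tuple[str, str, str]] = []

    def add(path: str, rule: str, message: str) -> None:
        out.append((path, rule, message))

    def required_string(path: str, value: Any, nonempty: bool = False) -> str | None:
        if value is None:
            add(path, "required_field", "required field is missing")
            return None
        if not isinstance(value, str):
            add(path, "wrong_type", f"expected a string, got {type(value).__name__}")
            return None
        if nonempty and not value.strip():
            add(path, "required_nonempty", "must be non-empty after trimming")
            return None
        return value

    def check_date(path: str, value: Any, required: bool) -> datetime.date | None:
        if value is None:
            if required:
                add(path, "required_field", "required field is missing")
            return None
        if not isinstance(value, str):
            add(path, "wrong_type", f"expected an ISO date string, got {type(value).__name__}")
            return None
        try:
            return parse_iso_date(value)
        except ValueError:
            add(path, "date_parse", f"not a valid calendar date: {value!r}")
            return None

    def check_enum(path: str, value: Any, catalogue: tuple[str, ...], required: bool) -> None:
        if value is None:
            if required:
                add(path, "required_field", "required field is missing")
            return
        if not isinstance(value, str):
            add(path, "wrong_type", f"expected a string, got {type(value).__name__}")
            return
        if _match_enum(value, catalogue) is None:
            add(path, "enum_value", f"{value!r} is not a catalogued value")

    for key in ("donorId", "collectionId", "sampleId"):
        required_string(key, doc.get(key), nonempty=True)

    timestamp = check_date("timestamp", doc.get("timestamp"), required=True)
    check_enum("dataSource", doc.get("dataSource"), DATA_SOURCES, required=True)

    birth: datetime.date | None = None
    donor = doc.get("donor")
    if donor is None:
        add("donor", "required_field", "required field is missing")
    elif not isinstance(donor, Mapping):
        add("donor", "wrong_type", "donor must be an object")
    else:
        birth = check_date("donor.birthDate", donor.get("birthDate"), required=True)
        check_enum("donor.sex", donor.get("sex"), SEXES, required=True)
        for key in ("birthPlace", "residencePlace", "ethnicOrigin"):
            value = donor.get(key)
            if value is not None and not isinstance(value, str):
                add(f"donor.{key}", "wrong_type", "expected a string")
        check_enum("donor.skinTone", donor.get("skinTone"), SKIN_TONES, required=False)
        check_enum("donor.hairColour", donor.get("hairColour"), HAIR_COLOURS, required=False)
        check_enum("donor.eyeColour", donor.get("eyeColour"), EYE_COLOURS, required=False)
        check_enum("donor.bloodGroup", donor.get("bloodGroup"), BLOOD_GROUPS, required=False)

    if timestamp is not None and birth is not None and timestamp < birth:
        add("timestamp", "date_order",
            f"record timestamp {timestamp.isoformat()} precedes donor birth date {birth.isoformat()}")

    anth = doc.get("anthropometry")
    if anth is not None:
        if not isinstance(anth, Mapping):
            add("anthropometry", "wrong_type", "anthropometry must be an object")
        else:
            values: dict[str, float] = {}
            for key in _MEASUREMENT_KEYS:
                raw = anth.get(key)
                if raw is None:
                    continue
                number = _check_number(add, f"anthropometry.{key}", raw)
                if number is not None:
                    values[key] = number
            extras = anth.get("extras")
            if extras is not None:
                if not isinstance(extras, Mapping):
                    add("anthropometry.extras", "wrong_type", "extras must be an object")
                else:
                    for name, raw in extras.items():
                        _check_number(add, f"anthropometry.extras.{name}", raw)
            # stored derived indices must agree with recomputation
            if {"weightKg", "heightCm", "bmi"} <= values.keys():
                expected = values["weightKg"] / (values["heightCm"] / 100.0) ** 2
                if not derived_agrees(values["bmi"], expected):
                    add("anthropometry.bmi", "derived_inconsistent",
                        f"stored bmi {values['bmi']} disagrees with recomputed {expected:.6f}")
            if {"weightKg", "heightCm", "ci"} <= values.keys():
                expected = values["weightKg"] / (values["heightCm"] / 100.0) ** 3
                if not derived_agrees(values["ci"], expected):
                    add("anthropometry.ci", "derived_inconsistent",
                        f"stored ci {values['ci']} disagrees with recomputed {expected:.6f}")
            if {"waistCm", "hipCm", "whr"} <= values.keys():
                expected = values["waistCm"] / values["hipCm"]
                if not derived_agrees(values["whr"], expected):
                    add("anthropometry.whr", "derived_inconsistent",
                        f"stored whr {values['whr']} disagrees with recomputed {expected:.6f}")

    events = doc.get("medicalEvents")
    if events is not None:
        if not isinstance(events, list):
            add("medicalEvents", "wrong_type", "medicalEvents must be an array")
        else:
            for i, event in enumerate(events):
                prefix = f"medicalEvents[{i}]"
                if not isinstance(event, Mapping):
                    add(prefix, "wrong_type", "medical event must be an object")
                    continue
                code = required_string(f"{prefix}.icd10Code", event.get("icd10Code"))
                if code is not None and ICD10_RE.fullmatch(code.strip()) is None:
                    add(f"{prefix}.icd10Code", "icd10_pattern",
                        f"{code!r} does not match {ICD10_PATTERN}")
                elif code is not None and ICD10_CODE_LIST and code.strip() not in ICD10_CODE_LIST:
                    add(f"{prefix}.icd10Code", "icd10_code_list",
                        f"{code!r} is not in the installed ICD-10 code list")
                check_enum(f"{prefix}.eventType", event.get("eventType"), EVENT_TYPES, required=True)
                event_date = check_date(f"{prefix}.eventDate", event.get("eventDate"), required=False)
                if event_date is not None and birth is not None and event_date < birth:
                    add(f"{prefix}.eventDate", "date_order",
                        f"event date {event_date.isoformat()} precedes donor birth date")

    sample = doc.get("sample")
    if sample is None:
        add("sample", "required_field", "required field is missing")
    elif not isinstance(sample, Mapping):
        add("sample", "wrong_type", "sample must be an object")
    else:
        check_enum("sample.materialForm", sample.get("materialForm"), MATERIAL_FORMS, required=True)

    return out


def validate_records(records: list[Any]) -> ValidationReport:
    """Validate a document set against every schema rule.

    Accepts a parsed JSON array of record objects (dataclass records are
    coerced).  Content errors are collected, never raised; a non-array or
    non-object element raises :class:`StructuralError`.
    """
    if not isinstance(records, list):
        raise StructuralError("input must be a JSON array of record objects")
    docs: list[dict[str, Any]] = []
    for i, record in enumerate(records):
        if isinstance(record, BioscoopRecord):
            docs.append(record.to_doc())
        elif isinstance(record, Mapping):
            docs.append(dict(record))
        else:
            raise StructuralError(f"element {i} is not an object")

    violations: list[Violation] = []
    for i, doc in enumerate(docs):
        violations.extend(Violation(i, p, r, m) for p, r, m in _validate_doc(doc))

    # sampleId unique across the set (which also makes (donorId, sampleId)
    # pairs unique)
    seen: dict[str, int] = {}
    for i, doc in enumerate(docs):
        sid = doc.get("sampleId")
        if isinstance(sid, str) and sid.strip():
            key = sid.strip()
            if key in seen:
                violations.append(Violation(
                    i, "sampleId", "unique_sample_id",
                    f"sampleId {key!r} already used by record {seen[key]}"))
            else:
                seen[key] = i

    violations.sort(key=lambda v: (v.record_index, v.path, v.rule_id))
    return ValidationReport(tuple(violations))


#: rule_id -> human description, the validator's complete rule catalogue.
RULE_CATALOGUE: dict[str, str] = {
    "required_field": "a required field is missing",
    "required_nonempty": "an identifier is empty after whitespace trimming",
    "wrong_type": "a field has the wrong JSON type",
    "date_parse": "a date field is not a valid ISO 8601 calendar date",
    "date_order": "a dated field precedes the donor birth date",
    "enum_value": "an enum field holds an uncatalogued value",
    "icd10_pattern": "an ICD-10 code does not match the code pattern",
    "positive_measurement": "a measurement is not a positive finite number",
    "derived_inconsistent": "a stored WHR/BMI/CI disagrees with recomputation",
    "unique_sample_id": "a sampleId occurs more than once in the document set",
}


# ---------------------------------------------------------------------------
# Canonicalization

def _canonical_number(value: float) -> float:
    return round(float(value), 6)


def canonicalize_record(record: Any, *, validate: bool = True) -> dict[str, Any]:
    """Return the canonical document form of a valid record.

    Canonical means: dates zero-padded ISO 8601; enum values in catalogue
    spelling (lower-case except bloodGroup and skinTone); identifiers
    trimmed; numbers rounded to 6 decimals; keys sorted at every level.
    Idempotent by construction.
    """
    doc = as_doc(record)
    if validate:
        report = validate_records([doc])
        if not report.valid:
            raise InvalidRecordError(report)

    out: dict[str, Any] = {
        "donorId": doc["donorId"].strip(),
        "collectionId": doc["collectionId"].strip(),
        "sampleId": doc["sampleId"].strip(),
        "timestamp": parse_iso_date(doc["timestamp"]).isoformat(),
        "dataSource": _match_enum(doc["dataSource"], DATA_SOURCES),
    }

    donor_in = doc["donor"]
    donor: dict[str, Any] = {
        "birthDate": parse_iso_date(donor_in["birthDate"]).isoformat(),
        "sex": _match_enum(donor_in["sex"], SEXES),
    }
    for key in ("birthPlace", "residencePlace", "ethnicOrigin"):
        if donor_in.get(key) is not None:
            donor[key] = donor_in[key]
    for key, catalogue in (
        ("skinTone", SKIN_TONES), ("hairColour", HAIR_COLOURS),
        ("eyeColour", EYE_COLOURS), ("bloodGroup", BLOOD_GROUPS),
    ):
        if donor_in.get(key) is not None:
            donor[key] = _match_enum(donor_in[key], catalogue)
    out["donor"] = dict(sorted(donor.items()))

    anth_in = doc.get("anthropometry")
    if anth_in:
        anth: dict[str, Any] = {}
        for key in _MEASUREMENT_KEYS:
            if anth_in.get(key) is not None:
                anth[key] = _canonical_number(anth_in[key])
        if anth_in.get("extras"):
            anth["extras"] = {
                name: _canonical_number(v)
                for name, v in sorted(anth_in["extras"].items())
            }
        if anth:
            out["anthropometry"] = dict(sorted(anth.items()))

    events = []
    for event in doc.get("medicalEvents") or []:
        canon_event: dict[str, Any] = {
            "eventType": _match_enum(event["eventType"], EVENT_TYPES),
            "icd10Code": event["icd10Code"].strip(),
        }
        if event.get("eventDate") is not None:
            canon_event["eventDate"] = parse_iso_date(event["eventDate"]).isoformat()
        events.append(dict(sorted(canon_event.items())))
    out["medicalEvents"] = events

    out["sample"] = {"materialForm": _match_enum(doc["sample"]["materialForm"], MATERIAL_FORMS)}
    return dict(sorted(out.items()))


def load_json_schema() -> dict[str, Any]:
    """The packaged JSON Schema (draft 2020-12) for a BioSCOOP document set."""
    text = resources.files("bioscoop.data").joinpath("bioscoop.schema.json").read_text("utf-8")
    return json.loads(text)
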