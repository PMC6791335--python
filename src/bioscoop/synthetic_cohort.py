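"""Deterministic mock-cohort generator.

Emulates a biobank test data set: 200 sample-donor records with randomly
drawn phenotype, anthropometry, ICD-10 medical events and sample material.
All randomness flows from one seeded :class:`random.Random`; the same
configuration and seed always produce byte-identical output, so the cohort
doubles as a reproducible fixture for the conversion and query layers.

Distributions are uniform over the packaged value pools and numeric ranges:

* height 140-210 cm, weight 40-150 kg, waist 50-150 cm, hip 60-160 cm
  (rounded to 0.1), with WHR/BMI/CI always filled consistently;
* birth years 1940-2004, record timestamps in 2018-2019;
* 0-5 medical events per donor, codes drawn from a small ICD-10 pool;
* each optional donor field independently missing with ``missing_rate``.

Value pools include "Gdansk, Poland" among birth places so the canonical
phrase query ``birthPlace:"Gdansk, Poland"`` always has data to match.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import io
import json
import random
from importlib import resources
from pathlib import Path
from typing import IO, Any

from . import derived_metrics
from .schema_model import (
    BLOOD_GROUPS,
    EVENT_TYPES,
    EYE_COLOURS,
    HAIR_COLOURS,
    SKIN_TONES,
    AnthropometricProfile,
    BioscoopRecord,
    DonorProfile,
    MedicalEvent,
    InvalidRecordError,
    SampleBlock,
    as_doc,
    validate_records,
)
from .io_convert import default_mapping

__all__ = ["CohortConfig", "generate_cohort", "write_cohort_csv", "default_value_pools"]

#: Plausible adult measurement ranges (cm / kg), sampled uniformly.
MEASUREMENT_RANGES = {
    "height_cm": (140.0, 210.0),
    "weight_kg": (40.0, 150.0),
    "waist_cm": (50.0, 150.0),
    "hip_cm": (60.0, 160.0),
}

BIRTH_YEARS = (1940, 2004)
TIMESTAMP_WINDOW = (datetime.date(2018, 1, 1), datetime.date(2019, 12, 31))

_POOL_FIELDS = {"birthPlace", "residencePlace", "ethnicOrigin", "sex", "icd10",
                "materialForm", "extras"}
_OPTIONAL_DONOR_FIELDS = (
    "birthPlace", "residencePlace", "ethnicOrigin", "skinTone",
    "hairColour", "eyeColour", "bloodGroup",
)


class ConfigError(ValueError):
    pass


def default_value_pools() -> dict[str, Any]:
    text = resources.files("bioscoop.data").joinpath("value_pools.json").read_text("utf-8")
    return json.loads(text)


@dataclasses.dataclass
class CohortConfig:
    n_records: int = 200
    seed: int = 0
    value_pools: dict[str, Any] = dataclasses.field(default_factory=default_value_pools)
    missing_rate: float = 0.05

    def validate(self) -> None:
        if not isinstance(self.n_records, int) or self.n_records < 1:
            raise ConfigError(f"n_records must be a positive integer, got {self.n_records!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError(f"missing_rate must be in [0, 1), got {self.missing_rate!r}")
        unknown = set(self.value_pools) - _POOL_FIELDS
        if unknown:
            raise ConfigError(f"value pool(s) for unknown field(s): {', '.join(sorted(unknown))}")
        for field in ("birthPlace", "residencePlace", "ethnicOrigin", "sex",
                      "icd10", "materialForm"):
            pool = self.value_pools.get(field)
            if not pool:
                raise ConfigError(f"value pool {field!r} is missing or empty")


def _random_date(rng: random.Random, lo: datetime.date, hi: datetime.date) -> datetime.date:
    return lo + datetime.timedelta(days=rng.randint(0, (hi - lo).days))


def _maybe(rng: random.Random, missing_rate: float, value):
    return None if rng.random() < missing_rate else value


def _round6(x: float) -> float:
    return round(x, 6)


def generate_cohort(config: CohortConfig | None = None) -> list[BioscoopRecord]:
    """Generate ``config.n_records`` valid records, reproducibly from the seed."""
    config = config or CohortConfig()
    config.validate()
    rng = random.Random(config.seed)
    pools = config.value_pools
    records: list[BioscoopRecord] = []

    for i in range(config.n_records):
        birth = datetime.date(rng.randint(*BIRTH_YEARS), rng.randint(1, 12), rng.randint(1, 28))
        timestamp = _random_date(rng, *TIMESTAMP_WINDOW)

        donor = DonorProfile(
            birth_date=birth,
            sex=rng.choice(pools["sex"]),
            birth_place=_maybe(rng, config.missing_rate, rng.choice(pools["birthPlace"])),
            residence_place=_maybe(rng, config.missing_rate, rng.choice(pools["residencePlace"])),
            ethnic_origin=_maybe(rng, config.missing_rate, rng.choice(pools["ethnicOrigin"])),
            skin_tone=_maybe(rng, config.missing_rate, rng.choice(SKIN_TONES)),
            hair_colour=_maybe(rng, config.missing_rate, rng.choice(HAIR_COLOURS)),
            eye_colour=_maybe(rng, config.missing_rate, rng.choice(EYE_COLOURS)),
            blood_group=_maybe(rng, config.missing_rate, rng.choice(BLOOD_GROUPS[:-1])),
        )

        measures = {
            name: round(rng.uniform(lo, hi), 1)
            for name, (lo, hi) in MEASUREMENT_RANGES.items()
        }
        extras = {}
        for name, (lo, hi) in sorted(pools.get("extras", {}).items()):
            value = _maybe(rng, config.missing_rate, round(rng.uniform(lo, hi), 1))
            if value is not None:
                extras[name] = value
        anthropometry = AnthropometricProfile(
            **measures,
            extras=extras,
            whr=_round6(derived_metrics.whr(measures["waist_cm"], measures["hip_cm"])),
            bmi=_round6(derived_metrics.bmi(measures["weight_kg"], measures["height_cm"])),
            ci=_round6(derived_metrics.corpulence_index(measures["weight_kg"], measures["height_cm"])),
        )

        events = []
        for _ in range(rng.randint(0, 5)):
            event_date = None
            if rng.random() < 0.8:
                event_date = _random_date(rng, birth, timestamp)
            events.append(MedicalEvent(
                icd10_code=rng.choice(pools["icd10"]),
                event_type=rng.choice(EVENT_TYPES),
                event_date=event_date,
            ))

        records.append(BioscoopRecord(
            donor_id=f"DON-{i + 1:04d}",
            collection_id=f"COL-{rng.randint(1, 5):02d}",
            sample_id=f"SAM-{i + 1:04d}",
            timestamp=timestamp,
            data_source="donor_questionnaire",
            donor=donor,
            sample=SampleBlock(material_form=rng.choice(pools["materialForm"])),
            anthropometry=anthropometry,
            medical_events=events,
        ))
    return records


def _csv_cell(doc: dict[str, Any], path: str) -> str:
    node: Any = doc
    for token in path.replace("]", "").split("."):
        if "[" in token:
            key, idx = token.split("[")
            seq = node.get(key) if isinstance(node, dict) else None
            node = seq[int(idx)] if seq and int(idx) < len(seq) else None
        elif isinstance(node, dict):
            node = node.get(token)
        else:
            node = None
        if node is None:
            return ""
    if isinstance(node, float):
        return repr(node)
    return str(node)


def write_cohort_csv(cohort: list[Any], destination: str | Path | IO) -> int:
    """Write the cohort as an RFC 4180 CSV matching the default column mapping.

    One header row plus one data row per record; cells containing the
    delimiter (e.g. ``"Gdansk, Poland"``) are quoted.  Returns the number
    of data rows written.  Refuses invalid records.
    """
    docs = [as_doc(r) for r in cohort]
    report = validate_records(docs)
    if not report.valid:
        raise InvalidRecordError(report)

    mapping = default_mapping()
    columns = list(mapping.entries)

    buffer = io.StringIO()
    writer = csv.writer(buffer, lineterminator="\r\n")  # RFC 4180 line ends
    writer.writerow(columns)
    for doc in docs:
        writer.writerow([_csv_cell(doc, mapping.entries[c]) for c in columns])
    payload = buffer.getvalue()

    if isinstance(destination, (str, Path)):
        with open(destination, "w", encoding="utf-8", newline="") as handle:
            handle.write(payload)
    elif isinstance(destination, io.TextIOBase):
        destination.write(payload)
    else:
        destination.write(payload.encode("utf-8"))
    return len(docs)
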