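"""CSV and JSON I/O for BioSCOOP documents.

Covers the classic ETL path of a biobank export: an RFC 4180 CSV with one
row per sample-donor record is read, each row is mapped onto the nested
record schema through an explicit :class:`ColumnMapping`, and the resulting
documents are validated and written as a canonical BioSCOOP JSON array.

Invalid rows are skipped and reported, never silently dropped and never
fatal: biobank exports are dirty, and the :class:`ValidationReport`
preserves an audit trail of exactly which rows failed and why.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
import math
import re
from importlib import resources
from pathlib import Path
from typing import Any, IO, Iterable, Mapping

import yaml

from .schema_model import (
    FIELD_TYPES,
    InvalidRecordError,
    StructuralError,
    ValidationReport,
    Violation,
    as_doc,
    canonicalize_record,
    validate_records,
)

__all__ = [
    "RowTable", "ColumnMapping", "CsvFormatError", "MappingError",
    "read_csv_table", "rows_to_records", "write_bioscoop_json",
    "read_bioscoop_json", "default_mapping",
]


class CsvFormatError(ValueError):
    """The CSV stream violates the expected tabular shape."""


class MappingError(ValueError):
    """The column mapping is inconsistent with the schema or the CSV header."""


@dataclasses.dataclass
class RowTable:
    """A parsed CSV: ordered header plus rows of string cells."""

    header: list[str]
    rows: list[list[str]]


_PATH_TOKEN_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)(?:\[([0-9]+)\])?$")


def _normalize_path(path: str) -> str:
    """``medicalEvents[3].icd10Code`` -> ``medicalEvents[].icd10Code``."""
    return re.sub(r"\[[0-9]+\]", "[]", path)


def _schema_type(path: str) -> str | None:
    normalized = _normalize_path(path)
    if normalized.startswith("anthropometry.extras.") and normalized.count(".") == 2:
        return "number"
    return FIELD_TYPES.get(normalized)


@dataclasses.dataclass
class ColumnMapping:
    """Declarative CSV column -> dotted record field path mapping.

    ``date_format`` is a ``strptime`` pattern applied to CSV date cells;
    cells equal to one of ``missing_tokens`` yield an absent field.
    """

    entries: dict[str, str]
    date_format: str = "%Y-%m-%d"
    missing_tokens: frozenset[str] = frozenset({"", "NA", "null"})

    def __post_init__(self) -> None:
        self.missing_tokens = frozenset(self.missing_tokens)
        seen: dict[str, str] = {}
        for column, path in self.entries.items():
            if _schema_type(path) is None:
                raise MappingError(f"column {column!r} targets unknown field path {path!r}")
            if path in seen:
                raise MappingError(
                    f"columns {seen[path]!r} and {column!r} both map to {path!r}")
            seen[path] = column

    @classmethod
    def from_file(cls, path: str | Path) -> "ColumnMapping":
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        if not isinstance(raw, Mapping) or "mapping" not in raw:
            raise MappingError(f"{path}: expected a mapping file with a 'mapping:' block")
        return cls(
            entries=dict(raw["mapping"]),
            date_format=raw.get("dateFormat", "%Y-%m-%d"),
            missing_tokens=frozenset(raw.get("missingTokens", ["", "NA", "null"])),
        )


def default_mapping() -> ColumnMapping:
    """The packaged mapping matching ``write_cohort_csv`` column names."""
    text = resources.files("bioscoop.data").joinpath("default_mapping.yaml").read_text("utf-8")
    raw = yaml.safe_load(text)
    return ColumnMapping(
        entries=dict(raw["mapping"]),
        date_format=raw["dateFormat"],
        missing_tokens=frozenset(raw["missingTokens"]),
    )


# ---------------------------------------------------------------------------
# CSV reading

def _open_text(source: str | Path | IO, mode: str = "r") -> tuple[IO, bool]:
    if isinstance(source, (str, Path)):
        encoding = "utf-8-sig" if "r" in mode else "utf-8"
        return open(source, mode, encoding=encoding, newline=""), True
    return source, False


def read_csv_table(source: str | Path | IO[str], delimiter: str = ",") -> RowTable:
    """Read an RFC 4180 CSV (quoted fields, embedded delimiters/newlines).

    Raises :class:`CsvFormatError` on an empty stream ("no header"), a
    duplicate header name, or a ragged row (reported with its 1-based
    data-row number).
    """
    if len(delimiter) != 1:
        raise CsvFormatError(f"delimiter must be a single character, got {delimiter!r}")
    handle, owned = _open_text(source)
    try:
        reader = csv.reader(handle, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise CsvFormatError("no header: CSV stream is empty") from None
        if header and header[0].startswith("\ufeff"):
            header[0] = header[0].lstrip("\ufeff")
        trimmed = [name.strip() for name in header]
        if len(set(trimmed)) != len(trimmed):
            dupes = sorted({n for n in trimmed if trimmed.count(n) > 1})
            raise CsvFormatError(f"duplicate header name(s): {', '.join(dupes)}")
        rows: list[list[str]] = []
        for i, row in enumerate(reader, start=1):
            if len(row) != len(header):
                raise CsvFormatError(
                    f"row {i}: expected {len(header)} cells, got {len(row)}")
            rows.append(row)
        return RowTable(header=trimmed, rows=rows)
    finally:
        if owned:
            handle.close()


# ---------------------------------------------------------------------------
# Row -> record conversion

def _set_path(doc: dict[str, Any], path: str, value: Any) -> None:
    node: Any = doc
    tokens = path.split(".")
    for pos, token in enumerate(tokens):
        match = _PATH_TOKEN_RE.match(token)
        if match is None:
            raise MappingError(f"malformed field path {path!r}")
        key, index = match.group(1), match.group(2)
        last = pos == len(tokens) - 1
        if index is None:
            if last:
                node[key] = value
            else:
                node = node.setdefault(key, {})
        else:
            idx = int(index)
            lst = node.setdefault(key, [])
            while len(lst) <= idx:
                lst.append({})
            if last:
                lst[idx] = value
            else:
                node = lst[idx]


def _parse_cell(cell: str, kind: str, date_format: str) -> tuple[Any, str | None]:
    """Returns (value, rule_id-or-None)."""
    import datetime

    cell = cell.strip()
    if kind == "date":
        try:
            parsed = datetime.datetime.strptime(cell, date_format).date()
        except ValueError:
            return None, "date_parse"
        return parsed.isoformat(), None
    if kind == "number":
        try:
            value = float(cell)
        except ValueError:
            return None, "number_parse"
        if not math.isfinite(value):
            return None, "number_parse"
        return value, None
    return cell, None  # string / enum cells pass through; validation judges them


def _prune(doc: dict[str, Any]) -> dict[str, Any]:
    events = doc.get("medicalEvents")
    if isinstance(events, list):
        doc["medicalEvents"] = [e for e in events if isinstance(e, dict) and e]
    anth = doc.get("anthropometry")
    if isinstance(anth, dict):
        extras = anth.get("extras")
        if isinstance(extras, dict) and not extras:
            anth.pop("extras")
        if not anth:
            doc.pop("anthropometry")
    return doc


def rows_to_records(
    table: RowTable, mapping: ColumnMapping
) -> tuple[list[dict[str, Any]], ValidationReport]:
    """Convert CSV rows to canonical BioSCOOP documents, one per valid row.

    The report indexes violations by data-row position (0-based).  Rows with
    unparseable cells or schema violations are excluded from the returned
    list but fully reported, so ``len(records) + rows_flagged == len(rows)``.
    """
    missing = [c for c in mapping.entries if c not in table.header]
    if missing:
        raise MappingError(
            f"mapped column(s) absent from CSV header: {', '.join(sorted(missing))}")

    col_index = {name: i for i, name in enumerate(table.header)}
    violations: list[Violation] = []
    docs: list[dict[str, Any] | None] = []

    for row_idx, row in enumerate(table.rows):
        doc: dict[str, Any] = {}
        parse_failed = False
        for column, path in mapping.entries.items():
            cell = row[col_index[column]]
            if cell.strip() in mapping.missing_tokens:
                continue
            value, rule = _parse_cell(cell, _schema_type(path), mapping.date_format)
            if rule is not None:
                violations.append(Violation(
                    row_idx, path, rule, f"cell {cell!r} in column {column!r}"))
                parse_failed = True
                continue
            _set_path(doc, path, value)
        docs.append(None if parse_failed else _prune(doc))

    parsed = [(i, d) for i, d in enumerate(docs) if d is not None]
    report = validate_records([d for _, d in parsed])
    for violation in report.violations:
        original = parsed[violation.record_index][0]
        violations.append(dataclasses.replace(violation, record_index=original))

    bad_rows = {v.record_index for v in violations}
    records = [
        canonicalize_record(d, validate=False)
        for i, d in parsed if i not in bad_rows
    ]
    violations.sort(key=lambda v: (v.record_index, v.path, v.rule_id))
    return records, ValidationReport(tuple(violations))


# ---------------------------------------------------------------------------
# BioSCOOP JSON

def _dump_canonical(docs: list[dict[str, Any]]) -> str:
    return json.dumps(docs, ensure_ascii=False, sort_keys=True, indent=2) + "\n"


def write_bioscoop_json(records: Iterable[Any], destination: str | Path | IO) -> int:
    """Write records as a canonical UTF-8 JSON array; returns the count.

    Output is stable: two writes of the same records are byte-identical.
    Refuses to write if any record is invalid (raises
    :class:`InvalidRecordError` carrying the validation report).
    """
    docs = [as_doc(r) for r in records]
    report = validate_records(docs)
    if not report.valid:
        raise InvalidRecordError(report)
    canonical = [canonicalize_record(d, validate=False) for d in docs]
    payload = _dump_canonical(canonical)

    if isinstance(destination, (str, Path)):
        with open(destination, "w", encoding="utf-8", newline="") as handle:
            handle.write(payload)
    elif isinstance(destination, io.TextIOBase):
        destination.write(payload)
    else:
        destination.write(payload.encode("utf-8"))
    return len(canonical)


def read_bioscoop_json(
    source: str | Path | IO,
) -> tuple[list[dict[str, Any]], ValidationReport]:
    """Read a BioSCOOP JSON array; returns (valid canonical docs, report).

    Round-trip law: ``read(write(X))`` equals ``canonicalize(X)``
    record-by-record.  Structural problems (not JSON, top level not an
    array) raise :class:`StructuralError` with a character offset where
    applicable; content problems are reported, not raised.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rb") as handle:
            raw = handle.read()
    else:
        raw = source.read()
    if isinstance(raw, bytes):
        text = raw.decode("utf-8-sig")
    else:
        text = raw.lstrip("\ufeff")

    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise StructuralError(f"not valid JSON at character {exc.pos}: {exc.msg}") from exc
    if not isinstance(data, list):
        raise StructuralError("top level must be an array of record objects")

    report = validate_records(data)  # raises StructuralError on non-object elements
    bad = {v.record_index for v in report.violations}
    records = [
        canonicalize_record(doc, validate=False)
        for i, doc in enumerate(data) if i not in bad
    ]
    return records, report
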