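"""Solr-style query parsing and evaluation over in-memory record sets.

Implements the Lucene-flavoured query dialect used for biobank sample
search — ``field:value``, ``field:"a phrase"``, ``numeric:[lo TO hi]``,
combined with upper-case ``AND`` / ``OR`` / ``NOT`` and parentheses — and
evaluates it against flattened views of BioSCOOP records, standing in for
an Apache Solr index at desk scale.

Deliberate simplifications relative to real Solr/Lucene, chosen so that a
query has exactly one unsurprising meaning when selecting medical samples:

* term matching is exact full-string and case-insensitive, never
  tokenized or stemmed;
* mixing ``AND`` and ``OR`` at one level without parentheses is a parse
  error instead of inheriting Lucene's non-boolean precedence;
* only inclusive ``[lo TO hi]`` ranges; ``{`` exclusive ranges are a
  parse error; ``*`` is an open bound;
* a field is either known to the schema (or an alias such as
  ``gender`` -> ``sex``) or a hard error — typos never silently match
  nothing;
* a record without the queried field never matches a positive term, but
  does match under ``NOT`` (complement over the whole corpus), as in
  Lucene.

:func:`brute_force_filter` re-implements evaluation as a per-record truth
test with no set algebra; it exists solely as an independent cross-check
of :func:`evaluate`.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Any, Union

from .schema_model import as_doc

__all__ = [
    "OPEN", "FieldTerm", "PhraseTerm", "RangeTerm", "BoolNode", "QueryNode",
    "ResultSet", "QueryParseError", "QueryError", "UnknownFieldError",
    "parse_query", "flatten_record", "evaluate", "brute_force_filter",
    "result_to_json", "NUMERIC_FIELDS", "QUERY_FIELDS", "ALIASES",
]


class _Open:
    def __repr__(self) -> str:  # pragma: no cover
        return "OPEN"


#: Sentinel for an unbounded range end (``*`` in query syntax).
OPEN = _Open()


@dataclasses.dataclass(frozen=True)
class FieldTerm:
    field: str
    value: str


@dataclasses.dataclass(frozen=True)
class PhraseTerm:
    field: str
    phrase: str


@dataclasses.dataclass(frozen=True)
class RangeTerm:
    """Inclusive range ``field:[lo TO hi]``; either bound may be OPEN."""

    field: str
    lo: Union[str, _Open]
    hi: Union[str, _Open]


@dataclasses.dataclass(frozen=True)
class BoolNode:
    op: str  # "AND" | "OR" | "NOT"
    children: tuple["QueryNode", ...]

    def __post_init__(self) -> None:
        if self.op == "NOT" and len(self.children) != 1:
            raise ValueError("NOT takes exactly one child")
        if self.op in ("AND", "OR") and len(self.children) < 2:
            raise ValueError(f"{self.op} takes at least two children")


QueryNode = Union[FieldTerm, PhraseTerm, RangeTerm, BoolNode]


@dataclasses.dataclass(frozen=True)
class ResultSet:
    """Sorted matching record indices within the queried corpus."""

    matched: tuple[int, ...]
    total: int


class QueryParseError(ValueError):
    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at character {position})")


class QueryError(ValueError):
    """A well-formed query that cannot be evaluated (e.g. bad range bound)."""


class UnknownFieldError(QueryError):
    def __init__(self, field: str):
        self.field = field
        super().__init__(f"unknown query field {field!r}")


# ---------------------------------------------------------------------------
# Field registry

NUMERIC_FIELDS = frozenset(
    {"heightCm", "weightKg", "waistCm", "hipCm", "whr", "bmi", "ci"})
DATE_FIELDS = frozenset({"timestamp", "birthDate"})
STRING_FIELDS = frozenset({
    "donorId", "collectionId", "sampleId", "dataSource", "sex",
    "birthPlace", "residencePlace", "ethnicOrigin", "skinTone",
    "hairColour", "eyeColour", "bloodGroup", "materialForm", "icd10",
})
QUERY_FIELDS = NUMERIC_FIELDS | DATE_FIELDS | STRING_FIELDS

#: Query-name aliases; the record schema stores "sex" while sample-search
#: front ends conventionally expose "gender".
ALIASES = {"gender": "sex"}


def resolve_field(name: str) -> str:
    canonical = ALIASES.get(name, name)
    if canonical not in QUERY_FIELDS:
        raise UnknownFieldError(name)
    return canonical


def flatten_record(record: Any) -> dict[str, Any]:
    """Project a record onto flat query-field names.

    Scalars stay scalars; medical-event codes flatten to the multi-valued
    field ``icd10``.  Dates are exposed as ISO strings, so lexicographic
    order equals chronological order.  Absent fields are absent keys.
    """
    doc = as_doc(record)
    view: dict[str, Any] = {}
    for key in ("donorId", "collectionId", "sampleId", "timestamp", "dataSource"):
        if doc.get(key) is not None:
            view[key] = doc[key]
    donor = doc.get("donor") or {}
    for key in ("birthDate", "birthPlace", "residencePlace", "sex", "ethnicOrigin",
                "skinTone", "hairColour", "eyeColour", "bloodGroup"):
        if donor.get(key) is not None:
            view[key] = donor[key]
    anth = doc.get("anthropometry") or {}
    for key in NUMERIC_FIELDS:
        if anth.get(key) is not None:
            view[key] = float(anth[key])
    codes = [e["icd10Code"] for e in doc.get("medicalEvents") or [] if "icd10Code" in e]
    if codes:
        view["icd10"] = codes
    sample = doc.get("sample") or {}
    if sample.get("materialForm") is not None:
        view["materialForm"] = sample["materialForm"]
    return view


# ---------------------------------------------------------------------------
# Parser (recursive descent)

_FIELD_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_BARE_STOP = set(' \t\r\n()"')


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    # -- low-level helpers
    def at_end(self) -> bool:
        return self.pos >= len(self.text)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self) -> None:
        while not self.at_end() and self.text[self.pos] in " \t\r\n":
            self.pos += 1

    def error(self, message: str, position: int | None = None) -> QueryParseError:
        return QueryParseError(message, self.pos if position is None else position)

    def match_word(self) -> str | None:
        """Consume and return an upper-case keyword-shaped word, else None."""
        match = re.match(r"[A-Z]+(?![A-Za-z0-9_:])", self.text[self.pos:])
        if match is None:
            return None
        self.pos += match.end()
        return match.group(0)

    # -- grammar
    def parse(self) -> QueryNode:
        self.skip_ws()
        if self.at_end():
            raise self.error("empty query")
        node = self.query()
        self.skip_ws()
        if not self.at_end():
            raise self.error(
                "unexpected trailing input; join clauses with AND or OR")
        return node

    def query(self) -> QueryNode:
        clauses = [self.clause()]
        ops: list[str] = []
        while True:
            save = self.pos
            self.skip_ws()
            op_pos = self.pos
            word = self.match_word()
            if word not in ("AND", "OR"):
                self.pos = save
                break
            self.skip_ws()
            ops.append(word)
            clauses.append(self.clause())
            if len(set(ops)) > 1:
                raise self.error(
                    "mixing AND and OR requires parentheses", op_pos)
        if not ops:
            return clauses[0]
        return BoolNode(ops[0], tuple(clauses))

    def clause(self) -> QueryNode:
        self.skip_ws()
        if self.at_end():
            raise self.error("dangling operator: expected a clause")
        save = self.pos
        word = self.match_word()
        if word == "NOT":
            return BoolNode("NOT", (self.clause(),))
        self.pos = save
        if self.peek() == "(":
            open_pos = self.pos
            self.pos += 1
            node = self.query()
            self.skip_ws()
            if self.peek() != ")":
                raise self.error("unbalanced parenthesis", open_pos)
            self.pos += 1
            return node
        return self.term()

    def term(self) -> QueryNode:
        match = _FIELD_RE.match(self.text, self.pos)
        if match is None:
            raise self.error(f"expected a field name, found {self.peek()!r}")
        field = ALIASES.get(match.group(0), match.group(0))
        self.pos = match.end()
        if self.peek() != ":":
            raise self.error(f"expected ':' after field name {match.group(0)!r}")
        self.pos += 1
        char = self.peek()
        if char == '"':
            return PhraseTerm(field, self.phrase())
        if char == "[":
            return self.range_term(field)
        if char == "{":
            raise self.error("exclusive {lo TO hi} ranges are not supported")
        value = self.bare_token(stop_extra=set())
        if not value:
            raise self.error("missing value after ':'")
        return FieldTerm(field, value)

    def phrase(self) -> str:
        open_pos = self.pos
        self.pos += 1  # consume opening quote
        end = self.text.find('"', self.pos)
        if end < 0:
            raise self.error("unbalanced quote", open_pos)
        phrase = self.text[self.pos:end]
        self.pos = end + 1
        return phrase

    def bare_token(self, stop_extra: set[str]) -> str:
        start = self.pos
        stops = _BARE_STOP | stop_extra
        while not self.at_end() and self.text[self.pos] not in stops:
            self.pos += 1
        return self.text[start:self.pos]

    def range_term(self, field: str) -> RangeTerm:
        open_pos = self.pos
        self.pos += 1  # consume '['
        self.skip_ws()
        lo = self.bare_token({"]"})
        if not lo:
            raise self.error("missing lower range bound")
        self.skip_ws()
        to_match = re.match(r"TO(?![A-Za-z0-9_])", self.text[self.pos:])
        if to_match is None:
            raise self.error("expected 'TO' between range bounds")
        self.pos += 2
        self.skip_ws()
        hi = self.bare_token({"]"})
        if not hi:
            raise self.error("missing upper range bound")
        self.skip_ws()
        if self.peek() != "]":
            raise self.error("unbalanced bracket", open_pos)
        self.pos += 1

        lo_bound = OPEN if lo == "*" else lo
        hi_bound = OPEN if hi == "*" else hi
        if lo_bound is not OPEN and hi_bound is not OPEN:
            try:
                lo_num, hi_num = float(lo), float(hi)
            except ValueError:
                pass
            else:
                if lo_num > hi_num:
                    raise self.error(
                        f"inverted numeric bounds: {lo} > {hi}", open_pos)
        return RangeTerm(field, lo_bound, hi_bound)


def parse_query(text: str) -> QueryNode:
    """Parse a query string into its AST; see the module docstring for the
    grammar.  Raises :class:`QueryParseError` with a character position on
    malformed input."""
    if not isinstance(text, str) or not text.strip():
        raise QueryParseError("empty query", 0)
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# Evaluation (set algebra over the corpus)

def check_fields(ast: QueryNode) -> None:
    """Raise :class:`UnknownFieldError` for any unresolvable field in the AST."""
    if isinstance(ast, BoolNode):
        for child in ast.children:
            check_fields(child)
    else:
        resolve_field(ast.field)


def _as_values(view: dict[str, Any], field: str) -> list[Any]:
    value = view.get(field)
    if value is None:
        return []
    return value if isinstance(value, list) else [value]


def _equals(candidate: Any, query_value: str, numeric: bool) -> bool:
    if numeric:
        try:
            return float(candidate) == float(query_value)
        except (TypeError, ValueError):
            return False
    return str(candidate).strip().lower() == query_value.strip().lower()


def _in_range(candidate: Any, term: RangeTerm, numeric: bool) -> bool:
    if numeric:
        try:
            value = float(candidate)
            lo_ok = term.lo is OPEN or float(term.lo) <= value
            hi_ok = term.hi is OPEN or value <= float(term.hi)
        except (TypeError, ValueError):
            raise QueryError(
                f"non-numeric range bound for numeric field {term.field!r}")
        return lo_ok and hi_ok
    value = str(candidate).strip().lower()
    lo_ok = term.lo is OPEN or str(term.lo).strip().lower() <= value
    hi_ok = term.hi is OPEN or value <= str(term.hi).strip().lower()
    return lo_ok and hi_ok


def _term_matches(term: QueryNode, view: dict[str, Any]) -> bool:
    field = resolve_field(term.field)
    numeric = field in NUMERIC_FIELDS
    values = _as_values(view, field)
    if isinstance(term, FieldTerm):
        return any(_equals(v, term.value, numeric) for v in values)
    if isinstance(term, PhraseTerm):
        return any(_equals(v, term.phrase, numeric=False) for v in values)
    return any(_in_range(v, term, numeric) for v in values)


def evaluate(ast: QueryNode, corpus: list[Any]) -> ResultSet:
    """Evaluate a query AST over a corpus by set algebra.

    Boolean nodes are set intersection/union/complement over record-index
    sets; ``NOT`` complements against the whole corpus, so records lacking
    the field match the negation.  Raises :class:`UnknownFieldError` for a
    field that is neither in the schema nor an alias.
    """
    check_fields(ast)
    views = [flatten_record(r) for r in corpus]
    everything = frozenset(range(len(views)))

    def index_set(node: QueryNode) -> frozenset[int]:
        if isinstance(node, BoolNode):
            child_sets = [index_set(c) for c in node.children]
            if node.op == "NOT":
                return everything - child_sets[0]
            if node.op == "AND":
                return frozenset.intersection(*child_sets)
            return frozenset.union(*child_sets)
        return frozenset(
            i for i, view in enumerate(views) if _term_matches(node, view))

    matched = tuple(sorted(index_set(ast)))
    return ResultSet(matched=matched, total=len(matched))


# ---------------------------------------------------------------------------
# Independent oracle: per-record recursive truth evaluation

def brute_force_filter(ast: QueryNode, corpus: list[Any]) -> ResultSet:
    """Same contract as :func:`evaluate`, by direct per-record predicate
    evaluation with no indexing or set algebra; exists to cross-check
    :func:`evaluate`."""
    check_fields(ast)

    def holds(node: QueryNode, view: dict[str, Any]) -> bool:
        if isinstance(node, BoolNode):
            if node.op == "NOT":
                return not holds(node.children[0], view)
            if node.op == "AND":
                return all(holds(c, view) for c in node.children)
            if node.op == "OR":
                return any(holds(c, view) for c in node.children)
            raise ValueError(f"unknown operator {node.op!r}")

        field = resolve_field(node.field)
        raw = view.get(field)
        candidates = raw if isinstance(raw, list) else [] if raw is None else [raw]
        for candidate in candidates:
            if isinstance(node, FieldTerm):
                if field in NUMERIC_FIELDS:
                    try:
                        if float(candidate) == float(node.value):
                            return True
                        continue
                    except (TypeError, ValueError):
                        continue
                if str(candidate).strip().lower() == node.value.strip().lower():
                    return True
            elif isinstance(node, PhraseTerm):
                if str(candidate).strip().lower() == node.phrase.strip().lower():
                    return True
            elif isinstance(node, RangeTerm):
                if field in NUMERIC_FIELDS:
                    try:
                        value = float(candidate)
                        lo = None if node.lo is OPEN else float(node.lo)
                        hi = None if node.hi is OPEN else float(node.hi)
                    except (TypeError, ValueError):
                        raise QueryError(
                            f"non-numeric range bound for numeric field {field!r}")
                    if (lo is None or lo <= value) and (hi is None or value <= hi):
                        return True
                else:
                    value = str(candidate).strip().lower()
                    lo = None if node.lo is OPEN else str(node.lo).strip().lower()
                    hi = None if node.hi is OPEN else str(node.hi).strip().lower()
                    if (lo is None or lo <= value) and (hi is None or value <= hi):
                        return True
        return False

    matched = tuple(
        i for i, record in enumerate(corpus)
        if holds(ast, flatten_record(record)))
    return ResultSet(matched=matched, total=len(matched))


def result_to_json(result: ResultSet, corpus: list[Any]) -> dict[str, Any]:
    """Serialize a result as ``{"total": n, "matchedSampleIds": [...]}``."""
    ids = [as_doc(corpus[i]).get("sampleId") for i in result.matched]
    return {"total": result.total, "matchedSampleIds": ids}
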