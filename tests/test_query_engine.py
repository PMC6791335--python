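"""Query parsing, flattening, and evaluation vs. the brute-force oracle."""

import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioscoop import (
    CohortConfig,
    brute_force_filter,
    evaluate,
    flatten_record,
    generate_cohort,
    parse_query,
)
from bioscoop.query_engine import (
    ALIASES,
    OPEN,
    BoolNode,
    FieldTerm,
    PhraseTerm,
    QueryError,
    QueryParseError,
    RangeTerm,
    ResultSet,
    UnknownFieldError,
)


class TestParseQuery:
    def test_basic_field_term(self):
        assert parse_query("gender:male") == FieldTerm("sex", "male")

    def test_phrase_term(self):
        assert parse_query('birthPlace:"Gdansk, Poland"') == PhraseTerm(
            "birthPlace", "Gdansk, Poland")

    def test_range_term(self):
        assert parse_query("bmi:[18 TO 23]") == RangeTerm("bmi", "18", "23")

    def test_open_bounds(self):
        assert parse_query("bmi:[* TO 23]") == RangeTerm("bmi", OPEN, "23")
        assert parse_query("bmi:[18 TO *]") == RangeTerm("bmi", "18", OPEN)

    def test_boolean_combination(self):
        ast = parse_query("gender:male AND bmi:[18 TO 23]")
        assert ast == BoolNode("AND", (FieldTerm("sex", "male"),
                                       RangeTerm("bmi", "18", "23")))

    def test_not_and_parentheses(self):
        ast = parse_query("(NOT gender:male) OR gender:male")
        assert ast == BoolNode("OR", (
            BoolNode("NOT", (FieldTerm("sex", "male"),)),
            FieldTerm("sex", "male")))

    def test_repeated_same_operator_is_nary(self):
        ast = parse_query("sex:male AND bmi:[18 TO 23] AND eyeColour:blue")
        assert ast.op == "AND" and len(ast.children) == 3

    @pytest.mark.parametrize("text", [
        "bmi:[23 TO 18]",                 # inverted numeric bounds
        "gender:male AND",                # dangling operator
        'birthPlace:"Gdansk',             # unbalanced quote
        "bmi:[18 TO 23",                  # unbalanced bracket
        "gender male",                    # missing colon
        "gender:",                        # missing value
        "a:1 AND b:2 OR c:3",             # mixed operators, no parentheses
        "bmi:{18 TO 23}",                 # exclusive ranges reserved
        "gender:male sex:female",         # bare juxtaposition
        "",                               # empty
        "   ",                            # blank
        "(gender:male",                   # unbalanced parenthesis
    ])
    def test_malformed_queries_raise_with_position(self, text):
        with pytest.raises(QueryParseError) as excinfo:
            parse_query(text)
        assert excinfo.value.position >= 0

    def test_lowercase_operators_are_not_keywords(self):
        # "and" is not an operator, so this is bare juxtaposition -> error
        with pytest.raises(QueryParseError):
            parse_query("gender:male and sex:female")

    def test_inverted_string_bounds_allowed(self):
        # only *numeric* inverted bounds are a parse error
        assert parse_query("birthPlace:[b TO a]") == RangeTerm("birthPlace", "b", "a")


class TestFlattenRecord:
    def test_gender_aliases_sex(self, valid_doc):
        view = flatten_record(valid_doc)
        assert view["sex"] == "male"
        assert ALIASES["gender"] == "sex"

    def test_icd10_is_multivalued(self, valid_doc):
        valid_doc["medicalEvents"].append(
            {"icd10Code": "I10", "eventType": "disease"})
        view = flatten_record(valid_doc)
        assert view["icd10"] == ["J45.1", "I10"]

    def test_absent_anthropometry_gives_no_bmi_key(self, valid_doc):
        del valid_doc["anthropometry"]
        assert "bmi" not in flatten_record(valid_doc)

    def test_dates_exposed_as_iso_strings(self, valid_doc):
        view = flatten_record(valid_doc)
        assert view["birthDate"] == "1975-04-12"
        assert view["timestamp"] == "2019-03-02"


def _mini_corpus(bmis):
    docs = []
    for i, value in enumerate(bmis):
        docs.append({
            "donorId": f"D{i}", "collectionId": "C", "sampleId": f"S{i}",
            "timestamp": "2019-01-01", "dataSource": "donor_questionnaire",
            "donor": {"birthDate": "1980-01-01", "sex": "male" if i % 2 else "female"},
            "anthropometry": {"bmi": value},
            "sample": {"materialForm": "serum"},
        })
    return docs


class TestEvaluate:
    def test_range_selects_only_values_inside(self):
        corpus = _mini_corpus([17.0, 20.0, 25.0])
        result = evaluate(parse_query("bmi:[18 TO 23]"), corpus)
        assert result == ResultSet((1,), 1)

    def test_fully_open_range_selects_records_having_the_field(self):
        corpus = _mini_corpus([17.0, 20.0])
        del corpus[0]["anthropometry"]
        result = evaluate(parse_query("bmi:[* TO *]"), corpus)
        assert result.matched == (1,)

    def test_excluded_middle_covers_whole_corpus(self):
        # a record without the field matches only through the NOT branch,
        # so term-or-negated-term is the full corpus
        corpus = _mini_corpus([17.0, 20.0, 25.0])
        del corpus[1]["anthropometry"]
        result = evaluate(parse_query("(NOT bmi:[* TO *]) OR bmi:[* TO *]"), corpus)
        assert result.matched == (0, 1, 2)

    def test_absent_field_matches_not_term(self):
        corpus = _mini_corpus([17.0, 20.0])
        del corpus[0]["anthropometry"]
        result = evaluate(BoolNode("NOT", (parse_query("bmi:[* TO *]"),)), corpus)
        assert result.matched == (0,)

    def test_string_match_is_case_insensitive(self, valid_doc):
        assert evaluate(parse_query("eyeColour:BLUE"), [valid_doc]).total == 1

    def test_range_boundaries_inclusive(self):
        corpus = _mini_corpus([18.0, 20.5, 23.0])
        result = evaluate(parse_query("bmi:[18 TO 23]"), corpus)
        assert result.matched == (0, 1, 2)

    def test_point_range_matches_exact_value(self):
        corpus = _mini_corpus([18.0, 20.5])
        result = evaluate(parse_query("bmi:[20.5 TO 20.5]"), corpus)
        assert result.matched == (1,)

    def test_unknown_field_is_a_hard_error(self, valid_doc):
        with pytest.raises(UnknownFieldError, match="shoeSize"):
            evaluate(FieldTerm("shoeSize", "44"), [valid_doc])
        with pytest.raises(UnknownFieldError):
            evaluate(FieldTerm("shoeSize", "44"), [])  # even on an empty corpus

    def test_non_numeric_bound_on_numeric_field(self, valid_doc):
        with pytest.raises(QueryError, match="non-numeric"):
            evaluate(RangeTerm("bmi", "low", "high"), [valid_doc])

    def test_multivalued_icd10_matches_any_code(self, valid_doc):
        valid_doc["medicalEvents"].append(
            {"icd10Code": "I10", "eventType": "disease"})
        assert evaluate(parse_query("icd10:I10"), [valid_doc]).total == 1
        assert evaluate(parse_query("icd10:J45.1"), [valid_doc]).total == 1
        assert evaluate(parse_query("icd10:C50.9"), [valid_doc]).total == 0


class TestBruteForceOracle:
    def test_empty_corpus_gives_empty_result(self):
        assert brute_force_filter(parse_query("sex:male"), []) == ResultSet((), 0)

    def test_singleton_match(self, valid_doc):
        assert brute_force_filter(parse_query("sex:male"), [valid_doc]).matched == (0,)


# ---------------------------------------------------------------------------
# Property: evaluate == brute_force_filter for random ASTs over real cohorts

_CORPORA = {
    seed: generate_cohort(CohortConfig(n_records=30, seed=seed))
    for seed in (0, 1, 2)
}

_string_terms = st.one_of(
    st.tuples(st.just("sex"), st.sampled_from(["male", "female", "other"])),
    st.tuples(st.just("birthPlace"),
              st.sampled_from(["Gdansk, Poland", "Lodz, Poland", "Oslo, Norway"])),
    st.tuples(st.just("eyeColour"),
              st.sampled_from(["brown", "blue", "green", "grey"])),
    st.tuples(st.just("bloodGroup"), st.sampled_from(["A+", "O-", "AB+"])),
    st.tuples(st.just("icd10"), st.sampled_from(["J45.1", "I10", "E11.9", "Z99"])),
    st.tuples(st.just("materialForm"), st.sampled_from(["serum", "dna", "tissue"])),
)

_field_term = _string_terms.map(lambda fv: FieldTerm(*fv))
_phrase_term = _string_terms.map(lambda fv: PhraseTerm(*fv))


@st.composite
def _range_term(draw):
    field = draw(st.sampled_from(["bmi", "whr", "ci", "heightCm", "weightKg",
                                  "waistCm", "hipCm", "birthDate", "timestamp"]))
    if field in ("birthDate", "timestamp"):
        dates = st.dates(min_value=datetime.date(1940, 1, 1),
                         max_value=datetime.date(2020, 1, 1))
        lo, hi = sorted(draw(st.tuples(dates, dates)))
        lo, hi = lo.isoformat(), hi.isoformat()
    else:
        a, b = sorted(draw(st.tuples(
            st.floats(min_value=0.1, max_value=250, allow_nan=False),
            st.floats(min_value=0.1, max_value=250, allow_nan=False))))
        lo, hi = f"{a:.2f}", f"{b:.2f}"
    if draw(st.booleans()):
        lo = OPEN
    if draw(st.booleans()):
        hi = OPEN
    return RangeTerm(field, lo, hi)


_terms = st.one_of(_field_term, _phrase_term, _range_term())


def _combine(children):
    ops = ["AND", "OR"]
    return st.one_of(
        st.tuples(st.sampled_from(ops), st.lists(children, min_size=2, max_size=3))
        .map(lambda t: BoolNode(t[0], tuple(t[1]))),
        children.map(lambda c: BoolNode("NOT", (c,))),
    )


_queries = st.recursive(_terms, _combine, max_leaves=6)


class TestOracleEquivalence:
    @settings(max_examples=400)
    @given(ast=_queries, seed=st.sampled_from(sorted(_CORPORA)))
    def test_evaluate_matches_brute_force(self, ast, seed):
        corpus = _CORPORA[seed]
        assert evaluate(ast, corpus) == brute_force_filter(ast, corpus)

    @settings(max_examples=100)
    @given(ast=_queries)
    def test_boolean_algebra_laws(self, ast):
        corpus = _CORPORA[0]
        base = evaluate(ast, corpus)
        # idempotence
        assert evaluate(BoolNode("AND", (ast, ast)), corpus) == base
        # double negation (complement over the whole corpus)
        assert evaluate(BoolNode("NOT", (BoolNode("NOT", (ast,)),)), corpus) == base

    @settings(max_examples=100)
    @given(a=_terms, b=_terms)
    def test_de_morgan(self, a, b):
        corpus = _CORPORA[1]
        lhs = evaluate(BoolNode("NOT", (BoolNode("OR", (a, b)),)), corpus)
        rhs = evaluate(BoolNode("AND", (BoolNode("NOT", (a,)),
                                        BoolNode("NOT", (b,)))), corpus)
        assert lhs == rhs

    @settings(max_examples=100)
    @given(lo=st.floats(min_value=10, max_value=40),
           delta=st.floats(min_value=0, max_value=20),
           widen=st.floats(min_value=0, max_value=10))
    def test_widening_a_range_never_shrinks_the_result(self, lo, delta, widen):
        corpus = _CORPORA[2]
        narrow = RangeTerm("bmi", f"{lo}", f"{lo + delta}")
        wide = RangeTerm("bmi", f"{lo - widen}", f"{lo + delta + widen}")
        assert set(evaluate(narrow, corpus).matched) <= set(
            evaluate(wide, corpus).matched)
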