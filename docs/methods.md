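# Methods

`bioscoop` implements a sample-communication format for biobanks: a JSON
document schema describing one biological sample together with its donor,
plus the surrounding workflow a biobank would actually run — exporting
tabular data, converting it to the exchange format, validating it, and
searching a document set with Lucene/Solr-style queries. This note records
the model, the defaults, and the design choices where the design was
genuinely open.

## The record model

The unit of exchange is a flat sample-level document: one JSON object per
(donor, sample) pair, carrying

- identifiers: `donorId`, `collectionId`, `sampleId` (non-empty after
  trimming; `sampleId` unique within a document set, which also makes
  (`donorId`, `sampleId`) pairs unique);
- a record `timestamp` (ISO 8601 calendar date) and a `dataSource`
  provenance tag (`donor_questionnaire` | `medical_record` |
  `physical_measurement`);
- a donor block: birth date and sex (required), plus optional birth and
  residence place ("City, Country" free text), ethnic origin, skin tone
  (Fitzpatrick-style ordinal `I`–`VI`, kept ordinal so range queries stay
  meaningful), hair and eye colour, and ABO/Rh blood group. Optionality is
  a deliberate choice: questionnaires are incomplete in practice, and the
  synthetic generator needs optional fields to exercise missingness;
- an optional anthropometry block: height, waist and hip in centimetres,
  weight in kilograms, an open `extras` map for further named measurements,
  and the derived indices WHR, BMI and CI;
- zero or more medical events, each an ICD-10 code (validated by the
  pattern `^[A-Z][0-9]{2}(\.[0-9]{1,2})?$`, not against a code list; a
  pluggable code-list hook ships empty so no external vocabulary download
  is required), an event type (disease/procedure), and an optional date;
- a sample block with the material form (whole blood, serum, plasma, DNA,
  RNA, saliva, tissue, urine, other).

Cross-field rules: no dated field may precede the donor's birth date, and
stored derived indices must agree with recomputation (below). Unknown keys
are ignored by the validator for forward compatibility.

A JSON Schema (draft 2020-12) document ships in `bioscoop/data/` as the
machine-readable description of the format. The executable validator is the
rule engine in `schema_model`, which additionally enforces the cross-field
and cross-record rules plain JSON Schema cannot express and reports stable
`rule_id`s per violation; a test keeps the schema document's enum
catalogues and patterns in sync with the code.

## Derived indices

With weight *w* (kg), height *h* (m), waist *wc* and hip *hc* (any common
length unit):

- BMI = *w* / *h*² (kg/m²),
- CI (corpulence/Rohrer's/ponderal index) = *w* / *h*³ (kg/m³),
- WHR = *wc* / *hc* (dimensionless),

so CI·*h* = BMI identically. These are the universally accepted definitions
of the named indices; they are centralized in `derived_metrics` so a
divergent convention could be swapped in one place. Heights are stored in
centimetres and converted to metres inside the formulas. Inputs must be
strictly positive and finite; nothing is rounded at computation time.

`enrich_record` fills an absent index from its raw inputs and *flags* —
never overwrites — a stored index that disagrees with recomputation:
exchange software must not silently alter payloads.

## Canonical form and numeric tolerance

Canonicalization gives every valid record a unique byte representation:
dates zero-padded ISO 8601, enum values in catalogue spelling (lower-case
except blood group and skin tone), identifiers trimmed, keys sorted at
every level, and numbers rounded to 6 decimal places. Round-trips and
equality comparisons are exact on canonical documents, and the
transformation is idempotent.

Stored-vs-recomputed agreement for WHR/BMI/CI is judged at relative 1e-6
*after canonicalization*: values agree if the relative test passes or both
round to the same 6-decimal canonical form. The second clause matters for
small WHR values (< 0.5), where the 6-decimal rounding step itself (absolute
error up to 5e-7) can exceed a purely relative 1e-6 band; comparing at
canonical precision keeps "round-trip through the canonical form" and
"consistent" from contradicting each other.

## CSV conversion

CSV is read per RFC 4180 (stdlib `csv`): quoted fields, embedded delimiters
and newlines, configurable single-character delimiter, UTF-8 with BOM
tolerated. A ragged row or duplicate header is an immediate format error
naming the row; content problems never are.

Rows map onto the nested schema through an explicit `ColumnMapping`
(column → dotted field path, a date format, and a set of missing-value
tokens, default `"", NA, null`) rather than header-name guessing — the
mapping is a reviewable config artefact. List-valued fields use indexed
paths: the default mapping encodes up to five medical events as column
triples `icd10Code1..5` / `eventType1..5` / `eventDate1..5`, which keeps the
CSV flat and the converter generic. Rows that fail to parse or validate are
skipped and reported with the row index, so converted records plus flagged
rows always account for every input row.

## The synthetic cohort

`generate_cohort` emulates a biobank's test export: 200 records by default,
all randomness from one seeded `random.Random` (no wall clock or OS
entropy), so one seed is one byte-identical cohort. Defaults:

- birth years 1940–2004 (adult donors), record timestamps in 2018–2019,
  so timestamps always postdate birth;
- anthropometry uniform over height 140–210 cm, weight 40–150 kg, waist
  50–150 cm, hip 60–160 cm, rounded to 0.1; WHR/BMI/CI always filled from
  the raw draws at canonical precision;
- sex uniform over {male, female}; pigmentation, blood group and material
  form uniform over their catalogues; places, ethnic origins and ICD-10
  codes uniform over small packaged pools that include "Gdansk, Poland",
  so the canonical phrase query has data to match;
- 0–5 medical events per donor, each dated with probability 0.8 between
  birth and the record timestamp;
- each optional donor field and each extra measurement independently
  missing at rate 0.05 (enough to exercise missing-token handling without
  hollowing out the cohort);
- IDs zero-padded (`DON-0001`, `SAM-0001`), collections drawn from five
  `COL-0k` labels, `dataSource` fixed to `donor_questionnaire`.

Distributions are deliberately uniform and independent. The generator does
**not** emulate real joint structure — no sex-specific anthropometry, no
comorbidity correlation, no realistic ICD-10 prevalence — so passing tests
demonstrate format, conversion and query correctness, not epidemiological
realism.

## The query engine

The grammar is the familiar Solr subset: `field:value`,
`field:"a phrase"`, `numeric:[lo TO hi]`, combined with upper-case `AND` /
`OR` / `NOT` and parentheses; `*` is an open bound; `gender` aliases the
stored `sex` field. Records are flattened to one flat view per record
(event codes become the multi-valued field `icd10`; dates become ISO
strings so lexicographic order is chronological), and evaluation is set
algebra over record-index sets.

Semantics chosen where Solr's are configurable or surprising, each picked
for predictability when the result is a medical-sample cohort:

- matching is exact full-string, case-insensitive — never tokenized or
  stemmed;
- mixing `AND` and `OR` at one level without parentheses is a parse error
  instead of Lucene's non-boolean precedence;
- bare juxtaposition of clauses (Solr's configurable default operator) is
  likewise rejected;
- ranges are inclusive only; `{exclusive}` ranges are reserved and raise
  a parse error, as does a numerically inverted range;
- an absent field never satisfies a positive term but does satisfy `NOT`
  (complement over the whole corpus), matching Lucene;
- an unknown field name is a hard error, not an empty result.

`brute_force_filter` is a second, independent implementation — a recursive
per-record truth test with no set algebra — kept solely to cross-check
`evaluate`; the test suite and the acceptance script compare the two on
1000 randomly generated (query, cohort) pairs. `extras` measurements are
not exposed as query fields; the query surface is the fixed schema.

## Problem sizes and verification

The shipped verification workflow uses the scale the format was exercised
at: one 200-record cohort for generation/validation and the three example
queries; twenty 50-record cohorts for CSV→JSON pipeline closure; five
30-record corpora × 200 random queries (1000 pairs) for engine/oracle
equivalence; property-based suites (hypothesis, derandomized) for parser,
algebraic and round-trip invariants. All quantities reported by
`scripts/acceptance.py` are recomputed from scratch on each run from the
given seed.

## Known limitations

- The field catalogue is the enumerated core plus the `extras` map; a
  fuller attribute list would extend `FIELD_TYPES` and the JSON Schema.
- ICD-10 validation is syntactic unless a code list is installed.
- The query engine holds the corpus in memory and rescans per query; it is
  a semantic stand-in for an index-backed search service, adequate for
  desk-scale corpora, not a search engine.
- CSV ingestion loads the whole table; multi-gigabyte streaming is out of
  scope.
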