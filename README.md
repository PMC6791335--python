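# bioscoop

A reference implementation of **BioSCOOP**, a biobank sample-communication
format: a JSON document schema for exchanging donor-plus-sample
descriptions between biobanks, together with the workflow around it —
CSV-to-JSON conversion, validation, a deterministic mock-cohort generator,
and a Solr-style query engine for sample search.

Biobanks store biological samples alongside donor phenotype and medical
data, but institutions run heterogeneous IT systems, so *finding* samples
across repositories ("female donors from Gdansk with BMI between 18 and
23, with an asthma diagnosis, serum available") requires a shared record
format and a query surface over it. `bioscoop` provides both at library
scale, for biobank data managers and researchers assembling cross-site
sample sets.

## The record and its indices

One document describes one (donor, sample) pair: identifiers
(`donorId`, `collectionId`, `sampleId`), a timestamp and data-source
provenance tag, a donor phenotype block (birth date, birth/residence
place, sex, ethnic origin, skin tone I–VI, hair and eye colour, blood
group), ICD-10 coded diseases and procedures, the sample material form,
and an anthropometry block carrying raw measurements with the standard
derived indices

- **BMI** = w / h² (kg/m², height in metres),
- **CI** (corpulence / Rohrer's index) = w / h³ (kg/m³),
- **WHR** = waist / hip (dimensionless),

which the package computes, validates for internal consistency (relative
1e-6 at canonical 6-decimal precision), and exposes to range queries.
Validation reports one violation per broken rule with a stable rule id;
canonicalization gives every valid record a unique byte representation so
round trips are exact.

Queries use the Lucene/Solr syntax: `gender:male`,
`birthPlace:"Gdansk, Poland"`, `bmi:[18 TO 23]`, combined with
`AND`/`OR`/`NOT` and parentheses. Evaluation is in-memory and
cross-checked against an independent brute-force oracle.

## Worked example

Generate a 200-record mock cohort, validate it, and search it:

```
$ bioscoop generate --n 200 --seed 1 --out cohort.json
generate: seed=1 records=200 out=cohort.json

$ bioscoop validate --in cohort.json
200 records, 0 violations

$ bioscoop search --in cohort.json --query 'gender:male AND bmi:[18 TO 23]'
search: in=cohort.json corpus=200 total=9
{
  "total": 9,
  "matchedSampleIds": [
    "SAM-0029",
    "SAM-0054",
    ...
  ]
}
```

9 of the 200 mock donors are male with a body-mass index between 18 and
23 kg/m² inclusive; the sample IDs identify which documents matched.
Exit codes: 0 clean, 1 validation failures present, 2 usage/query-parse
error, 3 I/O error.

The same pipeline from Python, including the CSV leg a real biobank export
would take:

```python
import io
from bioscoop import (CohortConfig, generate_cohort, write_cohort_csv,
                      read_csv_table, rows_to_records, default_mapping,
                      parse_query, evaluate)

cohort = generate_cohort(CohortConfig(n_records=200, seed=1))
buf = io.StringIO(); write_cohort_csv(cohort, buf)          # export
table = read_csv_table(io.StringIO(buf.getvalue()))          # re-ingest
records, report = rows_to_records(table, default_mapping())  # CSV -> JSON
assert report.valid and len(records) == 200
print(evaluate(parse_query("bmi:[18 TO 23]"), records).total)  # -> 26
```

## Layout

- `src/bioscoop/schema_model.py` — record types, validator, canonical form
- `src/bioscoop/derived_metrics.py` — WHR/BMI/CI and record enrichment
- `src/bioscoop/io_convert.py` — RFC 4180 CSV, column mapping, BioSCOOP JSON
- `src/bioscoop/synthetic_cohort.py` — seeded mock-cohort generator
- `src/bioscoop/query_engine.py` — query parser, evaluator, brute-force oracle
- `src/bioscoop/cli.py` — `bioscoop generate|convert|validate|search`
- `src/bioscoop/data/` — JSON Schema, default column mapping, value pools
- `docs/methods.md` — model, defaults, and design choices in detail

Related community standards — MIABIS, BRISQ, SPREC for biospecimen
description, ICD-10 for diagnoses — inform the field catalogue; no
cross-walk to them is implemented.
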