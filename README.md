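# ehrtql

A temporal query language (TQL) and in-memory patient datastore for
time-aware cohort search over longitudinal electronic health records —
electronic phenotyping, cohort extraction, and labeled-data generation,
expressed as short declarative queries instead of hundreds of lines of SQL
joins.

## Who this is for

Clinical informaticians and data scientists who need to answer questions
like *"male patients over 65 with type II diabetes, no history of stroke,
who went on to have a stroke within 3 months of starting glipizide"*
against OMOP-CDM-shaped data, and to get back not just the patient ids but
the **time intervals** at which each patient satisfied the definition.

## The model

Every TQL expression evaluates, per patient, to a canonical set of
half-open day intervals `[start, end)` on that patient's timeline (day
resolution, integer days since 1900-01-01). On top of this value space the
language provides

* a **Boolean algebra** — `AND`, `OR`, `NOT` — over the *patient level*
  ("ever had a record of …", returning the whole observation span or
  nothing), and
* a **temporal algebra** — `UNION`, `INTERSECT`, `INVERT`,
  `SEQUENCE(a, b*) ± (lo, hi)`, `COUNT`, `FIRST MENTION`,
  `NO HISTORY OF`, `NEVER HAD`, `DIFF` — over interval sets, where
  `SEQUENCE` windows test event-start offsets (`+` requires an event of the
  other operand inside `[start+lo, start+hi]`, `-` forbids one),

plus **feature selectors** for diagnosis and procedure codes
(`ICD9=`, `ICD10=`, `CPT=`), drugs (`RX=`, `ATC=`), laboratory values
(`LABS("code", lo, hi)`), demographics (`GENDER=`, `RACE=`, `AGE(lo, hi)`),
calendar windows (`YEAR`), and pre-extracted note mentions (`TEXT`).
Programs name intermediate definitions with `var` and reference them as
`$name`.

Two implementation ideas make this fast and trustworthy:

1. **Patient objects + a feature index.** All of a patient's data live in
   one object; an inverted index (feature key → patient ids) prunes, per
   query, the patients that could possibly match before full evaluation.
   The pruning is structural and *sound* — negation-bearing branches widen
   to all patients — so indexed execution is bit-identical to a full scan
   (a tested invariant).
2. **Knowledge-graph expansion at load time.** A patient coded ICD9
   `250.02` also answers queries for `250.0` and `250`; RxCUI `161`
   (acetaminophen) gains its ATC classes `N02BE`, `N02B`, `N02`, `N`.
   `ORIGINAL(...)` bypasses expansion.

## Worked example

Generate a seeded synthetic cohort with planted diabetes→glipizide→stroke
trajectories, then run the diabetes/stroke cohort definition:

```python
from ehrtql import synth, engine, fixtures, output

spec = synth.default_specs()["diabetes_stroke"]   # 400 patients
store, truth = synth.build_store(spec, seed=1)
result = engine.execute(fixtures.box_program(1), store)
print(len(result))                     # 62
print(result.matches["P000003"])       # IntervalSet([41603,41604))
```

62 of 400 patients qualify; the matched interval for `P000003` is day
41603 — 2013-11-27, the day of the planted stroke that followed glipizide
within the 3-month window. `truth` is the generator's ground-truth table,
and the result matches it patient-for-patient and day-for-day. A cohort
summary reproduces the planted structure:

```python
s = output.summarize(result, store, k=3)
s.n_patients        # 62
s.gender_counts     # {'male': 62}          (the query requires GENDER="male")
s.age_histogram     # {'70-79': 36, '80-89': 25, '90-99': 1}
s.top_features["ICD"][0]   # ('434.91', 62)  — every match has the stroke code
```

The same pipeline is available from the shell:

```bash
ehrtql synth --spec diabetes_stroke --seed 1 --out demo/
ehrtql etl   --omop demo/ --out demo-store/ --shards 4
ehrtql query --data demo-store/ --query my_query.tql --out-format json
```

`query` accepts `json` (patient ids + ISO-date intervals), `csv`,
`summary` (demographic histograms and top codes), and `timelines`
(per-patient interval tracks per variable). Programs whose final command is
`EXPORT($cohort, TIME=$expr, "label"=$expr, ...)` produce flat labeled
tables — one row per matched patient with the time the definition first
became true — for training-data generation.

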