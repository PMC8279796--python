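# Methods

## Value space and boundary conventions

Every query evaluates per patient to a canonical interval set: sorted,
pairwise disjoint, non-adjacent half-open day intervals `[start, end)`,
with days counted from 1900-01-01. A point event on day *d* is `[d, d+1)`.
Half-open intervals make adjacency and merging unambiguous: `[0,5)` and
`[5,9)` coalesce to `[0,9)`, and `[0,5) ∩ [5,9) = ∅`. Day resolution is
deliberate — the source data types are date-stamped; sub-day timing is out
of scope.

A canonical interval set over a bounded span is equivalent to the set of
integer days it covers. This equivalence is the backbone of verification:
an independent interpreter (`ehrtql.dayset`) evaluates every construct
directly on Python day sets (recovering "intervals" as maximal consecutive
runs) and shares no code with the fast interval-algebra path. The test
suite and the acceptance script check exact agreement between the two
semantics on tens of thousands of random ASTs over spans ≤ 5,000 days.

## Operator semantics

* `UNION` / `INTERSECT` — coalesced union / pairwise intersection of the
  operand interval sets.
* `INVERT(x)` — complement of `x` within the patient's observation span;
  double inversion restores `x` clipped to the span.
* `AND` / `OR` / `NOT` — patient-level ("at any time") predicates over
  operand non-emptiness, returning the whole span or the empty set. The
  span-valued convention keeps Boolean results composable with the temporal
  operators (`INTERSECT(AND(...), ...)` behaves as expected). The exact
  interval value of Boolean operators is not pinned down by the language
  description; this convention is this implementation's choice.
* `SEQUENCE(a, b*)` — returns the starred operand's intervals. Without a
  window, a non-starred interval must start strictly before (star on
  second) or strictly after (star on first) the starred interval's start;
  same-day events do not satisfy "followed by". With a window `±(lo, hi)`,
  ordering is replaced by the window test: a `+` (presence) window keeps a
  starred interval starting at *s* iff some non-starred interval starts in
  `[s+lo, s+hi]`; a `-` (absence) window keeps it iff none does. Windows
  anchor on **start** days and are inclusive at both ends. This anchoring
  reproduces both the "outcome within 3 months of exposure" idiom
  (`SEQUENCE($expo,$outcome*)+(-3 MONTHS, 0)`) and look-back exclusion
  idioms (`SEQUENCE($comorbidity,$index*)-(-1 YEAR, 1 DAY)`).
* `COUNT(x, min, max)` — passes `x` through unchanged when the number of
  its **coalesced disjoint intervals** is within bounds, else empty. Two
  records on the same day therefore count once; "at least 2 occurrences"
  means two distinct (non-adjacent) days. Counting rows instead would make
  duplicate coding satisfy recurrence criteria, which is rarely intended.
* `FIRST MENTION(x)` — the single earliest interval.
* `NO HISTORY OF(x)` — the whole span when `x` is empty, else
  `[span.start, first(x).start)` (empty if `x` starts at or before the
  span).
* `NEVER HAD(x)` — the whole span when `x` is empty, else empty.
* `DIFF(a, b)` — patient-level subtraction that keeps `a`'s intervals when
  `b` is empty (used for numerator = denominator minus treated).
* `AGE(lo, hi)` — `[birth + lo, birth + hi)` clipped to the span, with
  `MAX` unbounded. Durations use fixed lengths: 1 `DAY` = 1, 1 `MONTH` =
  30, 1 `YEAR` = 365 days. Fixed units keep the algebra calendar-free and
  reproducible; the ±1.25 %/year drift versus calendar years is immaterial
  at cohort-definition granularity but means, e.g., "AGE(64 YEARS)" falls
  a couple of weeks before the 64th calendar birthday.
* `LABS("code", lo, hi)` — measurement events with value in `[lo, hi]`.
* `GENDER=` / `RACE=` — attribute match (case-insensitive, since published
  queries mix `"male"` and `"FEMALE"`), returning the whole span.
* `TEXT("phrase", FLAG...)` — pre-extracted note mentions whose flag set
  (subset of NEGATED, FAMILY_HISTORY) equals the requested flags; a bare
  `TEXT("x")` therefore matches only affirmative, non-family-history
  mentions. Text processing itself is out of scope — the ETL consumes a
  pre-extracted mention table.
* `YEAR(lo, hi)` — calendar-year window clipped to the span (the one
  selector that consults the real calendar).
* `ORIGINAL(selector)` — restricts evaluation to source-data events,
  bypassing knowledge-graph expansion.

## Knowledge-graph expansion

Expansion happens once at load: for every original ICD9/ICD10 event, a
derived event (flagged non-original) is added at the same interval for each
ancestor in the terminology DAG (reflexive-transitive closure excluding the
code itself); every RX event additionally yields ATC-namespace events for
its mapped ATC classes and their ancestors. Expansion never changes
intervals, values, or spans, and is idempotent. Ontologies are plain
`child,parent` edge-list CSVs (cycles rejected at load) plus a
`rxcui,atc` mapping; the packaged fixture ontologies (~50 codes) cover the
codes used in the fixture queries, and full vocabularies drop in through
the same files. ICD9 and ICD10 are independent hierarchies; CPT is not
expanded (no hierarchy is attested for it here), and used-to-treat edges
are a format-compatible extension left unimplemented.

## Two-phase execution

`candidate_set` computes a structural over-approximation from the feature
index: selectors map to index postings (demographic postings are carried in
the index alongside event keys so that `GENDER="male"` can prune);
`OR`/`UNION` take unions, `AND`/`INTERSECT`/`SEQUENCE` intersections of
operand candidates; any negation-bearing branch (`NOT`, `INVERT`,
`NO HISTORY OF`, `NEVER HAD`, `DIFF`'s second operand, absence windows)
widens to all patients, which preserves soundness. Full evaluation then
runs only over candidates, with per-patient memoization of variable values
(well-defined because `$refs` are forward-only). The defining correctness
property — indexed execution equals brute-force evaluation of every
patient, exactly — is asserted over 100 random core-command queries on a
10,000-patient store in both the test suite and the acceptance script.

Stores serialize to autonomous JSON shard files partitioned by a CRC32 hash
of the patient id, with a JSON manifest; any subset of shards reloads into
a store whose query results are exactly the restriction to those patients.
Single-process only; multi-node distribution and the memory-compression
encoding of the original system are non-goals.

## ETL conventions

The loader reads an OMOP-CDM-v5.3-subset directory (`person` and
`observation_period` mandatory; `condition_occurrence`,
`procedure_occurrence`, `drug_exposure`, `measurement`, `text_mention`
optional). Codes come from `*_source_value` columns — `NS:code` prefixes
for conditions/procedures, bare RxCUI / LOINC strings for drugs and
measurements — rather than concept-id joins, so queries use source
terminologies directly and no vocabulary tables need shipping. Drug
exposures with an end date become multi-day intervals (inclusive end date →
half-open interval); no era construction is performed, since coalescing
happens in the algebra anyway. Events are clipped to the observation
period; events wholly outside it are dropped with a logged warning, giving
`INVERT`/`NO HISTORY OF` a well-defined universe. Persons without an
observation period are skipped with a warning. Demographics are stored as
patient attributes, not events.

## Synthetic cohorts and ground truth

The generator emits one population per fixture query. Each patient draws a
role from a prevalence table: a qualifying trajectory (e.g. two type II
diabetes codes ≥ 20 days apart, glipizide 10–120 days later, stroke 2–85
days after that, male, born 1930–1941 so the age criterion holds at event
time) or a near-miss control violating exactly one criterion (female
counterpart, too-young counterpart, stroke before diagnosis, stroke outside
the 90-day window, no stroke; analogously for the bronchitis, trial-
eligibility and labeling cohorts). Background noise — hypertension and
respiratory codes, office visits, normal-range HbA1c values, note mentions
— is Poisson per code-year from pools chosen disjoint from each query's
code set, so planted roles alone decide membership. Inter-event gaps are
uniform integers over stated ranges, never smaller than 2 days where
recurrence counting is at stake (same-day events would coalesce).

All randomness flows from a single seed through per-patient
`default_rng([seed, i])` streams: output is byte-identical across runs and
growing the population never alters existing patients. Before
`ground_truth.csv` is written, the generated tables are loaded through the
standard ETL and the fixture query is evaluated with the independent
day-set interpreter; generation aborts if the verified matched set differs
from the planted qualifying set. The truth table records each matched
patient and the first day the definition was satisfied.

Default sizes (400/400/300/300 patients; 10,000 for the index/scan
experiment) keep the full pipeline at around a minute on one CPU while
leaving dozens of positives per cohort. What these fixtures do **not**
emulate: realistic code co-occurrence and visit structure, calendar
seasonality, measurement units beyond `%`, censoring, or terminology noise
— passing tests demonstrate the engine's semantics, not clinical validity
of any definition on real data.

## Numerical and degenerate-input choices

Intervals with `start ≥ end` are rejected at construction. Empty interval
sets are first-class (a non-matching patient). `COUNT` bounds and window
bounds are validated (`min > max` rejected); `MAX` sentinels are unbounded
ends. Unknown codes, unknown index keys and unmapped RxCUIs yield empty
results, never errors. Ties in summary "top features" break
lexicographically. The parser requires fully parenthesized command calls
(all attested queries are), treats keywords case-insensitively, and accepts
the juxtaposed `varname=` form exactly as published; the attested command
set is the whole grammar, and anything else fails with an "unknown
command" error rather than guessing.

## Known limitations

* Fixed-length months/years (30/365 days) shift long windows slightly
  against the calendar.
* The index carries no value or time information, so `LABS`-heavy or
  negation-heavy queries prune little (they remain correct).
* `AGE(lo, hi)` is right-open at `birth + hi`: `AGE(18 YEARS, 64 YEARS)`
  ends at the fixed-length 64th birthday rather than including the whole
  65th year; definitions needing "through age 64 inclusive" should write
  `AGE(18 YEARS, 65 YEARS)`.
* Whether recurrence counts should be per visit rather than per distinct
  day is data-model dependent; this implementation counts distinct
  coalesced intervals.
* The day-set oracle is quadratic in span length and intended only for
  verification, not production evaluation.
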