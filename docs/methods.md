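# Methods

## Assessment model

`cdmaudit` treats completeness as three measurable layers over a declared
expected schema (the *manifest*):

**Structural.** Each manifest table is classified into exactly one of
`available` (queryable, ≥1 record), `empty` (queryable, 0 records) or
`not_available` (not queryable). The denominator for the aggregate
percentages is always the manifest size — an absent table counts against the
schema, because the schema is what a study plans against. Volume profiling
orders available tables by storage bytes; byte counts are exact file sizes
for the delimited dialect and an engine-derived approximation (summed
serialised cell lengths) for SQLite, so volume comparisons are only made
within the delimited dialect. Interpretation is attached mechanically from
two manifest flags: `derived` (era tables exist only if ETL derivation
scripts ran, so *empty + derived → derived-table-not-populated*) and
`holds_free_text` (*absent + free text → free-text-capture-gap*).

**Rule engine.** Rules are declarative YAML entries
(`id/kind/table/column/params/semantic_class`) evaluated against the dataset;
the engine reads each table at most once per run and never throws on an
absent table (it returns a `not_applicable` result — absence is itself a
structural finding, not an error). The four kinds:

- *missing_or_special*: a value is flagged when missing, or after trimming is
  empty, equals a sentinel string (default `NULL`, `NA`, `N/A`, `UNKNOWN`,
  case-insensitive), or consists solely of characters from
  `* - . ? # / \ + , _`. There is no canonical definition of a "special
  character entry" in source-value fields; this class is the package's
  documented default and is overridable per rule. An absent column flags
  every record with a `column-absent` warning: an uncollected column is the
  strongest form of incompleteness, and the warning keeps it distinguishable.
- *unmapped_concept*: concept id missing or 0 (the reserved "No matching
  concept" id). Counted in rows, or in distinct persons having at least one
  unmapped record (the default, matching how unmapped-concept findings are
  usually stated per person).
- *temporal_discontinuity*: events are bucketed per concept × calendar month
  (ISO-8601 dates; unparseable dates are excluded and counted). Within a
  concept's first-to-last observed month, zero-count months are filled in by
  default (configurable: `fill_gap_months=false` compares observed months
  only). A transition from `c_{t−1} > 0` flags when `c_t = 0` or
  `|c_t − c_{t−1}|/c_{t−1} ≥ threshold` (default 1.0, i.e. a 100% change,
  direction-free). A rise from zero is an *onset* and never flags —
  otherwise every concept's first active month would fire. Flagged/total are
  concept counts; the detail payload lists each flagged concept with its
  first offending month pair, sorted by concept, so output is independent of
  record order.
- *value_range*: strict bounds — `value > bound` flags under `max_le`
  (a value equal to the bound passes), `value < bound` under `min_ge`.
  Non-numeric values are skipped and counted separately rather than guessed.

Percentages everywhere are `100·flagged/total` computed on exact rationals
and rounded half-up to one decimal; this is the rounding that makes low-count
fractions such as 5/39 → 12.8 and 7/39 → 17.9 stable and reproducible.

A rule's `semantic_class` separates detection from meaning. The default
`incompleteness` yields the `deficit` interpretation; `expected_null` yields
`valid_by_default` without changing flagged/total. The motivating case is
the vocabulary `invalid_reason` column, which is NULL unless a concept or
relationship was deprecated: near-100% missingness there indicates healthy
vocabularies, and the report layer must never turn it into a deficit
finding.

**Profiling.** Demographic (sex/race/ethnicity) and per-person concept
profiles count distinct persons; a person is never double-counted within a
category, and overlapping categories (visit types) may sum above 100%.
Vocabulary profiles count table rows; vocabularies individually below 0.5%
of rows collapse into "Other" (configurable), and unresolvable concept ids
are reported under "Unmapped/Unknown" rather than dropped. Labels come from
a concept dictionary (CSV: `concept_id, concept_name, vocabulary_id,
domain_id`) with id 0 reserved for "No matching concept" and unknown ids
rendered `concept:<id>`; profiling must not fail on dictionary gaps. There
is deliberately no reference distribution or statistical balance test: the
profiles are inputs to a fitness-for-use judgement, not a verdict.

## Dataset access

One reader contract over two dialects: a directory of RFC-4180 CSVs
(`<table>.csv`, header row) and single-file SQLite. Missingness is
normalised on read — an empty delimited field and a database NULL map to the
same internal sentinel (additional literal sentinels are configurable,
default none). All values surface as strings; numeric/date parsing happens
in the rule that needs it. Headers match case-insensitively. This is what
makes dialect equivalence exact: the acceptance suite asserts the full audit
(structure minus byte sizes, rules, profiles) is identical across storages
of the same data.

## Synthetic data

The generator emulates the statistical structure the assessment consumes and
nothing more: no disease trajectories, visit careflows or dosing logic.

`generate_clean` writes all 39 manifest tables, populated and internally
consistent (every event references an existing person, concept ids come from
the dictionary pools and exclude 0, rule-targeted string columns hold benign
values, numerics sit inside their bounds). Defaults: 100 persons, coverage
span January 2005 – December 2023 (the span a mature hospital CDM typically
covers), per-domain event means of 1–5 events per person — small enough for
test suites, scalable by configuration. Event dates are engineered, not
uniform-random: each concept's events are spread so monthly counts within its
active span never rise and never drop to zero (counts differ by at most one,
non-increasing), so the clean dataset is silent under the temporal detector
by construction. All randomness flows through one seeded NumPy generator;
a fixed config is byte-identical across runs.

`apply_defects` plants seven defect kinds (missing value, special value,
unmapped concept, temporal gap, out-of-range value, emptied table, dropped
table) with exact counts or rates, sampling rows without replacement and
never overlapping two specs on the same column unless overlap is requested.
All mutations are staged in memory and committed only after the whole plan
validates, so a plan error (e.g. `exact_count` exceeding eligible rows)
leaves the dataset untouched. The emitted truth manifest records the exact
row positions, concepts and months affected — recovery tests compare audit
output against planted truth, not against re-derived expectations.

A temporal-gap spec deletes all events of one concept in `gap_months`
consecutive months chosen strictly inside the concept's active span, so
positive counts remain on both sides and the detector's contract (a planted
zero gap always flags) is testable without edge ambiguity.

## Benchmark fixture

`build_paper_fixture` constructs a dataset whose audit results are known in
advance: a 1.8-million-person demographic design (49.3%/50.7% sex split,
96.7% Korean race, ethnicity fully unmapped — the ethnicity field
distinguishes Hispanic/non-Hispanic and is a US-centric data-model design,
so full unmappedness there reflects the field's intent in an Asian setting,
not a capture failure), eleven engineered missing/special-value fractions,
a 96.9%-SNOMED observation table, person-level visit-type coverage from
80.4% (outpatient) to 2.6% (intensive care), and a 39-table structure with
7 empty and 5 absent tables.

Two scaling mechanisms keep the fixture desk-sized:

- The largest source tables (measurement, drug_exposure,
  procedure_occurrence, concept_relationship, drug_strength — hundreds of
  millions of rows at source scale) are represented at 1/1000 of their
  source sizes by design; all engineered fractions survive this reduction at
  one-decimal rounding.
- `scale` multiplies every count, using nearest-integer and
  largest-remainder rounding so each realized count is within 1 of its exact
  quota and partitions still sum to their totals; populated tables never
  collapse below one record. `small_table_floor` optionally keeps tables at
  or below that (post-reduction) row count at full size, because low-count
  fractions (38/124, 2/452, 117/34,330, 2,933/2,935) cannot keep their
  one-decimal percentages at reduced n. The acceptance runs use
  `scale=0.1, small_table_floor=50_000` — about 180k persons and 1.5M
  observation rows, auditable in well under a minute — which preserves every
  reference percentage exactly; the ±1 scaling property is verified
  separately at `scale=0.001` with no floor.

The fixture writes a truth manifest of all realized counts; tests assert the
audit against that manifest, not against constants duplicated in test code.

## Reporting

`assemble_report` merges the three components, recording skipped ones, and
derives an ordered findings list: deficit findings for incompleteness-class
rules at or above a severity threshold (default 5% — there is no canonical
cutoff for "substantial" missingness, so the threshold is explicit
configuration, not hidden policy), warnings for free-text capture gaps, info
notes for valid-by-default results and unpopulated derived tables. Findings
sort by severity then code; JSON output is schema-versioned (loaders reject
a major-version mismatch) and lossless; timestamps are UTC ISO-8601 and
excluded from determinism guarantees.

## What passing tests do and do not show

The synthetic generator and fixture exercise every code path with exact
ground truth, but they are statistically idealised: clean data is *perfectly*
clean, monthly series are engineered stable, defects are independent and
planted without replacement. Real EHR extracts exhibit correlated
missingness, seasonal and epidemic count variation (which the 100%-change
detector will flag as discontinuities — by design it is a screening rule,
not a causal test), mixed date formats, and encoding artifacts beyond the
default special-character class. Passing tests therefore demonstrate the
correctness of the measurement machinery, not the adequacy of the default
rulebook for any particular source system; rulebook, manifest, sentinel sets
and thresholds are all user-replaceable inputs.

## Numerical and degenerate-input choices

- Percentage rounding: half-up on exact rationals (`decimal`), one decimal.
- `total = 0` (empty table, empty person denominator) → `not_applicable`,
  never a division error; percentages are `None`, not 0.
- Ties: profile entries sort by descending count then label; top-concepts
  ties break by ascending concept id; rule results keep rulebook order;
  flagged-concept lists sort by concept.
- Dates parse as ISO-8601 only; nonconforming dates count as missing for
  temporal bucketing and are reported in the rule detail.
- Seeds: one `numpy.random.default_rng` per generator/plan; derived seeds
  stay below 2³¹.
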