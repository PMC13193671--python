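# cdmaudit

Completeness auditing for OMOP-CDM-style clinical databases.

Observational EHR datasets converted to the OMOP Common Data Model are widely
reused for medical research and AI development, but whether a given database
is *complete enough for a study* is rarely obvious: tables may be missing or
empty, source-value fields accumulate NULLs and placeholder characters,
local codes may never have been mapped to standard concepts, loading gaps
leave holes in the event timeline, and the covered population may not match
the study's target. `cdmaudit` operationalises completeness assessment as
three complementary components, for data engineers and researchers vetting a
CDM extract:

1. **Structural assessment** — every table an expected-schema manifest lists
   is classified `available` / `empty` / `not_available`, with row counts,
   storage volume, and interpretation notes (an empty ETL-derived table such
   as `dose_era` means the derivation scripts likely never ran; a missing
   `note` table means clinical free text was never captured).
2. **Rule-based assessment** — a declarative rulebook of four rule kinds:
   missing/special-character values, unmapped standard concepts (`concept_id
   = 0`, "No matching concept"), abrupt (≥100%) changes in per-concept
   monthly event counts, and numeric value-range bounds (e.g. `days_supply`
   must not exceed 180). Results carry semantics, not just counts: a column
   that is NULL by default (`invalid_reason`) can be flagged 100% missing yet
   interpreted `valid_by_default`.
3. **Descriptive profiling** — person-level distributions of sex, race,
   ethnicity and visit types, per-table mapped-vocabulary shares
   (SNOMED CT, LOINC, RxNorm, …), and the concepts covering the most persons
   per clinical domain.

For each rule the engine reports `flagged / total` and the percentage
`round_half_up(100·flagged/total, 1)`; for a temporal rule the units are
concepts and a concept is flagged when for consecutive months within its
active span `|c_t − c_{t−1}| / c_{t−1} ≥ 1` with `c_{t−1} > 0` (a drop to
zero always flags, a rise from zero is an onset and never flags).

Because real patient data cannot ship with a tool, `cdmaudit` also includes a
**seeded synthetic generator**: clean CDM-style datasets in which no rule
fires, an exact-count defect injector with a machine-readable truth manifest
(what was planted is what the audit must find), and a benchmark fixture whose
audit reproduces a fixed set of reference percentages.

## Worked example

```python
import cdmaudit as ca

# generate a small clean dataset, then plant known defects
cfg = ca.GeneratorConfig(n_persons=40, date_start="2019-01",
                         date_end="2020-12", seed=11)
ca.generate_clean(cfg, "demo")
ca.apply_defects("demo", ca.DefectPlan(seed=3, defects=[
    ca.DefectSpec(kind="missing_value", table="vocabulary",
                  column="vocabulary_version", exact_count=4),
    ca.DefectSpec(kind="drop_table", table="note"),
]))

h = ca.open_dataset("demo")
s = ca.structural_report(h, ca.default_manifest())
print(s.n_tables, s.n_available, s.n_empty, s.n_not_available,
      s.pct_not_available)
res = {r.rule_id: r for r in ca.run_rulebook(h, ca.default_rulebook())}
r = res["vocabulary.vocabulary_version.missing"]
print(r.flagged, r.total, r.proportion_pct, r.interpretation.value)
r = res["concept_relationship.invalid_reason.missing"]
print(r.proportion_pct, r.interpretation.value)
```

prints

```
39 38 0 1 2.6
4 12 33.3 deficit
100.0 valid_by_default
```

Reading: of the 39 expected tables, 38 are populated and the dropped `note`
table is not available (2.6% of the schema) — a free-text capture gap. The
four planted missing `vocabulary_version` values out of 12 vocabulary rows
are recovered exactly (33.3%, an incompleteness deficit), while
`concept_relationship.invalid_reason` is 100% missing but interpreted as
valid by default, because that field is only populated when a relationship
has been deprecated.

The same audit is available from the shell:

```bash
cdm-audit run-all --dataset demo --out report/
cdm-audit simulate --config cfg.yaml --defects plan.yaml --out sim/
cdm-audit fixture --scale 0.01 --seed 7 --out fx/
```

`run-all` writes `structural.json`, `rules.json`, `profiles.json`, a
versioned lossless `report.json`, a human-readable `report.md`, and a CSV
bundle.

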