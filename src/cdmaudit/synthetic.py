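"""Seeded synthetic CDM-style data: clean generation and exact-count defect injection.

``generate_clean`` writes a fully populated, internally consistent dataset in
which no default rule fires: every event references an existing person, every
concept id comes from the dictionary pools (never 0), rule-targeted string
columns hold benign values, numeric values sit inside their bounds, and each
concept's monthly event counts are engineered to be stable (non-increasing by
at most one), so the temporal detector stays silent.

``apply_defects`` then plants a :class:`DefectPlan` — missing values, special
characters, unmapped concepts, temporal gaps, range violations, emptied or
dropped tables — with exact counts and without replacement, and emits a truth
manifest recording precisely which rows/concepts/tables were touched. The
pair turns every assessment component into a recoverable-ground-truth
experiment: what was planted is what the audit must report.

Realism is deliberately limited to the statistical structure the assessment
consumes; there are no disease trajectories or dosing semantics.
"""

from __future__ import annotations

import enum
import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .dataset import open_dataset, write_table_csv
from .profiling import ConceptDictionary, default_dictionary
from .schema import SchemaManifest, default_manifest


class GeneratorConfig(BaseModel):
    n_persons: int = Field(default=100, ge=1)
    date_start: str = "2005-01"   # first calendar month of the coverage span
    date_end: str = "2023-12"     # last calendar month
    events_per_person: dict[str, float] = Field(default_factory=lambda: {
        "visit_occurrence": 3.0, "condition_occurrence": 2.0, "drug_exposure": 3.0,
        "procedure_occurrence": 1.0, "measurement": 5.0, "observation": 2.0,
    })
    seed: int = 0

    @model_validator(mode="after")
    def _span(self) -> "GeneratorConfig":
        if pd.Period(self.date_start, "M") > pd.Period(self.date_end, "M"):
            raise ValueError("date_start must not be after date_end")
        return self


class DefectKind(str, enum.Enum):
    missing_value = "missing_value"
    special_value = "special_value"
    unmapped_concept = "unmapped_concept"
    temporal_gap = "temporal_gap"
    out_of_range = "out_of_range"
    empty_table = "empty_table"
    drop_table = "drop_table"


class DefectSpec(BaseModel):
    kind: DefectKind
    table: str
    column: Optional[str] = None
    exact_count: Optional[int] = Field(default=None, ge=0)
    rate: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    params: dict[str, Any] = Field(default_factory=dict)

    @field_validator("table")
    @classmethod
    def _lower(cls, v: str) -> str:
        return v.strip().lower()

    @model_validator(mode="after")
    def _check(self) -> "DefectSpec":
        row_level = self.kind in (DefectKind.missing_value, DefectKind.special_value,
                                  DefectKind.unmapped_concept, DefectKind.out_of_range)
        if row_level:
            if self.column is None:
                raise ValueError(f"{self.kind.value} defect requires a column")
            if (self.exact_count is None) == (self.rate is None):
                raise ValueError(
                    f"{self.kind.value} defect requires exactly one of exact_count/rate")
        if self.kind is DefectKind.temporal_gap:
            if "date_column" not in self.params:
                raise ValueError("temporal_gap defect requires params.date_column")
        if self.kind is DefectKind.out_of_range and "violation_value" not in self.params:
            raise ValueError("out_of_range defect requires params.violation_value")
        return self


class DefectPlan(BaseModel):
    defects: list[DefectSpec] = Field(default_factory=list)
    seed: int = 0


class PlanError(ValueError):
    """A defect spec cannot be applied (e.g. exact_count exceeds eligible rows)."""


# ---------------------------------------------------------------------------
# clean generation
# ---------------------------------------------------------------------------

def _month_labels(start: str, end: str) -> list[str]:
    return [str(p) for p in pd.period_range(start, end, freq="M")]


def _stable_month_codes(n_events: int, n_months: int) -> np.ndarray:
    """Month indices whose per-month counts never rise and never drop to zero
    inside the occupied span — invisible to the discontinuity detector."""
    if n_events >= n_months:
        base, extra = divmod(n_events, n_months)
        counts = np.full(n_months, base, dtype=np.int64)
        counts[:extra] += 1
    else:
        counts = np.zeros(n_months, dtype=np.int64)
        counts[:n_events] = 1  # contiguous span of single events
    return np.repeat(np.arange(n_months), counts)


def _event_table(rng: np.random.Generator, name: str, id_col: str, n_events: int,
                 n_persons: int, concepts: list[int], concept_col: str,
                 date_col: str, months: list[str],
                 extra: dict[str, Any] | None = None) -> pd.DataFrame:
    """One clinical event table: ids, persons, pooled concepts, stable dates."""
    n_months = len(months)
    # allocate events to concepts round-robin so each concept's series is stable
    per_concept = np.full(len(concepts), n_events // len(concepts), dtype=np.int64)
    per_concept[: n_events % len(concepts)] += 1
    concept_ids = np.repeat(np.asarray(concepts, dtype=np.int64), per_concept)
    codes = np.concatenate([
        _stable_month_codes(int(k), n_months) for k in per_concept
    ]) if n_events else np.empty(0, dtype=np.int64)
    dates = pd.Categorical.from_codes(
        codes, categories=[m + "-15" for m in months])
    df = pd.DataFrame({
        id_col: np.arange(1, n_events + 1),
        "person_id": rng.integers(1, n_persons + 1, size=n_events),
        concept_col: concept_ids,
        date_col: dates,
    })
    for col, value in (extra or {}).items():
        df[col] = value
    return df


def generate_clean(config: GeneratorConfig, out_dir: str | Path,
                   manifest: SchemaManifest | None = None,
                   dictionary: ConceptDictionary | None = None) -> Path:
    """Write a clean delimited dataset covering every manifest table.

    Deterministic: the same config (seed included) produces byte-identical
    files. On the default rulebook, a clean dataset yields zero flagged
    records on every incompleteness-class rule.
    """
    manifest = manifest or default_manifest()
    dictionary = dictionary or default_dictionary()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    months = _month_labels(config.date_start, config.date_end)
    epp = config.events_per_person
    pools = {dom: dictionary.ids_for_domain(dom)
             for dom in ("Visit", "Condition", "Drug", "Measurement",
                         "Observation", "Procedure", "Specimen")}

    tables: dict[str, pd.DataFrame] = {}
    sex = rng.choice([8507, 8532], size=n)
    tables["person"] = pd.DataFrame({
        "person_id": np.arange(1, n + 1),
        "gender_concept_id": sex,
        "year_of_birth": rng.integers(1930, 2011, size=n),
        "race_concept_id": 38003585,
        "ethnicity_concept_id": 38003564,
        "gender_source_value": np.where(sex == 8507, "M", "F"),
    })
    tables["observation_period"] = pd.DataFrame({
        "observation_period_id": np.arange(1, n + 1),
        "person_id": np.arange(1, n + 1),
        "observation_period_start_date": months[0] + "-01",
        "observation_period_end_date": months[-1] + "-28",
    })

    def n_events(table: str) -> int:
        return max(1, int(round(n * epp.get(table, 1.0))))

    tables["visit_occurrence"] = _event_table(
        rng, "visit_occurrence", "visit_occurrence_id", n_events("visit_occurrence"),
        n, pools["Visit"], "visit_concept_id", "visit_start_date", months)
    tables["visit_detail"] = _event_table(
        rng, "visit_detail", "visit_detail_id", max(1, n // 2),
        n, pools["Visit"], "visit_detail_concept_id", "visit_detail_start_date", months)
    tables["condition_occurrence"] = _event_table(
        rng, "condition_occurrence", "condition_occurrence_id",
        n_events("condition_occurrence"), n, pools["Condition"],
        "condition_concept_id", "condition_start_date", months)
    drug = _event_table(
        rng, "drug_exposure", "drug_exposure_id", n_events("drug_exposure"),
        n, pools["Drug"], "drug_concept_id", "drug_exposure_start_date", months)
    ndrug = len(drug)
    drug["days_supply"] = rng.integers(1, 91, size=ndrug)
    drug["quantity"] = rng.integers(1, 101, size=ndrug)
    drug["dose_unit_source_value"] = "mg"
    tables["drug_exposure"] = drug
    tables["procedure_occurrence"] = _event_table(
        rng, "procedure_occurrence", "procedure_occurrence_id",
        n_events("procedure_occurrence"), n, pools["Procedure"],
        "procedure_concept_id", "procedure_date", months)
    tables["device_exposure"] = pd.DataFrame({
        "device_exposure_id": [1], "person_id": [1],
        "device_concept_id": [4000301], "device_exposure_start_date": [months[0] + "-15"],
    })
    meas = _event_table(
        rng, "measurement", "measurement_id", n_events("measurement"),
        n, pools["Measurement"], "measurement_concept_id", "measurement_date", months)
    meas["unit_source_value"] = "mg/dL"
    meas["value_source_value"] = rng.integers(1, 200, size=len(meas)).astype(str)
    tables["measurement"] = meas
    obs = _event_table(
        rng, "observation", "observation_id", n_events("observation"),
        n, pools["Observation"], "observation_concept_id", "observation_date", months)
    obs["value_as_string"] = "recorded"
    tables["observation"] = obs
    n_dead = max(1, n // 50)
    dead = rng.choice(np.arange(1, n + 1), size=n_dead, replace=False)
    dead.sort()
    tables["death"] = pd.DataFrame({
        "person_id": dead,
        "death_date": months[-1] + "-01",
        "cause_concept_id": rng.choice(pools["Condition"], size=n_dead),
        "cause_source_value": "I21.9",
    })
    tables["note"] = pd.DataFrame({
        "note_id": [1], "person_id": [1], "note_text": ["progress note"]})
    tables["note_nlp"] = pd.DataFrame({
        "note_nlp_id": [1], "note_id": [1], "lexical_variant": ["note"]})
    tables["specimen"] = pd.DataFrame({
        "specimen_id": np.arange(1, max(2, n // 10) + 1),
        "person_id": rng.integers(1, n + 1, size=max(2, n // 10)),
        "specimen_concept_id": 4000301,
        "specimen_date": months[0] + "-15",
    })
    tables["fact_relationship"] = pd.DataFrame({
        "domain_concept_id_1": [21], "fact_id_1": [1],
        "domain_concept_id_2": [27], "fact_id_2": [1]})
    n_loc = 10
    tables["location"] = pd.DataFrame({
        "location_id": np.arange(1, n_loc + 1),
        "city": "Incheon", "state": "Incheon",
        "zip": [f"2{i:04d}" for i in range(n_loc)],
    })
    tables["care_site"] = pd.DataFrame({
        "care_site_id": np.arange(1, 11),
        "care_site_name": [f"Care site {i}" for i in range(1, 11)],
        "place_of_service_source_value": "Outpatient",
    })
    tables["provider"] = pd.DataFrame({
        "provider_id": np.arange(1, 11),
        "specialty_concept_id": 4000201,
        "care_site_id": np.arange(1, 11),
    })
    tables["payer_plan_period"] = pd.DataFrame({
        "payer_plan_period_id": [1], "person_id": [1],
        "payer_plan_period_start_date": [months[0] + "-01"]})
    tables["cost"] = pd.DataFrame({
        "cost_id": [1, 2], "cost_event_id": [1, 2], "total_charge": [100.0, 250.0]})
    for era, concept_pool, date_col, id_col, cc in (
            ("drug_era", pools["Drug"], "drug_era_start_date", "drug_era_id",
             "drug_concept_id"),
            ("condition_era", pools["Condition"], "condition_era_start_date",
             "condition_era_id", "condition_concept_id")):
        tables[era] = _event_table(rng, era, id_col, max(1, n), n, concept_pool,
                                   cc, date_col, months)
    tables["dose_era"] = pd.DataFrame({
        "dose_era_id": [1], "person_id": [1],
        "drug_concept_id": [pools["Drug"][0]], "dose_value": [500.0]})
    tables["metadata"] = pd.DataFrame({
        "metadata_concept_id": [0], "name": ["generator"],
        "value_as_string": ["cdmaudit synthetic"]})
    tables["cdm_source"] = pd.DataFrame({
        "cdm_source_name": ["cdmaudit synthetic dataset"],
        "cdm_version": ["v5.3"], "source_release_date": [months[-1] + "-28"]})
    tables["concept"] = pd.DataFrame(
        [(cid, name, dom, voc, "") for cid, (name, voc, dom)
         in sorted(dictionary.entries.items())],
        columns=["concept_id", "concept_name", "domain_id", "vocabulary_id",
                 "invalid_reason"])
    vocabs = sorted({voc for _, voc, _ in dictionary.entries.values()})
    tables["vocabulary"] = pd.DataFrame({
        "vocabulary_id": vocabs,
        "vocabulary_name": [f"{v} vocabulary" for v in vocabs],
        "vocabulary_version": "2023-12-01",
    })
    domains = sorted({dom for _, _, dom in dictionary.entries.values()})
    tables["domain"] = pd.DataFrame({
        "domain_id": domains, "domain_name": domains})
    tables["concept_class"] = pd.DataFrame({
        "concept_class_id": ["Clinical Finding", "Drug Product"],
        "concept_class_name": ["Clinical Finding", "Drug Product"]})
    all_ids = sorted(cid for cid in dictionary.entries if cid != 0)
    tables["concept_relationship"] = pd.DataFrame({
        "concept_id_1": all_ids,
        "concept_id_2": all_ids,
        "relationship_id": "Maps to",
        "invalid_reason": pd.array([pd.NA] * len(all_ids), dtype="string"),
    })
    tables["relationship"] = pd.DataFrame({
        "relationship_id": ["Maps to"], "relationship_name": ["Maps to"]})
    tables["concept_synonym"] = pd.DataFrame({
        "concept_id": all_ids[:5],
        "concept_synonym_name": [dictionary.entries[c][0] for c in all_ids[:5]]})
    tables["concept_ancestor"] = pd.DataFrame({
        "ancestor_concept_id": all_ids[:5], "descendant_concept_id": all_ids[:5]})
    tables["source_to_concept_map"] = pd.DataFrame({
        "source_code": ["L001"], "target_concept_id": [all_ids[0]]})
    tables["drug_strength"] = pd.DataFrame({
        "drug_concept_id": pools["Drug"],
        "ingredient_concept_id": pools["Drug"],
        "amount_value": 500.0,
        "invalid_reason": pd.array([pd.NA] * len(pools["Drug"]), dtype="string"),
    })
    tables["cohort"] = pd.DataFrame({
        "cohort_definition_id": [1], "subject_id": [1],
        "cohort_start_date": [months[0] + "-01"]})
    tables["cohort_definition"] = pd.DataFrame({
        "cohort_definition_id": [1], "cohort_definition_name": ["all persons"]})
    tables["attribute_definition"] = pd.DataFrame({
        "attribute_definition_id": [1], "attribute_name": ["age at index"]})
    tables["cohort_attribute"] = pd.DataFrame({
        "cohort_definition_id": [1], "subject_id": [1],
        "attribute_definition_id": [1]})

    for spec in manifest:
        if spec.name not in tables:  # any manifest extension gets a minimal row
            tables[spec.name] = pd.DataFrame({c.name: [1] for c in spec.columns})
        write_table_csv(out, spec.name, tables[spec.name])
    return out


# ---------------------------------------------------------------------------
# defect injection
# ---------------------------------------------------------------------------

def apply_defects(dataset_dir: str | Path, plan: DefectPlan) -> dict:
    """Apply a defect plan to a delimited dataset in place; return the truth manifest.

    Specs are applied in order. Row-level specs sample target rows without
    replacement; two specs on the same (table, column) never overlap unless
    ``params.allow_overlap`` is true. All mutations are staged in memory and
    written only after the whole plan validates, so a plan error leaves the
    dataset untouched.
    """
    dataset_dir = Path(dataset_dir)
    handle = open_dataset(dataset_dir, "delimited_directory")
    rng = np.random.default_rng(plan.seed)
    staged: dict[str, pd.DataFrame | None] = {}   # None => table dropped
    emptied: set[str] = set()
    used: dict[tuple[str, str], set[int]] = {}
    truths: list[dict] = []

    def load(table: str) -> pd.DataFrame:
        if table not in staged:
            staged[table] = handle.read_table(table)
        df = staged[table]
        if df is None:
            raise PlanError(f"table {table!r} was dropped earlier in the plan")
        return df

    for i, spec in enumerate(plan.defects):
        table = spec.table
        truth: dict[str, Any] = {"index": i, "kind": spec.kind.value, "table": table,
                                 "column": spec.column}
        if spec.kind is DefectKind.drop_table:
            staged[table] = None
            truths.append(truth)
            continue
        if spec.kind is DefectKind.empty_table:
            df = load(table)
            staged[table] = df.iloc[0:0]
            emptied.add(table)
            truth["rows_removed"] = len(df)
            truths.append(truth)
            continue
        df = load(table)
        if spec.kind is DefectKind.temporal_gap:
            staged[table], gap_truth = _apply_temporal_gap(df, spec, rng)
            truth.update(gap_truth)
            truths.append(truth)
            continue
        # row-level value mutation
        column = spec.column.lower()  # type: ignore[union-attr]
        if column not in df.columns:
            raise PlanError(f"defect {i}: column {column!r} absent from {table!r}")
        key = (table, column)
        taken = used.setdefault(key, set())
        eligible = (np.arange(len(df)) if spec.params.get("allow_overlap")
                    else np.array(sorted(set(range(len(df))) - taken), dtype=np.int64))
        k = spec.exact_count if spec.exact_count is not None \
            else int(round(spec.rate * len(df)))  # type: ignore[operator]
        if k > len(eligible):
            raise PlanError(
                f"defect {i} ({spec.kind.value} on {table}.{column}): "
                f"exact_count {k} exceeds {len(eligible)} eligible rows")
        rows = rng.choice(eligible, size=k, replace=False) if k else np.empty(0, int)
        rows.sort()
        taken.update(int(r) for r in rows)
        if spec.kind is DefectKind.missing_value:
            value: object = pd.NA
        elif spec.kind is DefectKind.special_value:
            value = str(spec.params.get("special_value", "*"))
        elif spec.kind is DefectKind.unmapped_concept:
            value = "0"
        else:  # out_of_range
            value = str(spec.params["violation_value"])
        col = df[column].astype("string")
        col.iloc[rows] = value
        df[column] = col
        staged[table] = df
        truth.update({"rows": [int(r) for r in rows], "count": int(k),
                      "value": None if value is pd.NA else value})
        truths.append(truth)

    # commit
    for table, df in staged.items():
        path = dataset_dir / f"{table}.csv"
        if df is None:
            if path.exists():
                path.unlink()
        else:
            write_table_csv(dataset_dir, table, df)
    manifest = {"seed": plan.seed, "defects": truths}
    (dataset_dir / "defect_truth.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _apply_temporal_gap(df: pd.DataFrame, spec: DefectSpec, rng: np.random.Generator
                        ) -> tuple[pd.DataFrame, dict]:
    date_column = spec.params["date_column"].lower()
    concept_column = spec.params.get("concept_column", spec.column or "").lower()
    gap_months = int(spec.params.get("gap_months", 3))
    if not concept_column or concept_column not in df.columns:
        raise PlanError(f"temporal_gap: concept column {concept_column!r} absent")
    if date_column not in df.columns:
        raise PlanError(f"temporal_gap: date column {date_column!r} absent")
    months = pd.to_datetime(df[date_column], format="ISO8601",
                            errors="coerce").dt.to_period("M")
    concept = spec.params.get("concept")
    if concept is None:
        spans = (
            pd.DataFrame({"c": df[concept_column], "m": months})
            .dropna().groupby("c")["m"]
            .agg(lambda s: s.max().ordinal - s.min().ordinal + 1)
        )
        wide = spans[spans >= gap_months + 2]
        if wide.empty:
            raise PlanError("temporal_gap: no concept spans enough months")
        concept = str(sorted(wide.index)[0])
    concept = str(concept)
    cmask = df[concept_column].astype("string") == concept
    cmonths = months[cmask].dropna()
    if cmonths.empty:
        raise PlanError(f"temporal_gap: concept {concept!r} has no dated events")
    lo, hi = cmonths.min(), cmonths.max()
    span = hi.ordinal - lo.ordinal + 1
    if span < gap_months + 2:
        raise PlanError(
            f"temporal_gap: concept {concept!r} spans {span} months, "
            f"needs at least {gap_months + 2}")
    start_offset = int(rng.integers(1, span - gap_months))
    gap = [lo + start_offset + j for j in range(gap_months)]
    gap_set = set(gap)
    drop_mask = cmask & months.isin(gap_set)
    out = df[~drop_mask].reset_index(drop=True)
    return out, {"concept": concept, "gap_months": [str(m) for m in gap],
                 "rows_removed": int(drop_mask.sum())}
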