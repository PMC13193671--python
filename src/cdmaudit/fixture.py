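"""Reference benchmark fixture: a dataset whose audit results are known in advance.

``build_paper_fixture`` writes a CDM-style dataset engineered so that the
structural report, the default rulebook, and the profiling battery reproduce a
fixed set of published-style completeness findings exactly:

* 39 expected tables of which 7 are empty and 5 absent (17.9% / 12.8%);
* eleven missing/special-value table-column pairs (e.g. vocabulary_version
  38/124 = 30.6%, observation value_as_string 23.8%, death cause 0.3%), with
  the two ``invalid_reason`` pairs planted at ~100% yet tagged expected_null;
* demographic structure: 49.3%/50.7% male/female, 96.7% Korean race with the
  remainder unmapped, ethnicity 100% unmapped ("No matching concept");
* an observation table mapped 96.9% to SNOMED CT, and visit-type person
  coverage of 80.4% outpatient down to 2.6% intensive care.

Scaling: ``scale`` multiplies every engineered count with nearest-integer /
largest-remainder rounding (each realized count within 1 of the exact quota),
with a floor of one record so populated tables never collapse to empty. The
very large source tables (measurement, drug_exposure, procedure_occurrence,
concept_relationship, drug_strength — hundreds of millions of rows at the
source) are represented at 1/1000 of their source size by design; their
engineered fractions are preserved. ``small_table_floor`` optionally keeps
tables at or below that row count at full size regardless of ``scale``, so
low-count fractions (38/124, 2/452, ...) keep their printed one-decimal
percentages at reduced scale.

The returned truth manifest records every realized count, so tests can verify
the audit against the fixture rather than against constants buried in code.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import largest_remainder, scaled_count
from .dataset import write_table_csv
from .profiling import default_dictionary

# engineered full-scale design: person-level structure
N_PERSONS = 1_798_153
SEX_COUNTS = {"Male": 886_489, "Female": 911_664}                # concepts 8507/8532
RACE_COUNTS = {"Korean": 1_739_628, "No matching concept": 58_525}
VISIT_PERSONS = {                                                # persons with >=1 visit
    9202: 1_444_995,   # outpatient
    9203: 687_254,     # emergency room
    9201: 494_492,     # inpatient
    9205: 272_061,     # health examination
    32037: 46_651,     # intensive care
}
CONDITION_PERSONS = {4060985: 134_783, 320128: 115_262, 4149481: 111_126}

# engineered full-scale design: table sizes and flagged counts
# (tables marked //1000 are the 1/1000 representations of very large sources)
OBSERVATION_ROWS = 15_313_463
OBSERVATION_FLAGGED = 3_643_581            # value_as_string missing
OBSERVATION_VOCAB = {"SNOMED": 14_833_557, "LOINC": 399_874, "KCD7": 80_032}
MEASUREMENT_ROWS = 642_624                 # //1000
MEASUREMENT_UNIT_FLAGGED = 25_584          # //1000
MEASUREMENT_VALUE_FLAGGED = 1_910          # //1000
MEASUREMENT_VOCAB = {"LOINC": 468_274_853, "SNOMED": 116_316_640,
                     "OMOP Extension": 52_320_453, "KCD7": 5_726_710}
DRUG_ROWS = 166_706                        # //1000
DRUG_DOSE_UNIT_FLAGGED = 0                 # //1000 of 232
DRUG_VOCAB = {"RxNorm Extension": 143_512_501, "RxNorm": 16_810_245,
              "OMOP Extension": 4_026_859, "KDC": 2_352_875}
PROCEDURE_ROWS = 159_008                   # //1000
PROCEDURE_VOCAB = {"OMOP Extension": 85_344_562, "SNOMED": 69_604_840,
                   "KCD7": 4_065_510}
CONCEPT_REL_ROWS = 55_082                  # //1000, invalid_reason all missing
DRUG_STRENGTH_ROWS = 2_935                 # //1000
DRUG_STRENGTH_FLAGGED = 2_933              # //1000 of 2,932,914 / 2,935,461
VOCABULARY_ROWS, VOCABULARY_FLAGGED = 124, 38
CARE_SITE_ROWS, CARE_SITE_POS_FLAGGED, CARE_SITE_NAME_FLAGGED = 1_715, 28, 26
LOCATION_ROWS, LOCATION_FLAGGED = 452, 2
DEATH_ROWS, DEATH_FLAGGED = 34_330, 117

EMPTY_TABLES = ("metadata", "dose_era", "cost", "payer_plan_period",
                "device_exposure", "fact_relationship", "cohort_attribute")
ABSENT_TABLES = ("note", "note_nlp", "attribute_definition", "cohort_definition",
                 "concept_synonym")

EMPTY_HEADERS = {
    "metadata": ["metadata_concept_id", "name", "value_as_string"],
    "dose_era": ["dose_era_id", "person_id", "drug_concept_id", "dose_value"],
    "cost": ["cost_id", "cost_event_id", "total_charge"],
    "payer_plan_period": ["payer_plan_period_id", "person_id",
                          "payer_plan_period_start_date"],
    "device_exposure": ["device_exposure_id", "person_id", "device_concept_id",
                        "device_exposure_start_date"],
    "fact_relationship": ["domain_concept_id_1", "fact_id_1",
                          "domain_concept_id_2", "fact_id_2"],
    "cohort_attribute": ["cohort_definition_id", "subject_id",
                         "attribute_definition_id"],
}

MONTHS = [str(p) for p in pd.period_range("2005-01", "2023-12", freq="M")]


def _scaled(full: int, scale: float, small_table_floor: int) -> int:
    """Scale a table row count; keep small tables full-size when floored."""
    if small_table_floor and full <= small_table_floor:
        return full
    return max(1, scaled_count(full, scale)) if full > 0 else 0


def _partition(full_counts: list[int], total: int) -> list[int]:
    return largest_remainder([float(c) for c in full_counts], total)


def _stable_dates(n: int, rng: np.random.Generator) -> pd.Categorical:
    """n dates spread evenly over the coverage months (stable monthly counts)."""
    n_months = len(MONTHS)
    base, extra = divmod(n, n_months)
    if base == 0:
        counts = np.zeros(n_months, dtype=np.int64)
        counts[:n] = 1
    else:
        counts = np.full(n_months, base, dtype=np.int64)
        counts[:extra] += 1
    codes = np.repeat(np.arange(n_months), counts)
    return pd.Categorical.from_codes(codes, categories=[m + "-15" for m in MONTHS])


def _flag_column(n: int, flagged: int, clean_value: str,
                 flag_value: object = pd.NA) -> pd.Series:
    """A string column whose first ``flagged`` entries carry the defect."""
    col = pd.Series([clean_value] * n, dtype="string")
    if flagged:
        col.iloc[:flagged] = flag_value
    return col


def _concepts_and_dates(vocab_counts: dict[str, int], total: int,
                        pools: dict[str, list[int]]
                        ) -> tuple[np.ndarray, pd.Categorical]:
    """Concept ids realizing a per-vocabulary row partition, with per-concept
    stable dates.

    Within each vocabulary the rows are spread round-robin over that
    vocabulary's concept pool, and each concept's rows get an evenly spread
    monthly date series, so no concept trips the discontinuity detector.
    """
    vocabs = list(vocab_counts)
    alloc = _partition([vocab_counts[v] for v in vocabs], total)
    n_months = len(MONTHS)
    concept_parts: list[np.ndarray] = []
    code_parts: list[np.ndarray] = []
    for voc, k in zip(vocabs, alloc):
        pool = np.asarray(pools[voc], dtype=np.int64)
        per = np.full(len(pool), k // len(pool), dtype=np.int64)
        per[: k % len(pool)] += 1
        concept_parts.append(np.repeat(pool, per))
        for k_c in per:
            k_c = int(k_c)
            base, extra = divmod(k_c, n_months)
            if base == 0:
                counts = np.zeros(n_months, dtype=np.int64)
                counts[:k_c] = 1
            else:
                counts = np.full(n_months, base, dtype=np.int64)
                counts[:extra] += 1
            code_parts.append(np.repeat(np.arange(n_months), counts))
    concepts = np.concatenate(concept_parts) if concept_parts else np.empty(0, np.int64)
    codes = np.concatenate(code_parts) if code_parts else np.empty(0, np.int64)
    dates = pd.Categorical.from_codes(codes, categories=[m + "-15" for m in MONTHS])
    return concepts, dates


def build_paper_fixture(out_dir: str | Path, scale: float = 1.0, seed: int = 0,
                        small_table_floor: int = 0) -> tuple[Path, dict]:
    """Write the benchmark fixture at the given scale; return (path, truth manifest)."""
    if not (0 < scale <= 1.0):
        raise ValueError("scale must be in (0, 1]")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    dictionary = default_dictionary()
    truth: dict = {"scale": scale, "seed": seed,
                   "small_table_floor": small_table_floor,
                   "reduced_source_tables": {
                       "note": "measurement, drug_exposure, procedure_occurrence, "
                               "concept_relationship and drug_strength are 1/1000 "
                               "representations of their source sizes",
                   },
                   "tables": {}}

    def record(table: str, rows: int, **extra) -> None:
        truth["tables"][table] = {"rows": rows, **extra}

    def sz(full: int) -> int:
        return _scaled(full, scale, small_table_floor)

    # ---- person ----------------------------------------------------------
    n_persons = max(1, scaled_count(N_PERSONS, scale))
    n_male, n_female = _partition(list(SEX_COUNTS.values()), n_persons)
    n_korean, n_race_unmapped = _partition(list(RACE_COUNTS.values()), n_persons)
    gender = np.concatenate([np.full(n_male, 8507, dtype=np.int64),
                             np.full(n_female, 8532, dtype=np.int64)])
    race = np.concatenate([np.full(n_korean, 38003585, dtype=np.int64),
                           np.zeros(n_race_unmapped, dtype=np.int64)])
    rng.shuffle(gender)
    rng.shuffle(race)
    person = pd.DataFrame({
        "person_id": np.arange(1, n_persons + 1),
        "gender_concept_id": gender,
        "year_of_birth": rng.integers(1930, 2011, size=n_persons),
        "race_concept_id": race,
        "ethnicity_concept_id": np.zeros(n_persons, dtype=np.int64),
        "gender_source_value": pd.Categorical.from_codes(
            (gender == 8532).astype(np.int8), categories=["M", "F"]),
    })
    write_table_csv(out, "person", person)
    record("person", n_persons, male=n_male, female=n_female,
           race_korean=n_korean, race_unmapped=n_race_unmapped,
           ethnicity_unmapped=n_persons)
    del person, gender, race

    # ---- observation (value_as_string missingness + SNOMED-dominated) ----
    n_obs = sz(OBSERVATION_ROWS)
    n_obs_flag = min(n_obs, scaled_count(
        OBSERVATION_FLAGGED, 1.0 if n_obs == OBSERVATION_ROWS else scale))
    pools = {
        "SNOMED": dictionary.ids_for_domain("Observation", "SNOMED"),
        "LOINC": dictionary.ids_for_domain("Observation", "LOINC"),
        "KCD7": dictionary.ids_for_domain("Observation", "KCD7"),
    }
    obs_concepts, obs_dates = _concepts_and_dates(OBSERVATION_VOCAB, n_obs, pools)
    obs = pd.DataFrame({
        "observation_id": np.arange(1, n_obs + 1),
        "person_id": rng.integers(1, n_persons + 1, size=n_obs),
        "observation_concept_id": obs_concepts,
        "observation_date": obs_dates,
        "value_as_string": pd.Categorical.from_codes(
            np.where(np.arange(n_obs) < n_obs_flag, -1, 0), categories=["recorded"]),
    })
    write_table_csv(out, "observation", obs)
    vocab_real = dict(zip(OBSERVATION_VOCAB,
                          _partition(list(OBSERVATION_VOCAB.values()), n_obs)))
    record("observation", n_obs, value_as_string_flagged=n_obs_flag,
           vocabulary_rows=vocab_real)
    del obs, obs_concepts

    # ---- measurement (1/1000 source representation) ----------------------
    n_meas = sz(MEASUREMENT_ROWS)
    s_meas = 1.0 if n_meas == MEASUREMENT_ROWS else scale
    unit_flag = min(n_meas, scaled_count(MEASUREMENT_UNIT_FLAGGED, s_meas))
    value_flag = min(n_meas, scaled_count(MEASUREMENT_VALUE_FLAGGED, s_meas))
    mpools = {
        "LOINC": dictionary.ids_for_domain("Measurement", "LOINC"),
        "SNOMED": dictionary.ids_for_domain("Measurement", "SNOMED"),
        "OMOP Extension": dictionary.ids_for_domain("Measurement", "OMOP Extension"),
        "KCD7": dictionary.ids_for_domain("Measurement", "KCD7"),
    }
    meas_concepts, meas_dates = _concepts_and_dates(MEASUREMENT_VOCAB, n_meas, mpools)
    meas = pd.DataFrame({
        "measurement_id": np.arange(1, n_meas + 1),
        "person_id": rng.integers(1, n_persons + 1, size=n_meas),
        "measurement_concept_id": meas_concepts,
        "measurement_date": meas_dates,
        # unit flags at the head, value flags at the tail: the pairs overlap
        # only if forced to by table size
        "unit_source_value": _flag_column(n_meas, unit_flag, "mg/dL", "*"),
        "value_source_value": _flag_column(n_meas, value_flag, "120", "-")[::-1].values,
    })
    write_table_csv(out, "measurement", meas)
    record("measurement", n_meas, unit_source_value_flagged=unit_flag,
           value_source_value_flagged=value_flag)
    del meas

    # ---- drug_exposure (1/1000 source representation) ---------------------
    n_drug = sz(DRUG_ROWS)
    s_drug = 1.0 if n_drug == DRUG_ROWS else scale
    dose_flag = min(n_drug, scaled_count(DRUG_DOSE_UNIT_FLAGGED, s_drug))
    dpools = {
        "RxNorm Extension": dictionary.ids_for_domain("Drug", "RxNorm Extension"),
        "RxNorm": dictionary.ids_for_domain("Drug", "RxNorm"),
        "OMOP Extension": dictionary.ids_for_domain("Drug", "OMOP Extension"),
        "KDC": dictionary.ids_for_domain("Drug", "KDC"),
    }
    drug_concepts, drug_dates = _concepts_and_dates(DRUG_VOCAB, n_drug, dpools)
    drug = pd.DataFrame({
        "drug_exposure_id": np.arange(1, n_drug + 1),
        "person_id": rng.integers(1, n_persons + 1, size=n_drug),
        "drug_concept_id": drug_concepts,
        "drug_exposure_start_date": drug_dates,
        "days_supply": rng.integers(1, 91, size=n_drug),
        "quantity": rng.integers(1, 101, size=n_drug),
        "dose_unit_source_value": _flag_column(n_drug, dose_flag, "mg", "*"),
    })
    write_table_csv(out, "drug_exposure", drug)
    record("drug_exposure", n_drug, dose_unit_source_value_flagged=dose_flag)
    del drug

    # ---- procedure_occurrence (1/1000 source representation) --------------
    n_proc = sz(PROCEDURE_ROWS)
    ppools = {
        "OMOP Extension": dictionary.ids_for_domain("Procedure", "OMOP Extension"),
        "SNOMED": dictionary.ids_for_domain("Procedure", "SNOMED"),
        "KCD7": dictionary.ids_for_domain("Procedure", "KCD7"),
    }
    proc_concepts, proc_dates = _concepts_and_dates(PROCEDURE_VOCAB, n_proc, ppools)
    proc = pd.DataFrame({
        "procedure_occurrence_id": np.arange(1, n_proc + 1),
        "person_id": rng.integers(1, n_persons + 1, size=n_proc),
        "procedure_concept_id": proc_concepts,
        "procedure_date": proc_dates,
    })
    write_table_csv(out, "procedure_occurrence", proc)
    record("procedure_occurrence", n_proc)
    del proc

    # ---- visit_occurrence: exact distinct-person coverage per visit type --
    visit_frames = []
    visit_truth = {}
    next_id = 1
    for concept_id, full_persons in VISIT_PERSONS.items():
        k = min(n_persons, scaled_count(full_persons, scale))
        persons = rng.choice(np.arange(1, n_persons + 1), size=k, replace=False)
        persons.sort()
        visit_frames.append(pd.DataFrame({
            "visit_occurrence_id": np.arange(next_id, next_id + k),
            "person_id": persons,
            "visit_concept_id": np.full(k, concept_id, dtype=np.int64),
            "visit_start_date": _stable_dates(k, rng),
        }))
        visit_truth[str(concept_id)] = int(k)
        next_id += k
    visit = pd.concat(visit_frames, ignore_index=True)
    write_table_csv(out, "visit_occurrence", visit)
    record("visit_occurrence", len(visit), persons_by_type=visit_truth)
    del visit, visit_frames

    # ---- condition_occurrence: exact distinct-person coverage -------------
    cond_frames = []
    cond_truth = {}
    next_id = 1
    for concept_id, full_persons in CONDITION_PERSONS.items():
        k = min(n_persons, scaled_count(full_persons, scale))
        persons = rng.choice(np.arange(1, n_persons + 1), size=k, replace=False)
        persons.sort()
        cond_frames.append(pd.DataFrame({
            "condition_occurrence_id": np.arange(next_id, next_id + k),
            "person_id": persons,
            "condition_concept_id": np.full(k, concept_id, dtype=np.int64),
            "condition_start_date": _stable_dates(k, rng),
        }))
        cond_truth[str(concept_id)] = int(k)
        next_id += k
    cond = pd.concat(cond_frames, ignore_index=True)
    write_table_csv(out, "condition_occurrence", cond)
    record("condition_occurrence", len(cond), persons_by_concept=cond_truth)
    del cond, cond_frames

    # ---- death ------------------------------------------------------------
    n_death = sz(DEATH_ROWS)
    n_death = min(n_death, n_persons)
    death_flag = min(n_death, DEATH_FLAGGED if n_death == DEATH_ROWS
                     else scaled_count(DEATH_FLAGGED, scale))
    dead = rng.choice(np.arange(1, n_persons + 1), size=n_death, replace=False)
    dead.sort()
    death = pd.DataFrame({
        "person_id": dead,
        "death_date": _stable_dates(n_death, rng),
        "cause_concept_id": np.full(n_death, 4329847, dtype=np.int64),
        "cause_source_value": _flag_column(n_death, death_flag, "I21.9"),
    })
    write_table_csv(out, "death", death)
    record("death", n_death, cause_source_value_flagged=death_flag)

    # ---- small reference / metadata tables --------------------------------
    n_vocab = sz(VOCABULARY_ROWS)
    vocab_flag = min(n_vocab, VOCABULARY_FLAGGED if n_vocab == VOCABULARY_ROWS
                     else scaled_count(VOCABULARY_FLAGGED, scale))
    vocab = pd.DataFrame({
        "vocabulary_id": [f"VOC{i:03d}" for i in range(n_vocab)],
        "vocabulary_name": [f"Vocabulary {i}" for i in range(n_vocab)],
        "vocabulary_version": _flag_column(n_vocab, vocab_flag, "2023-12-01"),
    })
    write_table_csv(out, "vocabulary", vocab)
    record("vocabulary", n_vocab, vocabulary_version_flagged=vocab_flag)

    n_care = sz(CARE_SITE_ROWS)
    pos_flag = min(n_care, CARE_SITE_POS_FLAGGED if n_care == CARE_SITE_ROWS
                   else scaled_count(CARE_SITE_POS_FLAGGED, scale))
    name_flag = min(n_care, CARE_SITE_NAME_FLAGGED if n_care == CARE_SITE_ROWS
                    else scaled_count(CARE_SITE_NAME_FLAGGED, scale))
    care = pd.DataFrame({
        "care_site_id": np.arange(1, n_care + 1),
        "care_site_name": _flag_column(n_care, name_flag, "Ward", "?")[::-1].values,
        "place_of_service_source_value": _flag_column(n_care, pos_flag, "Outpatient", "*"),
    })
    write_table_csv(out, "care_site", care)
    record("care_site", n_care, place_of_service_flagged=pos_flag,
           care_site_name_flagged=name_flag)

    n_loc = sz(LOCATION_ROWS)
    loc_flag = min(n_loc, LOCATION_FLAGGED if n_loc == LOCATION_ROWS
                   else scaled_count(LOCATION_FLAGGED, scale))
    loc = pd.DataFrame({
        "location_id": np.arange(1, n_loc + 1),
        "city": "Incheon",
        "state": _flag_column(n_loc, loc_flag, "Incheon"),
        "zip": [f"2{i:04d}" for i in range(n_loc)],
    })
    write_table_csv(out, "location", loc)
    record("location", n_loc, state_flagged=loc_flag)

    n_cr = sz(CONCEPT_REL_ROWS)
    cr = pd.DataFrame({
        "concept_id_1": np.arange(1, n_cr + 1),
        "concept_id_2": np.arange(1, n_cr + 1),
        "relationship_id": "Maps to",
        "invalid_reason": pd.array([pd.NA] * n_cr, dtype="string"),
    })
    write_table_csv(out, "concept_relationship", cr)
    record("concept_relationship", n_cr, invalid_reason_flagged=n_cr)
    del cr

    n_ds = sz(DRUG_STRENGTH_ROWS)
    ds_flag = min(n_ds, DRUG_STRENGTH_FLAGGED if n_ds == DRUG_STRENGTH_ROWS
                  else scaled_count(DRUG_STRENGTH_FLAGGED, scale))
    ds = pd.DataFrame({
        "drug_concept_id": np.arange(1, n_ds + 1),
        "ingredient_concept_id": np.arange(1, n_ds + 1),
        "amount_value": 500.0,
        "invalid_reason": _flag_column(n_ds, ds_flag, "D"),
    })
    write_table_csv(out, "drug_strength", ds)
    record("drug_strength", n_ds, invalid_reason_flagged=ds_flag)

    # remaining populated tables (modest, internally consistent)
    n_small = max(1, scaled_count(1000, scale))
    op_persons = np.arange(1, min(n_small, n_persons) + 1)
    write_table_csv(out, "observation_period", pd.DataFrame({
        "observation_period_id": op_persons,
        "person_id": op_persons,
        "observation_period_start_date": MONTHS[0] + "-01",
        "observation_period_end_date": MONTHS[-1] + "-28",
    }))
    record("observation_period", len(op_persons))
    vd_persons = np.arange(1, min(n_small, n_persons) + 1)
    write_table_csv(out, "visit_detail", pd.DataFrame({
        "visit_detail_id": vd_persons,
        "person_id": vd_persons,
        "visit_detail_concept_id": 9202,
        "visit_detail_start_date": _stable_dates(len(vd_persons), rng),
    }))
    record("visit_detail", len(vd_persons))
    n_spec = max(1, scaled_count(50_000, scale))
    write_table_csv(out, "specimen", pd.DataFrame({
        "specimen_id": np.arange(1, n_spec + 1),
        "person_id": rng.integers(1, n_persons + 1, size=n_spec),
        "specimen_concept_id": 4000301,
        "specimen_date": _stable_dates(n_spec, rng),
    }))
    record("specimen", n_spec)
    for era, cc, date_col, id_col, pool in (
            ("drug_era", "drug_concept_id", "drug_era_start_date", "drug_era_id",
             dictionary.ids_for_domain("Drug")),
            ("condition_era", "condition_concept_id", "condition_era_start_date",
             "condition_era_id", dictionary.ids_for_domain("Condition"))):
        n_era = max(len(MONTHS), scaled_count(10_000, scale))
        concepts = np.repeat(np.asarray(pool[:2], dtype=np.int64),
                             [n_era - n_era // 2, n_era // 2])
        dates = pd.Categorical(np.concatenate([
            np.asarray(_stable_dates(n_era - n_era // 2, rng)),
            np.asarray(_stable_dates(n_era // 2, rng))]))
        write_table_csv(out, era, pd.DataFrame({
            id_col: np.arange(1, n_era + 1),
            "person_id": rng.integers(1, n_persons + 1, size=n_era),
            cc: concepts,
            date_col: dates,
        }))
        record(era, n_era)
    write_table_csv(out, "provider", pd.DataFrame({
        "provider_id": np.arange(1, 101),
        "specialty_concept_id": 4000201,
        "care_site_id": np.arange(1, 101) % max(1, n_care) + 1,
    }))
    record("provider", 100)
    write_table_csv(out, "cdm_source", pd.DataFrame({
        "cdm_source_name": ["cdmaudit benchmark fixture"],
        "cdm_version": ["v5.3"], "source_release_date": [MONTHS[-1] + "-28"],
    }))
    record("cdm_source", 1)
    concept = pd.DataFrame(
        [(cid, name, dom, voc, "") for cid, (name, voc, dom)
         in sorted(dictionary.entries.items())],
        columns=["concept_id", "concept_name", "domain_id", "vocabulary_id",
                 "invalid_reason"])
    write_table_csv(out, "concept", concept)
    record("concept", len(concept))
    domains = sorted({dom for _, _, dom in dictionary.entries.values()})
    write_table_csv(out, "domain", pd.DataFrame({
        "domain_id": domains, "domain_name": domains}))
    record("domain", len(domains))
    write_table_csv(out, "concept_class", pd.DataFrame({
        "concept_class_id": ["Clinical Finding", "Drug Product"],
        "concept_class_name": ["Clinical Finding", "Drug Product"]}))
    record("concept_class", 2)
    write_table_csv(out, "relationship", pd.DataFrame({
        "relationship_id": ["Maps to"], "relationship_name": ["Maps to"]}))
    record("relationship", 1)
    ids = sorted(cid for cid in dictionary.entries if cid != 0)
    write_table_csv(out, "concept_ancestor", pd.DataFrame({
        "ancestor_concept_id": ids[:5], "descendant_concept_id": ids[:5]}))
    record("concept_ancestor", 5)
    write_table_csv(out, "source_to_concept_map", pd.DataFrame({
        "source_code": ["L001"], "target_concept_id": [ids[0]]}))
    record("source_to_concept_map", 1)
    write_table_csv(out, "cohort", pd.DataFrame({
        "cohort_definition_id": [1], "subject_id": [1],
        "cohort_start_date": [MONTHS[0] + "-01"]}))
    record("cohort", 1)

    # ---- 7 empty tables (header only) and 5 absent tables -----------------
    for table in EMPTY_TABLES:
        write_table_csv(out, table, pd.DataFrame(columns=EMPTY_HEADERS[table]))
        record(table, 0, status="empty")
    for table in ABSENT_TABLES:
        path = out / f"{table}.csv"
        if path.exists():
            path.unlink()
        truth["tables"][table] = {"rows": None, "status": "not_available"}

    (out / "fixture_truth.json").write_text(json.dumps(truth, indent=2))
    return out, truth
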