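"""Rule engine: each kind against hand-enumerated and brute-force oracles."""

import csv

import pandas as pd
import pytest

import cdmaudit as ca
from cdmaudit.rules import (DEFAULT_SPECIAL_CHARS, DEFAULT_SPECIAL_VALUES,
                            RulebookError, series_discontinuities)

from conftest import make_dataset


# --------------------------------------------------------------------------
# independent record-by-record oracles (csv module, no pandas, no engine code)
# --------------------------------------------------------------------------

def read_records(path):
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def oracle_missing_special(records, column):
    sentinels = {v.upper() for v in DEFAULT_SPECIAL_VALUES}
    flagged = 0
    for rec in records:
        v = rec.get(column)
        if v is None or v.strip() == "":
            flagged += 1
            continue
        s = v.strip()
        if s.upper() in sentinels or all(ch in DEFAULT_SPECIAL_CHARS for ch in s):
            flagged += 1
    return flagged


def oracle_unmapped(records, concept_col, unit, person_col="person_id"):
    def is_unmapped(rec):
        v = rec.get(concept_col, "")
        try:
            return v is None or v.strip() == "" or int(float(v)) == 0
        except ValueError:
            return True
    if unit == "rows":
        return sum(1 for r in records if is_unmapped(r)), len(records)
    persons = {r[person_col] for r in records}
    flagged = {r[person_col] for r in records if is_unmapped(r)}
    return len(flagged), len(persons)


def oracle_value_range(records, column, bound, direction="max_le"):
    flagged = 0
    for rec in records:
        try:
            v = float(rec.get(column, ""))
        except (TypeError, ValueError):
            continue
        if (direction == "max_le" and v > bound) or (direction == "min_ge" and v < bound):
            flagged += 1
    return flagged


def oracle_temporal(records, concept_col, date_col, threshold=1.0):
    by_concept = {}
    for rec in records:
        date = rec.get(date_col, "")
        if len(date) < 7:
            continue
        month = date[:7]
        by_concept.setdefault(rec[concept_col], {}).setdefault(month, 0)
        by_concept[rec[concept_col]][month] += 1
    flagged = set()
    for concept, by_month in by_concept.items():
        months = sorted(by_month)
        span = pd.period_range(months[0], months[-1], freq="M")
        counts = [by_month.get(str(m), 0) for m in span]
        for t in range(1, len(counts)):
            if counts[t - 1] > 0 and (
                    counts[t] == 0
                    or abs(counts[t] - counts[t - 1]) / counts[t - 1] >= threshold):
                flagged.add(concept)
    return flagged, set(by_concept)


# --------------------------------------------------------------------------
# missing / special values
# --------------------------------------------------------------------------

TOY_VALUES = ["", "-", "*", "A1", "NULL", " na ", "ok", "..", "x-y", None]


def test_missing_special_toy_matches_hand_enumeration(tmp_path):
    d = make_dataset(tmp_path / "d", {
        "t": pd.DataFrame({"v": pd.array(TOY_VALUES, dtype="string")})})
    res = ca.run_missing_special(ca.open_dataset(d), "t", "v")
    # hand scan: "",-,*,NULL," na ",..,None flagged; A1, ok, x-y pass
    assert (res.flagged, res.total) == (7, 10)
    assert res.flagged == oracle_missing_special(read_records(d / "t.csv"), "v")
    assert res.proportion_pct == 70.0


def test_missing_special_clean_column_zero(clean_copy):
    res = ca.run_missing_special(ca.open_dataset(clean_copy), "care_site",
                                 "care_site_name")
    assert res.flagged == 0 and res.proportion_pct == 0.0


def test_vocabulary_version_printed_fraction(tmp_path):
    values = pd.array([None] * 38 + ["v5"] * 86, dtype="string")
    d = make_dataset(tmp_path / "d", {"vocabulary": pd.DataFrame(
        {"vocabulary_version": values})})
    res = ca.run_missing_special(ca.open_dataset(d), "vocabulary",
                                 "vocabulary_version")
    assert (res.flagged, res.total, res.proportion_pct) == (38, 124, 30.6)


def test_absent_column_flags_everything_with_warning(clean_copy):
    res = ca.run_missing_special(ca.open_dataset(clean_copy), "person", "ghost")
    assert res.flagged == res.total > 0
    assert "column-absent" in res.warnings


def test_not_available_table_is_result_not_exception(clean_copy):
    (clean_copy / "note.csv").unlink()
    res = ca.run_missing_special(ca.open_dataset(clean_copy), "note", "note_text")
    assert res.interpretation is ca.Interpretation.not_applicable
    assert (res.flagged, res.total) == (0, 0) and res.proportion_pct is None


def test_expected_null_changes_interpretation_not_counts(tmp_path):
    d = make_dataset(tmp_path / "d", {"t": pd.DataFrame(
        {"invalid_reason": pd.array([None] * 5, dtype="string")})})
    h = ca.open_dataset(d)
    inc = ca.run_missing_special(h, "t", "invalid_reason")
    exp = ca.run_missing_special(h, "t", "invalid_reason",
                                 semantic_class=ca.SemanticClass.expected_null)
    assert (inc.flagged, inc.total) == (exp.flagged, exp.total) == (5, 5)
    assert inc.proportion_pct == exp.proportion_pct == 100.0
    assert inc.interpretation is ca.Interpretation.deficit
    assert exp.interpretation is ca.Interpretation.valid_by_default


# --------------------------------------------------------------------------
# unmapped concepts
# --------------------------------------------------------------------------

def test_unmapped_persons_hand_enumeration(tmp_path):
    # 6 persons; p2 and p5 each have one unmapped drug record
    df = pd.DataFrame({
        "person_id": ["p1", "p2", "p2", "p3", "p4", "p5", "p6"],
        "drug_concept_id": ["10", "0", "11", "12", "13", None, "14"],
    })
    d = make_dataset(tmp_path / "d", {"drug_exposure": df})
    res = ca.run_unmapped(ca.open_dataset(d), "drug_exposure", "drug_concept_id",
                          unit="persons")
    assert (res.flagged, res.total) == (2, 6)
    assert (res.flagged, res.total) == oracle_unmapped(
        read_records(d / "drug_exposure.csv"), "drug_concept_id", "persons")


def test_unmapped_all_and_none(tmp_path):
    d = make_dataset(tmp_path / "d", {
        "person": pd.DataFrame({"person_id": range(1, 6),
                                "ethnicity_concept_id": [0] * 5,
                                "race_concept_id": [38003585] * 5})})
    h = ca.open_dataset(d)
    assert ca.run_unmapped(h, "person", "ethnicity_concept_id").proportion_pct == 100.0
    assert ca.run_unmapped(h, "person", "race_concept_id").flagged == 0


def test_unmapped_rows_vs_persons_units(tmp_path):
    df = pd.DataFrame({"person_id": ["a", "a", "b"],
                       "c_id": ["0", "0", "5"]})
    d = make_dataset(tmp_path / "d", {"t": df})
    h = ca.open_dataset(d)
    rows = ca.run_unmapped(h, "t", "c_id", unit="rows")
    persons = ca.run_unmapped(h, "t", "c_id", unit="persons")
    assert (rows.flagged, rows.total) == (2, 3)
    assert (persons.flagged, persons.total) == (1, 2)


# --------------------------------------------------------------------------
# temporal discontinuities
# --------------------------------------------------------------------------

@pytest.mark.parametrize("counts, flagged_positions", [
    ([5, 5, 5], []),          # constant series: zero change
    ([5, 0, 3], [1]),         # drop to zero is a 100% change
    ([4, 8], [1]),            # |8-4|/4 = 1.0 >= threshold
    ([4, 7], []),             # 75% change, below threshold
    ([0, 0, 3, 3], []),       # rise from zero is an onset, not a flag
    ([2, 1, 2], [2]),         # 1 -> 2 doubles
])
def test_series_detector_cases(counts, flagged_positions):
    flags, _ = series_discontinuities(counts, threshold=1.0)
    assert flags == flagged_positions


def _month_table(concept_counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    rows = []
    for concept, by_month in concept_counts.items():
        for month, k in by_month.items():
            rows += [{"c_id": concept, "d": f"{month}-10"}] * k
    return pd.DataFrame(rows)


def test_temporal_engine_gap_and_stability(tmp_path):
    df = _month_table({
        "steady": {"2020-01": 5, "2020-02": 5, "2020-03": 5},
        "gapped": {"2020-01": 5, "2020-03": 3},   # implicit zero in 2020-02
    })
    d = make_dataset(tmp_path / "d", {"t": df})
    res = ca.run_temporal_discontinuity(ca.open_dataset(d), "t", "c_id", "d")
    flagged = {fc["concept"] for fc in res.detail["flagged_concepts"]}
    assert flagged == {"gapped"}
    assert (res.flagged, res.total) == (1, 2)
    assert res.detail["flagged_concepts"][0]["month_pair"] == ["2020-01", "2020-02"]
    oracle_flags, oracle_concepts = oracle_temporal(
        read_records(d / "t.csv"), "c_id", "d")
    assert flagged == oracle_flags and res.total == len(oracle_concepts)


def test_temporal_adjacent_months_switch(tmp_path):
    # same gapped series: with gap filling it flags; comparing observed
    # months only (5 -> 3 is a 40% change) it does not
    df = _month_table({"g": {"2020-01": 5, "2020-03": 3}})
    d = make_dataset(tmp_path / "d", {"t": df})
    h = ca.open_dataset(d)
    assert ca.run_temporal_discontinuity(h, "t", "c_id", "d").flagged == 1
    assert ca.run_temporal_discontinuity(h, "t", "c_id", "d",
                                         fill_gap_months=False).flagged == 0


def test_temporal_order_invariance(tmp_path):
    df = _month_table({"a": {"2020-01": 3, "2020-02": 6},
                       "b": {"2020-01": 2, "2020-02": 2}})
    d1 = make_dataset(tmp_path / "d1", {"t": df})
    d2 = make_dataset(tmp_path / "d2",
                      {"t": df.sample(frac=1.0, random_state=4)})
    r1 = ca.run_temporal_discontinuity(ca.open_dataset(d1), "t", "c_id", "d")
    r2 = ca.run_temporal_discontinuity(ca.open_dataset(d2), "t", "c_id", "d")
    assert r1.to_dict() == r2.to_dict()


def test_temporal_unparseable_dates_not_applicable(tmp_path):
    d = make_dataset(tmp_path / "d", {"t": pd.DataFrame(
        {"c_id": ["a"], "d": ["not-a-date"]})})
    res = ca.run_temporal_discontinuity(ca.open_dataset(d), "t", "c_id", "d")
    assert res.interpretation is ca.Interpretation.not_applicable


# --------------------------------------------------------------------------
# value ranges
# --------------------------------------------------------------------------

def test_value_range_strict_bound(tmp_path):
    d = make_dataset(tmp_path / "d", {"drug_exposure": pd.DataFrame({
        "drug_concept_id": ["1", "1", "2"],
        "days_supply": ["30", "90", "181"]})})
    res = ca.run_value_range(ca.open_dataset(d), "drug_exposure", "days_supply",
                             bound=180, group_column="drug_concept_id")
    assert res.flagged == 1
    assert res.detail["per_concept_extreme"] == {"2": 181.0}


def test_value_range_boundary_inclusive_and_extremes(tmp_path):
    d = make_dataset(tmp_path / "d", {"t": pd.DataFrame({
        "g": ["1", "1", "2"], "quantity": ["601", "650", "600"]})})
    res = ca.run_value_range(ca.open_dataset(d), "t", "quantity", bound=600,
                             group_column="g")
    assert res.flagged == 2  # 600 itself passes: bounds are strict
    assert res.detail["per_concept_extreme"] == {"1": 650.0}
    assert res.flagged == oracle_value_range(read_records(d / "t.csv"),
                                             "quantity", 600)


def test_value_range_nonnumeric_skipped_and_counted(tmp_path):
    d = make_dataset(tmp_path / "d", {"t": pd.DataFrame(
        {"v": ["10", "abc", "700", None]})})
    res = ca.run_value_range(ca.open_dataset(d), "t", "v", bound=600)
    assert res.flagged == 1
    assert res.detail["nonnumeric_skipped"] == 1


def test_value_range_min_ge_direction(tmp_path):
    d = make_dataset(tmp_path / "d", {"t": pd.DataFrame({"v": ["0", "-1", "5"]})})
    res = ca.run_value_range(ca.open_dataset(d), "t", "v", bound=0,
                             direction="min_ge")
    assert res.flagged == 1


# --------------------------------------------------------------------------
# rulebook plumbing
# --------------------------------------------------------------------------

def test_default_rulebook_contents(rulebook):
    by_id = {r.id: r for r in rulebook}
    vv = by_id["vocabulary.vocabulary_version.missing"]
    assert (vv.table, vv.column, vv.kind) == (
        "vocabulary", "vocabulary_version", ca.RuleKind.missing_or_special)
    assert by_id["concept_relationship.invalid_reason.missing"].semantic_class \
        is ca.SemanticClass.expected_null
    kinds = {r.kind for r in rulebook}
    assert kinds == set(ca.RuleKind)


def test_load_rulebook_single_and_invalid(tmp_path):
    path = tmp_path / "r.yaml"
    path.write_text(
        "rules:\n"
        "  - {id: r1, kind: missing_or_special, table: t, column: v}\n")
    assert len(ca.load_rulebook(path)) == 1
    path.write_text(
        "rules:\n"
        "  - {id: bad, kind: value_range, table: t, column: v}\n")
    with pytest.raises(RulebookError, match="bad"):
        ca.load_rulebook(path)
    path.write_text("rules:\n  - {id: r2, kind: bogus_kind, table: t, column: v}\n")
    with pytest.raises(RulebookError, match="r2"):
        ca.load_rulebook(path)


def test_run_rulebook_order_and_not_applicable(clean_copy, rulebook):
    (clean_copy / "condition_era.csv").unlink()
    results = ca.run_rulebook(ca.open_dataset(clean_copy), rulebook)
    assert [r.rule_id for r in results] == [r.id for r in rulebook]
    na = {r.rule_id for r in results
          if r.interpretation is ca.Interpretation.not_applicable}
    assert "condition_era.condition.unmapped" in na
    assert "condition_era.monthly_change" in na
    assert ca.run_rulebook(ca.open_dataset(clean_copy), []) == []


def test_clean_dataset_zero_incompleteness_flags(clean_dataset, rulebook):
    results = ca.run_rulebook(ca.open_dataset(clean_dataset), rulebook)
    for r in results:
        if r.semantic_class is ca.SemanticClass.incompleteness:
            assert r.flagged == 0, r.rule_id
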