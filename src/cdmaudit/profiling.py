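"""Descriptive completeness/diversity profiling.

Distributions of persons and records across demographic groups, mapped
standard vocabularies, visit types, and the most frequently recorded clinical
concepts. There is no gold-standard distribution to compare against: these
profiles exist so a researcher can judge whether the dataset covers the
population and clinical contexts an intended study needs.

Counting conventions follow common practice for CDM characterisation:
demographic and per-person concept profiles count distinct persons (a person
is never double-counted within one category, and percentages of overlapping
categories such as visit types may legitimately sum above 100); vocabulary
profiles count table rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .dataset import DatasetHandle, NotAvailableError
from ._util import pct

RESERVED_UNMAPPED_ID = 0
RESERVED_UNMAPPED_LABEL = "No matching concept"


class ConceptDictionary:
    """Concept id -> (name, vocabulary, domain) lookup.

    Id 0 is always present as the reserved "No matching concept" entry; unknown
    ids render as ``concept:<id>`` so profiling never fails on dictionary gaps.
    """

    def __init__(self, entries: dict[int, tuple[str, str, str]] | None = None):
        self.entries: dict[int, tuple[str, str, str]] = dict(entries or {})
        self.entries.setdefault(RESERVED_UNMAPPED_ID, (RESERVED_UNMAPPED_LABEL, "None", "Metadata"))
        name, voc, dom = self.entries[RESERVED_UNMAPPED_ID]
        if name != RESERVED_UNMAPPED_LABEL:
            raise ValueError(f"concept id 0 must be labelled {RESERVED_UNMAPPED_LABEL!r}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConceptDictionary":
        df = pd.read_csv(path, dtype={"concept_id": "int64"})
        df.columns = [c.lower() for c in df.columns]
        needed = {"concept_id", "concept_name", "vocabulary_id", "domain_id"}
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"concept dictionary {path} lacks columns: {sorted(missing)}")
        entries = {
            int(r.concept_id): (str(r.concept_name), str(r.vocabulary_id), str(r.domain_id))
            for r in df.itertuples()
        }
        return cls(entries)

    def name(self, concept_id: object) -> str:
        cid = _as_int(concept_id)
        if cid is None or cid == RESERVED_UNMAPPED_ID:
            return RESERVED_UNMAPPED_LABEL
        if cid in self.entries:
            return self.entries[cid][0]
        return f"concept:{cid}"

    def vocabulary(self, concept_id: object) -> str | None:
        cid = _as_int(concept_id)
        if cid is None or cid == RESERVED_UNMAPPED_ID:
            return None
        entry = self.entries.get(cid)
        return entry[1] if entry else None

    def domain(self, concept_id: object) -> str | None:
        cid = _as_int(concept_id)
        entry = self.entries.get(cid) if cid is not None else None
        return entry[2] if entry else None

    def __len__(self) -> int:
        return len(self.entries)

    def ids_for_domain(self, domain: str, vocabulary: str | None = None) -> list[int]:
        return sorted(
            cid for cid, (_, voc, dom) in self.entries.items()
            if dom == domain and cid != 0 and (vocabulary is None or voc == vocabulary)
        )


def _as_int(value: object) -> int | None:
    try:
        if value is None or (isinstance(value, float) and pd.isna(value)) or pd.isna(value):
            return None
    except (TypeError, ValueError):
        pass
    try:
        return int(float(str(value)))
    except (TypeError, ValueError):
        return None


def default_dictionary() -> ConceptDictionary:
    ref = resources.files("cdmaudit.data").joinpath("concepts_default.csv")
    with resources.as_file(ref) as path:
        return ConceptDictionary.from_csv(path)


def default_dictionary_path() -> Path:
    return Path(str(resources.files("cdmaudit.data").joinpath("concepts_default.csv")))


@dataclass
class CategoryDistribution:
    dimension: str
    unit: str                      # "persons" or "rows"
    entries: list[tuple[str, int, float]]   # (label, count, percent)
    denominator: int
    multi_membership: bool = False
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension, "unit": self.unit,
            "entries": [{"category": c, "count": n, "percent": p}
                        for c, n, p in self.entries],
            "denominator": self.denominator,
            "multi_membership": self.multi_membership,
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CategoryDistribution":
        return cls(dimension=d["dimension"], unit=d["unit"],
                   entries=[(e["category"], e["count"], e["percent"])
                            for e in d["entries"]],
                   denominator=d["denominator"],
                   multi_membership=d.get("multi_membership", False),
                   warnings=list(d.get("warnings", [])))

    def as_mapping(self) -> dict[str, tuple[int, float]]:
        return {c: (n, p) for c, n, p in self.entries}


def _distribution(dimension: str, unit: str, counts: dict[str, int], denominator: int,
                  multi: bool = False) -> CategoryDistribution:
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    entries = [(label, n, pct(n, denominator) if denominator else 0.0)
               for label, n in ordered]
    return CategoryDistribution(dimension=dimension, unit=unit, entries=entries,
                                denominator=denominator, multi_membership=multi)


def _not_applicable_profile(dimension: str, unit: str, reason: str) -> CategoryDistribution:
    return CategoryDistribution(dimension=dimension, unit=unit, entries=[],
                                denominator=0, warnings=[reason])


def demographic_profile(handle: DatasetHandle, dictionary: ConceptDictionary
                        ) -> list[CategoryDistribution]:
    """Person-level sex, race and ethnicity distributions.

    The denominator is the person-table record count; concept ids resolve
    through the dictionary, with missing/0 rendered "No matching concept".
    """
    try:
        person = handle.read_table("person")
    except NotAvailableError:
        return [_not_applicable_profile(dim, "persons", "person-table-not-available")
                for dim in ("sex", "race", "ethnicity")]
    denominator = len(person)
    out = []
    for dimension, column in (("sex", "gender_concept_id"),
                              ("race", "race_concept_id"),
                              ("ethnicity", "ethnicity_concept_id")):
        if column not in person.columns:
            out.append(_not_applicable_profile(dimension, "persons",
                                               f"column-absent:{column}"))
            continue
        labels = person[column].map(dictionary.name)
        counts = labels.value_counts().to_dict()
        out.append(_distribution(dimension, "persons",
                                 {str(k): int(v) for k, v in counts.items()},
                                 denominator))
    return out


def vocabulary_distribution(handle: DatasetHandle, table: str, concept_column: str,
                            dictionary: ConceptDictionary,
                            other_threshold_pct: float = 0.5) -> CategoryDistribution:
    """Row counts per mapped standard vocabulary for one clinical table.

    Vocabularies individually below ``other_threshold_pct`` percent of rows
    collapse into "Other"; concepts the dictionary cannot resolve (including
    id 0) are counted under "Unmapped/Unknown", never dropped.
    """
    dimension = f"vocabulary:{table}"
    try:
        df = handle.read_table(table)
    except NotAvailableError:
        return _not_applicable_profile(dimension, "rows", "table-not-available")
    concept_column = concept_column.lower()
    if concept_column not in df.columns:
        return _not_applicable_profile(dimension, "rows",
                                       f"column-absent:{concept_column}")
    total = len(df)
    ids = pd.to_numeric(df[concept_column], errors="coerce")
    id_counts = ids.value_counts(dropna=False)
    vocab_counts: dict[str, int] = {}
    for cid, n in id_counts.items():
        voc = dictionary.vocabulary(cid)
        key = voc if voc is not None else "Unmapped/Unknown"
        vocab_counts[key] = vocab_counts.get(key, 0) + int(n)
    collapsed: dict[str, int] = {}
    for voc, n in vocab_counts.items():
        share = 100 * n / total if total else 0.0
        if voc != "Unmapped/Unknown" and share < other_threshold_pct:
            collapsed["Other"] = collapsed.get("Other", 0) + n
        else:
            collapsed[voc] = collapsed.get(voc, 0) + n
    return _distribution(dimension, "rows", collapsed, total)


def visit_type_profile(handle: DatasetHandle, dictionary: ConceptDictionary
                       ) -> CategoryDistribution:
    """Distinct persons with at least one visit of each visit-type concept.

    Percentages use all persons as the denominator and may sum above 100
    because one person can have several visit types (multi-membership).
    """
    try:
        person = handle.read_table("person")
        visits = handle.read_table("visit_occurrence")
    except NotAvailableError as exc:
        return _not_applicable_profile("visit_type", "persons", str(exc))
    if "visit_concept_id" not in visits.columns or "person_id" not in visits.columns:
        return _not_applicable_profile("visit_type", "persons", "column-absent")
    denominator = len(person)
    labels = visits["visit_concept_id"].map(dictionary.name)
    counts = (
        pd.DataFrame({"label": labels, "person": visits["person_id"]})
        .groupby("label", observed=True)["person"].nunique().to_dict()
    )
    dist = _distribution("visit_type", "persons",
                         {str(k): int(v) for k, v in counts.items()},
                         denominator, multi=True)
    return dist


def top_concepts_by_person(handle: DatasetHandle, table: str, concept_column: str,
                           dictionary: ConceptDictionary, n: int = 3
                           ) -> CategoryDistribution:
    """Top-n concepts in a clinical table ranked by distinct-person coverage.

    Ties break by ascending concept id. Percent of all persons; a person with
    several of the top concepts counts once under each (multi-membership).
    """
    dimension = f"top_concepts:{table}"
    try:
        person = handle.read_table("person")
        df = handle.read_table(table)
    except NotAvailableError as exc:
        return _not_applicable_profile(dimension, "persons", str(exc))
    concept_column = concept_column.lower()
    if concept_column not in df.columns or "person_id" not in df.columns:
        return _not_applicable_profile(dimension, "persons", "column-absent")
    denominator = len(person)
    ids = pd.to_numeric(df[concept_column], errors="coerce").fillna(0).astype("int64")
    per_concept = (
        pd.DataFrame({"concept": ids, "person": df["person_id"]})
        .groupby("concept", observed=True)["person"].nunique()
    )
    ranked = sorted(per_concept.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    entries = [(dictionary.name(cid), int(cnt),
                pct(int(cnt), denominator) if denominator else 0.0)
               for cid, cnt in ranked]
    return CategoryDistribution(dimension=dimension, unit="persons", entries=entries,
                                denominator=denominator, multi_membership=True)


def standard_profiles(handle: DatasetHandle, dictionary: ConceptDictionary,
                      top_n: int = 3) -> list[CategoryDistribution]:
    """The default profiling battery: demographics, visit types, per-domain
    vocabulary distributions, and top concepts for the major clinical tables."""
    profiles = demographic_profile(handle, dictionary)
    profiles.append(visit_type_profile(handle, dictionary))
    for table, col in (("measurement", "measurement_concept_id"),
                       ("drug_exposure", "drug_concept_id"),
                       ("observation", "observation_concept_id"),
                       ("procedure_occurrence", "procedure_concept_id")):
        profiles.append(vocabulary_distribution(handle, table, col, dictionary))
    for table, col in (("condition_occurrence", "condition_concept_id"),
                       ("drug_exposure", "drug_concept_id"),
                       ("measurement", "measurement_concept_id")):
        profiles.append(top_concepts_by_person(handle, table, col, dictionary, n=top_n))
    return profiles
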