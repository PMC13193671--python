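"""Declarative completeness rule engine.

Four rule kinds cover the completeness failure modes a CDM-style clinical
database exhibits:

``missing_or_special``
    A value column is flagged when a record's value is missing, or — after
    whitespace trimming — empty, equal (case-insensitively) to a sentinel
    string ("NULL", "NA", "N/A", "UNKNOWN" by default), or composed entirely
    of special characters (``* - . ? # / \\ + , _``). Source-value fields in
    real EHR extracts accumulate exactly these placeholder artifacts.

``unmapped_concept``
    A record is unmapped when its standard-concept id is missing or 0 (the
    reserved "No matching concept" sentinel). Counted in rows or in distinct
    persons having at least one unmapped record.

``temporal_discontinuity``
    Events are bucketed per concept x calendar month; a concept is flagged
    when, between consecutive months within its active span (zero-count
    months in between included by default), the relative change
    |c_t - c_{t-1}| / c_{t-1} reaches the threshold (default 1.0, i.e. a
    100% change) or the count drops from positive to zero. Rises from zero
    are onsets, reported separately and never flagged — otherwise every
    concept's first month would fire.

``value_range``
    Records whose numeric value strictly violates a bound (value > bound for
    ``max_le``, value < bound for ``min_ge``) are flagged; a value equal to
    the bound passes. Non-numeric values are skipped and counted separately.

Semantics matter as much as counts: a rule may be tagged
``semantic_class: expected_null`` (e.g. the vocabulary ``invalid_reason``
column, which is NULL by default and populated only on deprecation). Such a
rule still reports its flagged fraction — possibly 100% — but its
interpretation is ``valid_by_default``, never a deficit.
"""

from __future__ import annotations

import enum
import re
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Callable, Iterable, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .dataset import DatasetHandle, NotAvailableError
from ._util import pct

DEFAULT_SPECIAL_VALUES: frozenset[str] = frozenset({"NULL", "NA", "N/A", "UNKNOWN"})
#: characters a value may consist solely of to count as a special entry
DEFAULT_SPECIAL_CHARS: str = r"*-.?#/\+,_"


class RuleKind(str, enum.Enum):
    missing_or_special = "missing_or_special"
    unmapped_concept = "unmapped_concept"
    temporal_discontinuity = "temporal_discontinuity"
    value_range = "value_range"


class SemanticClass(str, enum.Enum):
    incompleteness = "incompleteness"
    expected_null = "expected_null"


class RuleSpec(BaseModel):
    id: str = Field(min_length=1)
    kind: RuleKind
    table: str
    column: str
    params: dict[str, Any] = Field(default_factory=dict)
    semantic_class: SemanticClass = SemanticClass.incompleteness

    @model_validator(mode="after")
    def _check_params(self) -> "RuleSpec":
        p = self.params
        if self.kind is RuleKind.value_range:
            if "bound" not in p:
                raise ValueError(f"rule {self.id!r}: value_range requires params.bound")
            direction = p.get("direction", "max_le")
            if direction not in ("max_le", "min_ge"):
                raise ValueError(f"rule {self.id!r}: direction must be max_le or min_ge")
        if self.kind is RuleKind.temporal_discontinuity:
            if "date_column" not in p:
                raise ValueError(
                    f"rule {self.id!r}: temporal_discontinuity requires params.date_column")
            thr = p.get("threshold", 1.0)
            if not (isinstance(thr, (int, float)) and thr > 0):
                raise ValueError(f"rule {self.id!r}: threshold must be a positive number")
        if self.kind is RuleKind.unmapped_concept:
            unit = p.get("unit", "persons")
            if unit not in ("rows", "persons"):
                raise ValueError(f"rule {self.id!r}: unit must be rows or persons")
        return self


class Interpretation(str, enum.Enum):
    deficit = "deficit"
    valid_by_default = "valid_by_default"
    not_applicable = "not_applicable"


@dataclass
class RuleResult:
    rule_id: str
    kind: RuleKind
    table: str
    column: str
    flagged: int
    total: int
    proportion_pct: float | None
    semantic_class: SemanticClass
    interpretation: Interpretation
    detail: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    elapsed_s: float | None = None

    def to_dict(self) -> dict:
        return {
            "rule_id": self.rule_id, "kind": self.kind.value, "table": self.table,
            "column": self.column, "flagged": self.flagged, "total": self.total,
            "proportion_pct": self.proportion_pct,
            "semantic_class": self.semantic_class.value,
            "interpretation": self.interpretation.value,
            "detail": self.detail, "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleResult":
        return cls(rule_id=d["rule_id"], kind=RuleKind(d["kind"]), table=d["table"],
                   column=d["column"], flagged=d["flagged"], total=d["total"],
                   proportion_pct=d["proportion_pct"],
                   semantic_class=SemanticClass(d["semantic_class"]),
                   interpretation=Interpretation(d["interpretation"]),
                   detail=d.get("detail", {}), warnings=list(d.get("warnings", [])))


class RulebookError(ValueError):
    """Malformed rulebook file or invalid rule definition."""


def load_rulebook(path: str | Path) -> list[RuleSpec]:
    """Load and validate a YAML rulebook (``rules:`` -> list of rule mappings)."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise RulebookError(f"malformed rulebook {path}: {exc}") from exc
    if not isinstance(raw, dict) or not isinstance(raw.get("rules"), list):
        raise RulebookError(f"rulebook {path} must be a mapping with a 'rules' list")
    rules = []
    for entry in raw["rules"]:
        rid = entry.get("id", "<missing id>") if isinstance(entry, dict) else "<bad entry>"
        try:
            rules.append(RuleSpec.model_validate(entry))
        except Exception as exc:
            raise RulebookError(f"invalid rule {rid!r}: {exc}") from exc
    return rules


def default_rulebook() -> list[RuleSpec]:
    """The bundled default rulebook: 11 missing/special-value table-column
    checks, per-domain unmapped-concept and monthly-change checks, and the two
    prescription value-range bounds."""
    ref = resources.files("cdmaudit.data").joinpath("rulebook_default.yaml")
    raw = yaml.safe_load(ref.read_text())
    return [RuleSpec.model_validate(e) for e in raw["rules"]]


def default_rulebook_path() -> Path:
    return Path(str(resources.files("cdmaudit.data").joinpath("rulebook_default.yaml")))


# ---------------------------------------------------------------------------
# result plumbing
# ---------------------------------------------------------------------------

def _interp(semantic_class: SemanticClass, total: int) -> Interpretation:
    if total == 0:
        return Interpretation.not_applicable
    if semantic_class is SemanticClass.expected_null:
        return Interpretation.valid_by_default
    return Interpretation.deficit


def _result(rule_id: str, kind: RuleKind, table: str, column: str, flagged: int,
            total: int, semantic_class: SemanticClass, detail: dict | None = None,
            warnings_: list[str] | None = None) -> RuleResult:
    proportion = pct(flagged, total) if total > 0 else None
    return RuleResult(rule_id=rule_id, kind=kind, table=table, column=column,
                      flagged=flagged, total=total, proportion_pct=proportion,
                      semantic_class=semantic_class,
                      interpretation=_interp(semantic_class, total),
                      detail=detail or {}, warnings=warnings_ or [])


def _not_applicable(rule_id: str, kind: RuleKind, table: str, column: str,
                    semantic_class: SemanticClass, reason: str) -> RuleResult:
    return RuleResult(rule_id=rule_id, kind=kind, table=table, column=column,
                      flagged=0, total=0, proportion_pct=None,
                      semantic_class=semantic_class,
                      interpretation=Interpretation.not_applicable,
                      detail={"reason": reason})


# ---------------------------------------------------------------------------
# rule kernels
# ---------------------------------------------------------------------------

def missing_or_special_mask(values: pd.Series,
                            special_values: Iterable[str] = DEFAULT_SPECIAL_VALUES,
                            special_chars: str = DEFAULT_SPECIAL_CHARS) -> pd.Series:
    """Boolean mask of values that are missing or special-character entries."""
    s = values.astype("string")
    stripped = s.str.strip()
    mask = s.isna() | stripped.eq("")
    sent = {v.upper() for v in special_values}
    if sent:
        mask |= stripped.str.upper().isin(sent).fillna(False)
    if special_chars:
        pattern = "[" + re.escape(special_chars) + "]+"
        mask |= stripped.str.fullmatch(pattern).fillna(False)
    return mask.fillna(True).astype(bool)


def run_missing_special(handle: DatasetHandle, table: str, column: str,
                        special_values: Iterable[str] = DEFAULT_SPECIAL_VALUES,
                        special_chars: str = DEFAULT_SPECIAL_CHARS,
                        rule_id: str = "",
                        semantic_class: SemanticClass = SemanticClass.incompleteness,
                        _df: pd.DataFrame | None = None) -> RuleResult:
    """Count records whose value is missing (NULL) or a special-character entry.

    An absent column is the strongest incompleteness: every record is flagged
    and a ``column-absent`` warning recorded.
    """
    rule_id = rule_id or f"{table}.{column}.missing_or_special"
    kind = RuleKind.missing_or_special
    column = column.lower()
    try:
        df = _df if _df is not None else handle.read_table(table)
    except NotAvailableError:
        return _not_applicable(rule_id, kind, table, column, semantic_class,
                               "table-not-available")
    total = len(df)
    warnings_: list[str] = []
    if column not in df.columns:
        warnings_.append("column-absent")
        flagged = total
    else:
        flagged = int(missing_or_special_mask(
            df[column], special_values, special_chars).sum())
    return _result(rule_id, kind, table, column, flagged, total, semantic_class,
                   warnings_=warnings_)


def unmapped_mask(concept_ids: pd.Series) -> pd.Series:
    """True where a concept id is missing or the 'No matching concept' id 0."""
    ids = pd.to_numeric(concept_ids, errors="coerce")
    return (ids.isna() | (ids == 0)).astype(bool)


def run_unmapped(handle: DatasetHandle, table: str, concept_column: str,
                 unit: str = "persons", person_column: str = "person_id",
                 rule_id: str = "",
                 semantic_class: SemanticClass = SemanticClass.incompleteness,
                 _df: pd.DataFrame | None = None) -> RuleResult:
    """Count records (or distinct persons) carrying unmapped standard concepts."""
    rule_id = rule_id or f"{table}.{concept_column}.unmapped"
    kind = RuleKind.unmapped_concept
    concept_column = concept_column.lower()
    try:
        df = _df if _df is not None else handle.read_table(table)
    except NotAvailableError:
        return _not_applicable(rule_id, kind, table, concept_column, semantic_class,
                               "table-not-available")
    warnings_: list[str] = []
    if concept_column not in df.columns:
        warnings_.append("column-absent")
        mask = pd.Series(True, index=df.index)
    else:
        mask = unmapped_mask(df[concept_column])
    if unit == "rows":
        flagged, total = int(mask.sum()), len(df)
    else:
        person_column = person_column.lower()
        if person_column not in df.columns:
            return _not_applicable(rule_id, kind, table, concept_column, semantic_class,
                                   f"person-column-absent:{person_column}")
        persons = df[person_column]
        total = int(persons.nunique(dropna=True))
        flagged = int(persons[mask].nunique(dropna=True))
    return _result(rule_id, kind, table, concept_column, flagged, total,
                   semantic_class, detail={"unit": unit}, warnings_=warnings_)


def series_discontinuities(counts: Sequence[int], threshold: float = 1.0
                           ) -> tuple[list[int], list[int]]:
    """Scan a monthly count series for discontinuities.

    Returns ``(flag_positions, onset_positions)`` where position ``t`` refers
    to the transition from month ``t-1`` to month ``t``. A transition flags
    when the previous count is positive and either the count drops to zero or
    the relative change reaches the threshold. A rise from zero is an onset.
    """
    flags: list[int] = []
    onsets: list[int] = []
    for t in range(1, len(counts)):
        prev, cur = counts[t - 1], counts[t]
        if prev > 0:
            if cur == 0 or abs(cur - prev) / prev >= threshold:
                flags.append(t)
        elif cur > 0:
            onsets.append(t)
    return flags, onsets


def run_temporal_discontinuity(handle: DatasetHandle, table: str, concept_column: str,
                               date_column: str, threshold: float = 1.0,
                               fill_gap_months: bool = True, rule_id: str = "",
                               semantic_class: SemanticClass = SemanticClass.incompleteness,
                               _df: pd.DataFrame | None = None) -> RuleResult:
    """Flag concepts whose monthly event counts change abruptly.

    ``fill_gap_months=True`` (default) inserts zero-count months between a
    concept's first and last observed month, so a recording gap is seen as a
    drop to zero; ``False`` compares adjacent observed months only.
    ``flagged``/``total`` count concepts, not records; the detail payload
    lists each flagged concept with its first offending month pair.
    """
    rule_id = rule_id or f"{table}.{concept_column}.temporal_discontinuity"
    kind = RuleKind.temporal_discontinuity
    concept_column, date_column = concept_column.lower(), date_column.lower()
    try:
        df = _df if _df is not None else handle.read_table(table)
    except NotAvailableError:
        return _not_applicable(rule_id, kind, table, concept_column, semantic_class,
                               "table-not-available")
    for col in (concept_column, date_column):
        if col not in df.columns:
            return _not_applicable(rule_id, kind, table, concept_column, semantic_class,
                                   f"column-absent:{col}")
    dates = pd.to_datetime(df[date_column], format="ISO8601", errors="coerce")
    valid = dates.notna()
    n_bad_dates = int((~valid).sum())
    if valid.sum() == 0:
        return _not_applicable(rule_id, kind, table, concept_column, semantic_class,
                               "no-parseable-dates")
    months = dates[valid].dt.to_period("M")
    concepts = df.loc[valid, concept_column].fillna("<missing>")
    grouped = (
        pd.DataFrame({"concept": concepts, "month": months})
        .groupby(["concept", "month"], observed=True).size()
    )
    flagged_detail: list[dict] = []
    n_concepts = 0
    for concept, series in grouped.groupby(level=0, observed=True):
        n_concepts += 1
        s = series.droplevel(0).sort_index()
        if fill_gap_months:
            full = pd.period_range(s.index.min(), s.index.max(), freq="M")
            s = s.reindex(full, fill_value=0)
        counts = s.to_list()
        flags, _onsets = series_discontinuities(counts, threshold)
        if flags:
            t = flags[0]
            flagged_detail.append({
                "concept": str(concept),
                "month_pair": [str(s.index[t - 1]), str(s.index[t])],
                "counts": [int(counts[t - 1]), int(counts[t])],
            })
    flagged_detail.sort(key=lambda d: d["concept"])
    detail = {"flagged_concepts": flagged_detail, "unparseable_dates": n_bad_dates,
              "threshold": threshold, "fill_gap_months": fill_gap_months}
    return _result(rule_id, kind, table, concept_column, len(flagged_detail),
                   n_concepts, semantic_class, detail=detail)


def run_value_range(handle: DatasetHandle, table: str, value_column: str,
                    bound: float, direction: str = "max_le",
                    group_column: str | None = None, rule_id: str = "",
                    semantic_class: SemanticClass = SemanticClass.incompleteness,
                    _df: pd.DataFrame | None = None) -> RuleResult:
    """Flag records strictly violating a numeric bound.

    ``max_le``: values > bound flag (a value equal to the bound passes);
    ``min_ge``: values < bound flag. The detail payload carries the violating
    extreme per concept group and the count of non-numeric values skipped.
    """
    rule_id = rule_id or f"{table}.{value_column}.value_range"
    kind = RuleKind.value_range
    value_column = value_column.lower()
    try:
        df = _df if _df is not None else handle.read_table(table)
    except NotAvailableError:
        return _not_applicable(rule_id, kind, table, value_column, semantic_class,
                               "table-not-available")
    if value_column not in df.columns:
        return _not_applicable(rule_id, kind, table, value_column, semantic_class,
                               f"column-absent:{value_column}")
    raw = df[value_column]
    values = pd.to_numeric(raw, errors="coerce")
    nonnumeric = int((values.isna() & raw.notna()).sum())
    if direction == "max_le":
        violators = values > bound
    else:
        violators = values < bound
    flagged = int(violators.sum())
    per_group: dict[str, float] = {}
    if group_column and group_column.lower() in df.columns and flagged:
        gcol = df.loc[violators, group_column.lower()].fillna("<missing>")
        vvals = values[violators]
        agg = vvals.groupby(gcol.values).max() if direction == "max_le" \
            else vvals.groupby(gcol.values).min()
        per_group = {str(k): float(v) for k, v in sorted(agg.items(), key=lambda kv: str(kv[0]))}
    detail = {"bound": bound, "direction": direction,
              "per_concept_extreme": per_group, "nonnumeric_skipped": nonnumeric}
    return _result(rule_id, kind, table, value_column, flagged, len(df),
                   semantic_class, detail=detail)


# ---------------------------------------------------------------------------
# rulebook runner
# ---------------------------------------------------------------------------

def run_rule(handle: DatasetHandle, rule: RuleSpec,
             _df: pd.DataFrame | None = None) -> RuleResult:
    """Dispatch a single declarative rule to its kernel."""
    p = rule.params
    common = dict(rule_id=rule.id, semantic_class=rule.semantic_class, _df=_df)
    if rule.kind is RuleKind.missing_or_special:
        return run_missing_special(
            handle, rule.table, rule.column,
            special_values=p.get("special_values", DEFAULT_SPECIAL_VALUES),
            special_chars=p.get("special_chars", DEFAULT_SPECIAL_CHARS), **common)
    if rule.kind is RuleKind.unmapped_concept:
        return run_unmapped(
            handle, rule.table, rule.column, unit=p.get("unit", "persons"),
            person_column=p.get("person_column", "person_id"), **common)
    if rule.kind is RuleKind.temporal_discontinuity:
        return run_temporal_discontinuity(
            handle, rule.table, rule.column, date_column=p["date_column"],
            threshold=float(p.get("threshold", 1.0)),
            fill_gap_months=bool(p.get("fill_gap_months", True)), **common)
    return run_value_range(
        handle, rule.table, rule.column, bound=float(p["bound"]),
        direction=p.get("direction", "max_le"),
        group_column=p.get("group_column"), **common)


def run_rulebook(handle: DatasetHandle, rules: Sequence[RuleSpec],
                 log: Callable[[str], None] | None = None) -> list[RuleResult]:
    """Run every rule in rulebook order, reading each table at most once.

    Rules targeting not-available tables yield ``not_applicable`` results,
    never exceptions. Per-rule wall time is recorded on the result and
    optionally logged.
    """
    cache: dict[str, pd.DataFrame | None] = {}
    results: list[RuleResult] = []
    for rule in rules:
        t0 = time.perf_counter()
        table = rule.table.lower()
        if table not in cache:
            try:
                cache[table] = handle.read_table(table)
            except NotAvailableError:
                cache[table] = None
        df = cache[table]
        if df is None:
            res = _not_applicable(rule.id, rule.kind, rule.table, rule.column,
                                  rule.semantic_class, "table-not-available")
        else:
            res = run_rule(handle, rule, _df=df)
        res.elapsed_s = time.perf_counter() - t0
        if log is not None:
            log(f"rule {rule.id}: flagged={res.flagged}/{res.total} "
                f"({res.elapsed_s:.3f}s)")
        results.append(res)
    return results
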