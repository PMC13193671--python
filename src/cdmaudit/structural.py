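"""Structural completeness assessment: table availability, row counts, volume.

Every table the schema manifest expects is classified into exactly one of
three statuses:

* ``not_available`` — the table is not present and cannot be queried;
* ``empty``         — present but holding zero records;
* ``available``     — present with at least one record.

Aggregate percentages are computed over the full manifest (the expected
schema is the denominator, so absent tables count against it), rounded
half-up to one decimal. Interpretation notes distinguish an empty
ETL-derived table (derivation scripts likely never ran) from a missing
free-text table (narrative capture gap), which carry very different
remediation advice.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .dataset import DatasetHandle
from .schema import SchemaManifest, TableSpec
from ._util import pct


class TableStatus(str, enum.Enum):
    available = "available"
    empty = "empty"
    not_available = "not_available"


@dataclass
class TableReport:
    name: str
    status: TableStatus
    rows: int | None = None    # None for not_available tables
    bytes: int | None = None   # None for not_available tables
    note: str = "none"         # machine-readable interpretation code

    def to_dict(self) -> dict:
        return {"name": self.name, "status": self.status.value, "rows": self.rows,
                "bytes": self.bytes, "note": self.note}


@dataclass
class StructuralReport:
    per_table: dict[str, TableReport]
    n_tables: int
    n_available: int
    n_empty: int
    n_not_available: int
    pct_empty: float
    pct_not_available: float
    total_rows: int
    unexpected_tables: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_table": {k: v.to_dict() for k, v in self.per_table.items()},
            "n_tables": self.n_tables,
            "n_available": self.n_available,
            "n_empty": self.n_empty,
            "n_not_available": self.n_not_available,
            "pct_empty": self.pct_empty,
            "pct_not_available": self.pct_not_available,
            "total_rows": self.total_rows,
            "unexpected_tables": list(self.unexpected_tables),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StructuralReport":
        per_table = {
            k: TableReport(name=v["name"], status=TableStatus(v["status"]),
                           rows=v["rows"], bytes=v["bytes"], note=v.get("note", "none"))
            for k, v in d["per_table"].items()
        }
        return cls(per_table=per_table, n_tables=d["n_tables"],
                   n_available=d["n_available"], n_empty=d["n_empty"],
                   n_not_available=d["n_not_available"], pct_empty=d["pct_empty"],
                   pct_not_available=d["pct_not_available"], total_rows=d["total_rows"],
                   unexpected_tables=list(d.get("unexpected_tables", [])))


def classify_table(handle: DatasetHandle, spec: TableSpec) -> TableStatus:
    """Classify one expected table: not queryable / zero records / populated."""
    if not handle.table_exists(spec.name):
        return TableStatus.not_available
    if handle.row_count(spec.name) == 0:
        return TableStatus.empty
    return TableStatus.available


def structural_report(handle: DatasetHandle, manifest: SchemaManifest) -> StructuralReport:
    """Classify every manifest table and aggregate counts/percentages.

    Tables present in the dataset but absent from the manifest are listed under
    ``unexpected_tables`` and are not classified.
    """
    per_table: dict[str, TableReport] = {}
    total_rows = 0
    for spec in manifest:
        status = classify_table(handle, spec)
        if status is TableStatus.not_available:
            per_table[spec.name] = TableReport(spec.name, status)
        else:
            rows = handle.row_count(spec.name)
            nbytes = handle.table_bytes(spec.name)
            per_table[spec.name] = TableReport(spec.name, status, rows=rows, bytes=nbytes)
            total_rows += rows
    n = len(manifest)
    n_empty = sum(1 for r in per_table.values() if r.status is TableStatus.empty)
    n_na = sum(1 for r in per_table.values() if r.status is TableStatus.not_available)
    expected = set(manifest.table_names())
    unexpected = sorted(t for t in handle.tables_present() if t not in expected)
    report = StructuralReport(
        per_table=per_table, n_tables=n,
        n_available=n - n_empty - n_na, n_empty=n_empty, n_not_available=n_na,
        pct_empty=pct(n_empty, n), pct_not_available=pct(n_na, n),
        total_rows=total_rows, unexpected_tables=unexpected,
    )
    return annotate_interpretation(report, manifest)


def annotate_interpretation(report: StructuralReport, manifest: SchemaManifest) -> StructuralReport:
    """Attach machine-readable interpretation notes to structural findings.

    * empty + derived table        -> ``derived-table-not-populated``
      (the ETL derivation scripts were most likely never executed; the source
      data for the table may still be complete)
    * not_available + free-text    -> ``free-text-capture-gap``
      (clinical narratives were not captured / the table was never implemented)
    * anything else                -> ``none``
    """
    for spec in manifest:
        tr = report.per_table.get(spec.name)
        if tr is None:
            continue
        if tr.status is TableStatus.empty and spec.derived:
            tr.note = "derived-table-not-populated"
        elif tr.status is TableStatus.not_available and spec.holds_free_text:
            tr.note = "free-text-capture-gap"
        else:
            tr.note = "none"
    return report


def volume_profile(handle: DatasetHandle, manifest: SchemaManifest) -> list[tuple[str, int, float]]:
    """Available tables ordered by descending storage bytes with volume fractions.

    Empty and absent tables are excluded; fractions sum to 1 (up to float
    round-off). Ties are broken by table name so output is deterministic.
    """
    rows: list[tuple[str, int]] = []
    for spec in manifest:
        if classify_table(handle, spec) is TableStatus.available:
            rows.append((spec.name, handle.table_bytes(spec.name)))
    total = sum(b for _, b in rows)
    rows.sort(key=lambda x: (-x[1], x[0]))
    if total == 0:
        return [(name, b, 0.0) for name, b in rows]
    return [(name, b, b / total) for name, b in rows]
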