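"""Completeness report assembly and rendering.

Combines the three assessment components — structural availability, rule
results, and descriptive profiles — into one report with an ordered findings
list that carries interpretation, not just detection: a missing free-text
table is a narrative capture gap; an empty derived table points at ETL; an
expected-null column at 100% missing is valid by default and never a deficit.

JSON output is lossless and schema-versioned; Markdown mirrors the assessment
order (structural, then rules, then profiles); the CSV bundle writes one file
per component.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from .profiling import CategoryDistribution
from .rules import Interpretation, RuleResult, SemanticClass
from .structural import StructuralReport, TableStatus

SCHEMA_VERSION = "1.0"
DEFAULT_SEVERITY_THRESHOLD_PCT = 5.0

_SEVERITY_ORDER = {"deficit": 0, "warning": 1, "info": 2}


@dataclass
class Finding:
    severity: str          # deficit | warning | info
    code: str              # machine-readable
    message: str           # human sentence

    def to_dict(self) -> dict:
        return {"severity": self.severity, "code": self.code, "message": self.message}


@dataclass
class CompletenessReport:
    structural: StructuralReport | None
    rule_results: list[RuleResult]
    profiles: list[CategoryDistribution]
    metadata: dict
    findings: list[Finding] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "metadata": dict(self.metadata),
            "skipped": list(self.skipped),
            "structural": self.structural.to_dict() if self.structural else None,
            "rule_results": [r.to_dict() for r in self.rule_results],
            "profiles": [p.to_dict() for p in self.profiles],
            "findings": [f.to_dict() for f in self.findings],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompletenessReport":
        major = str(d.get("schema_version", "")).split(".")[0]
        if major != SCHEMA_VERSION.split(".")[0]:
            raise ValueError(
                f"report schema version {d.get('schema_version')!r} is incompatible "
                f"with {SCHEMA_VERSION}")
        structural = (StructuralReport.from_dict(d["structural"])
                      if d.get("structural") else None)
        return cls(
            structural=structural,
            rule_results=[RuleResult.from_dict(r) for r in d.get("rule_results", [])],
            profiles=[CategoryDistribution.from_dict(p) for p in d.get("profiles", [])],
            metadata=dict(d.get("metadata", {})),
            findings=[Finding(**f) for f in d.get("findings", [])],
            skipped=list(d.get("skipped", [])),
            schema_version=d["schema_version"],
        )


def assemble_report(structural: StructuralReport | None = None,
                    rule_results: list[RuleResult] | None = None,
                    profiles: list[CategoryDistribution] | None = None,
                    metadata: dict | None = None,
                    severity_threshold_pct: float = DEFAULT_SEVERITY_THRESHOLD_PCT
                    ) -> CompletenessReport:
    """Assemble components into a report with deterministically ordered findings.

    Findings are sorted by severity (deficit, warning, info), then code. Any
    component passed as None is recorded under ``skipped``.
    """
    metadata = dict(metadata or {})
    metadata.setdefault("generated_at",
                        datetime.now(timezone.utc).isoformat(timespec="seconds"))
    skipped = []
    findings: list[Finding] = []
    if structural is None:
        skipped.append("structural")
    else:
        for tr in structural.per_table.values():
            if tr.note == "free-text-capture-gap":
                findings.append(Finding(
                    "warning", "free-text-capture-gap",
                    f"table '{tr.name}' holding clinical free text is not available; "
                    "narrative capture is limited"))
            elif tr.note == "derived-table-not-populated":
                findings.append(Finding(
                    "info", f"derived-table-not-populated:{tr.name}",
                    f"derived table '{tr.name}' is empty; ETL derivation scripts "
                    "were most likely not executed"))
    if rule_results is None:
        rule_results = []
        skipped.append("rules")
    else:
        for res in rule_results:
            if (res.semantic_class is SemanticClass.incompleteness
                    and res.interpretation is Interpretation.deficit
                    and res.proportion_pct is not None
                    and res.proportion_pct >= severity_threshold_pct):
                findings.append(Finding(
                    "deficit", f"rule-deficit:{res.rule_id}",
                    f"rule '{res.rule_id}' flagged {res.flagged}/{res.total} "
                    f"({res.proportion_pct}%) in {res.table}.{res.column}"))
            elif res.interpretation is Interpretation.valid_by_default:
                findings.append(Finding(
                    "info", f"valid-by-default:{res.rule_id}",
                    f"rule '{res.rule_id}' flagged {res.flagged}/{res.total} but the "
                    "field is null by default; this signals validity, not "
                    "incompleteness"))
    if profiles is None:
        profiles = []
        skipped.append("profiles")
    findings.sort(key=lambda f: (_SEVERITY_ORDER[f.severity], f.code))
    return CompletenessReport(structural=structural, rule_results=rule_results,
                              profiles=profiles, metadata=metadata,
                              findings=findings, skipped=skipped)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render(report: CompletenessReport, fmt: str, out_dir: str | Path) -> list[Path]:
    """Write the report in the requested format; returns the files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path = out / "report.json"
        path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
        return [path]
    if fmt == "markdown":
        path = out / "report.md"
        path.write_text(_to_markdown(report))
        return [path]
    if fmt == "csv_bundle":
        return _to_csv_bundle(report, out)
    raise ValueError(f"unknown report format {fmt!r}; expected json/markdown/csv_bundle")


def load_report(path: str | Path) -> CompletenessReport:
    return CompletenessReport.from_dict(json.loads(Path(path).read_text()))


def _to_markdown(report: CompletenessReport) -> str:
    lines = ["# Completeness assessment report", ""]
    for key, value in sorted(report.metadata.items()):
        lines.append(f"- {key}: {value}")
    lines.append("")
    if report.structural:
        s = report.structural
        lines += ["## Structural assessment", "",
                  f"{s.n_tables} expected tables: {s.n_available} available, "
                  f"{s.n_empty} empty ({s.pct_empty}%), "
                  f"{s.n_not_available} not available ({s.pct_not_available}%); "
                  f"{s.total_rows} records in total.", "",
                  "| table | status | rows | note |", "|---|---|---|---|"]
        for name, tr in s.per_table.items():
            lines.append(f"| {name} | {tr.status.value} | "
                         f"{'' if tr.rows is None else tr.rows} | {tr.note} |")
        lines.append("")
    if report.rule_results:
        lines += ["## Rule-based assessment", "",
                  "| rule | table | column | flagged, n/N (%) | interpretation |",
                  "|---|---|---|---|---|"]
        for r in report.rule_results:
            pct_s = "n/a" if r.proportion_pct is None else f"{r.proportion_pct}"
            lines.append(f"| {r.rule_id} | {r.table} | {r.column} | "
                         f"{r.flagged}/{r.total} ({pct_s}) | {r.interpretation.value} |")
        lines.append("")
    if report.profiles:
        lines += ["## Completeness and diversity profiles", ""]
        for p in report.profiles:
            lines += [f"### {p.dimension} (unit: {p.unit}, n={p.denominator})", "",
                      "| category | count | percent |", "|---|---|---|"]
            for label, n, percent in p.entries:
                lines.append(f"| {label} | {n} | {percent} |")
            lines.append("")
    if report.findings:
        lines += ["## Findings", ""]
        for f in report.findings:
            lines.append(f"- **{f.severity}** `{f.code}` — {f.message}")
        lines.append("")
    return "\n".join(lines)


def _to_csv_bundle(report: CompletenessReport, out: Path) -> list[Path]:
    written: list[Path] = []
    if report.structural:
        path = out / "structural.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["table", "status", "rows", "bytes", "note"])
            for name, tr in report.structural.per_table.items():
                w.writerow([name, tr.status.value, tr.rows, tr.bytes, tr.note])
        written.append(path)
    path = out / "rules.csv"
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rule_id", "table", "column", "flagged", "total", "pct",
                    "interpretation"])
        for r in report.rule_results:
            w.writerow([r.rule_id, r.table, r.column, r.flagged, r.total,
                        r.proportion_pct, r.interpretation.value])
    written.append(path)
    path = out / "profiles.csv"
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["dimension", "unit", "category", "count", "percent",
                    "denominator"])
        for p in report.profiles:
            for label, n, percent in p.entries:
                w.writerow([p.dimension, p.unit, label, n, percent, p.denominator])
    written.append(path)
    return written
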