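"""Schema manifest: the declarative description of which tables and columns a
CDM-style dataset is expected to contain.

Every assessment component is driven by a :class:`SchemaManifest` rather than a
hard-coded table list, so that site-specific schemas (extra tables, trimmed
vocabularies) are a manifest edit, not a code change. A default 39-table OMOP
CDM v5.3-style manifest ships with the package.
"""

from __future__ import annotations

import enum
from importlib import resources
from pathlib import Path
from typing import Iterator

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class ColumnRole(str, enum.Enum):
    """Semantic role of a column, used by rules/profiling to interpret values."""

    row_id = "row_id"
    person_id = "person_id"
    concept_id = "concept_id"
    source_value = "source_value"
    date = "date"
    datetime = "datetime"
    numeric_value = "numeric_value"
    text_value = "text_value"
    code = "code"
    other = "other"


class ColumnSpec(BaseModel):
    name: str = Field(min_length=1)
    role: ColumnRole = ColumnRole.other
    nullable: bool = True

    @field_validator("name")
    @classmethod
    def _lower(cls, v: str) -> str:
        # headers are matched case-insensitively throughout
        return v.strip().lower()


class TableSpec(BaseModel):
    name: str = Field(min_length=1)
    columns: list[ColumnSpec] = Field(min_length=1)
    derived: bool = False          # populated by ETL derivation scripts (era tables)
    holds_free_text: bool = False  # clinical narrative tables (note, note_nlp)

    @field_validator("name")
    @classmethod
    def _lower(cls, v: str) -> str:
        return v.strip().lower()

    @model_validator(mode="after")
    def _unique_columns(self) -> "TableSpec":
        names = [c.name for c in self.columns]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate column name(s) in table {self.name!r}: {dupes}")
        return self

    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def has_column(self, name: str) -> bool:
        return name.lower() in set(self.column_names())


class SchemaManifest(BaseModel):
    tables: list[TableSpec] = Field(min_length=1)
    version_label: str = "unversioned"

    @model_validator(mode="after")
    def _unique_tables(self) -> "SchemaManifest":
        names = [t.name for t in self.tables]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate table name(s) in manifest: {dupes}")
        return self

    def __len__(self) -> int:
        return len(self.tables)

    def __iter__(self) -> Iterator[TableSpec]:  # type: ignore[override]
        return iter(self.tables)

    def table_names(self) -> list[str]:
        return [t.name for t in self.tables]

    def get(self, name: str) -> TableSpec:
        name = name.lower()
        for t in self.tables:
            if t.name == name:
                return t
        raise KeyError(f"table {name!r} not in manifest")

    def __contains__(self, name: object) -> bool:
        return isinstance(name, str) and name.lower() in set(self.table_names())


class ManifestError(ValueError):
    """Malformed or invalid schema manifest."""


def load_manifest(path: str | Path) -> SchemaManifest:
    """Load and validate a YAML schema manifest.

    Raises :class:`ManifestError` on unparseable files, duplicate table names,
    or unknown column roles.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ManifestError(f"malformed manifest {path}: {exc}") from exc
    if not isinstance(raw, dict) or "tables" not in raw:
        raise ManifestError(f"manifest {path} must be a mapping with a 'tables' key")
    try:
        return SchemaManifest.model_validate(raw)
    except Exception as exc:
        raise ManifestError(f"invalid manifest {path}: {exc}") from exc


def default_manifest() -> SchemaManifest:
    """The bundled 39-table OMOP CDM v5.3-style manifest."""
    ref = resources.files("cdmaudit.data").joinpath("manifest_cdm_v5_3.yaml")
    raw = yaml.safe_load(ref.read_text())
    return SchemaManifest.model_validate(raw)


def default_manifest_path() -> Path:
    return Path(str(resources.files("cdmaudit.data").joinpath("manifest_cdm_v5_3.yaml")))
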