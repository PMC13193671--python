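"""Dataset access layer: one contract, two storage dialects.

A dataset is either a directory of RFC-4180 delimited files (``<table>.csv``
with a header row) or a single-file SQLite database with one relation per
table. Both dialects are read through the same four operations —
``table_exists``, ``read_table``, ``row_count``, ``table_bytes`` — and both
normalise missingness to a single internal sentinel (pandas ``NA``): a
database NULL and an empty delimited field are the same missing value.

All values are surfaced as strings; numeric and date interpretation is the
caller's job (the rule engine parses what it needs). This keeps the two
dialects byte-for-byte equivalent for every downstream assessment.
"""

from __future__ import annotations

import csv
import sqlite3
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class DatasetError(Exception):
    """Base class for dataset access problems."""


class NotAvailableError(DatasetError):
    """The requested table is not present in the dataset."""


class SchemaColumnError(DatasetError):
    """A required column is absent from a present table."""


#: literal strings (beyond the empty field) also read as missing; configurable
DEFAULT_MISSING_SENTINELS: frozenset[str] = frozenset()


def _normalise_missing(df: pd.DataFrame, sentinels: Iterable[str]) -> pd.DataFrame:
    df = df.astype("string")
    mask = df.isna() | df.eq("")
    sent = {s.upper() for s in sentinels}
    if sent:
        for col in df.columns:
            mask[col] |= df[col].str.upper().isin(sent)
    return df.mask(mask, pd.NA)


class DatasetHandle:
    """Uniform reader over a delimited directory or a SQLite database.

    Parameters
    ----------
    locator:
        Directory path (delimited dialect) or database file path (SQL dialect).
    dialect:
        ``"delimited_directory"`` or ``"sql_database"``.
    missing_sentinels:
        Literal strings (case-insensitive) normalised to missing on read, in
        addition to the empty field / NULL. Default: none.
    """

    DIALECTS = ("delimited_directory", "sql_database")

    def __init__(self, locator: str | Path, dialect: str,
                 missing_sentinels: Iterable[str] = DEFAULT_MISSING_SENTINELS):
        if dialect not in self.DIALECTS:
            raise ValueError(f"unknown dialect {dialect!r}; expected one of {self.DIALECTS}")
        self.locator = Path(locator)
        self.dialect = dialect
        self.missing_sentinels = frozenset(missing_sentinels)
        if not self.locator.exists():
            raise IOError(f"dataset locator does not exist: {self.locator}")
        if dialect == "delimited_directory" and not self.locator.is_dir():
            raise IOError(f"delimited_directory locator is not a directory: {self.locator}")
        if dialect == "sql_database" and not self.locator.is_file():
            raise IOError(f"sql_database locator is not a file: {self.locator}")

    # -- internals ---------------------------------------------------------
    def _csv_path(self, table: str) -> Path:
        return self.locator / f"{table.lower()}.csv"

    def _connect(self) -> sqlite3.Connection:
        return sqlite3.connect(self.locator)

    def _sql_tables(self) -> set[str]:
        with self._connect() as con:
            rows = con.execute(
                "SELECT name FROM sqlite_master WHERE type IN ('table','view')"
            ).fetchall()
        return {r[0].lower() for r in rows}

    # -- contract ----------------------------------------------------------
    def table_exists(self, table: str) -> bool:
        """True iff the table can be queried. Absence is a value, not an error."""
        if self.dialect == "delimited_directory":
            return self._csv_path(table).is_file()
        return table.lower() in self._sql_tables()

    def read_table(self, table: str, columns: Sequence[str] | None = None,
                   required: bool = False) -> pd.DataFrame:
        """Read a table as a string DataFrame with missingness normalised to NA.

        Column names are lower-cased. If ``columns`` is given, absent ones are
        surfaced as all-missing with a warning — unless ``required=True``, in
        which case :class:`SchemaColumnError` is raised.
        """
        if not self.table_exists(table):
            raise NotAvailableError(f"table {table!r} not available in {self.locator}")
        if self.dialect == "delimited_directory":
            try:
                df = pd.read_csv(self._csv_path(table), dtype=str,
                                 keep_default_na=False, na_values=[""])
            except pd.errors.EmptyDataError:
                df = pd.DataFrame()
        else:
            with self._connect() as con:
                df = pd.read_sql_query(f'SELECT * FROM "{table.lower()}"', con)
        df.columns = [str(c).lower() for c in df.columns]
        df = _normalise_missing(df, self.missing_sentinels)
        if columns is not None:
            columns = [c.lower() for c in columns]
            for col in columns:
                if col not in df.columns:
                    if required:
                        raise SchemaColumnError(
                            f"required column {col!r} absent from table {table!r}")
                    warnings.warn(
                        f"column {col!r} absent from table {table!r}; "
                        "surfaced as all-missing", stacklevel=2)
                    df[col] = pd.array([pd.NA] * len(df), dtype="string")
            df = df[list(columns)]
        return df

    def row_count(self, table: str) -> int:
        """Exact record count (header excluded for delimited files)."""
        if not self.table_exists(table):
            raise NotAvailableError(f"table {table!r} not available in {self.locator}")
        if self.dialect == "delimited_directory":
            path = self._csv_path(table)
            # RFC-4180-aware: quoted fields may span lines, so count records,
            # not lines
            with open(path, newline="") as fh:
                reader = csv.reader(fh)
                n = sum(1 for _ in reader)
            return max(n - 1, 0)
        with self._connect() as con:
            (n,) = con.execute(f'SELECT COUNT(*) FROM "{table.lower()}"').fetchone()
        return int(n)

    def table_bytes(self, table: str) -> int:
        """Storage size. Exact file size for the delimited dialect; for the SQL
        dialect an engine-derived approximation (serialised cell lengths)."""
        if not self.table_exists(table):
            raise NotAvailableError(f"table {table!r} not available in {self.locator}")
        if self.dialect == "delimited_directory":
            return self._csv_path(table).stat().st_size
        with self._connect() as con:
            cols = [r[1] for r in con.execute(f'PRAGMA table_info("{table.lower()}")')]
            expr = " + ".join(f'COALESCE(LENGTH("{c}"), 0)' for c in cols) or "0"
            (n,) = con.execute(f'SELECT COALESCE(SUM({expr}), 0) FROM "{table.lower()}"').fetchone()
        return int(n)

    def tables_present(self) -> list[str]:
        """All queryable table names, sorted."""
        if self.dialect == "delimited_directory":
            return sorted(p.stem.lower() for p in self.locator.glob("*.csv"))
        return sorted(self._sql_tables())


def open_dataset(locator: str | Path, dialect: str | None = None,
                 missing_sentinels: Iterable[str] = DEFAULT_MISSING_SENTINELS) -> DatasetHandle:
    """Open a dataset, auto-detecting the dialect when not given.

    A directory opens as ``delimited_directory``; a file as ``sql_database``.
    """
    locator = Path(locator)
    if dialect is None:
        if locator.is_dir():
            dialect = "delimited_directory"
        elif locator.is_file():
            dialect = "sql_database"
        else:
            raise IOError(f"dataset locator does not exist: {locator}")
    return DatasetHandle(locator, dialect, missing_sentinels)


# -- writers (used by the synthetic generator and the dialect converter) ----

def write_table_csv(directory: str | Path, table: str, df: pd.DataFrame) -> Path:
    """Write a table as RFC-4180 CSV; missing values become empty fields."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{table.lower()}.csv"
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def dataset_to_sqlite(src_dir: str | Path, db_path: str | Path) -> Path:
    """Convert a delimited-directory dataset to a single-file SQLite database.

    All columns are stored as TEXT and missing values as NULL, preserving the
    dialect-equivalence contract exactly.
    """
    src = open_dataset(src_dir, "delimited_directory")
    db_path = Path(db_path)
    if db_path.exists():
        db_path.unlink()
    con = sqlite3.connect(db_path)
    try:
        for table in src.tables_present():
            df = src.read_table(table)
            cols = ", ".join(f'"{c}" TEXT' for c in df.columns)
            con.execute(f'CREATE TABLE "{table}" ({cols})')
            placeholders = ", ".join("?" for _ in df.columns)
            rows = [
                tuple(None if pd.isna(v) else str(v) for v in rec)
                for rec in df.itertuples(index=False, name=None)
            ]
            con.executemany(f'INSERT INTO "{table}" VALUES ({placeholders})', rows)
        con.commit()
    finally:
        con.close()
    return db_path
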