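import shutil
from pathlib import Path

import pandas as pd
import pytest

import cdmaudit as ca


@pytest.fixture(scope="session")
def manifest():
    return ca.default_manifest()


@pytest.fixture(scope="session")
def dictionary():
    return ca.default_dictionary()


@pytest.fixture(scope="session")
def rulebook():
    return ca.default_rulebook()


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """One small clean dataset shared read-only across the session."""
    out = tmp_path_factory.mktemp("clean") / "data"
    cfg = ca.GeneratorConfig(n_persons=40, date_start="2019-01",
                             date_end="2020-12", seed=11)
    ca.generate_clean(cfg, out)
    return out


@pytest.fixture()
def clean_copy(clean_dataset, tmp_path):
    """A mutable per-test copy of the clean dataset."""
    dst = tmp_path / "data"
    shutil.copytree(clean_dataset, dst)
    return dst


def make_dataset(directory: Path, tables: dict[str, pd.DataFrame]) -> Path:
    """Write an ad-hoc delimited dataset from in-memory tables."""
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        ca.write_table_csv(directory, name, df)
    return directory


def small_manifest(*tables: tuple[str, list[str]]) -> ca.SchemaManifest:
    """Manifest for ad-hoc test datasets (all columns role 'other')."""
    return ca.SchemaManifest(
        version_label="test",
        tables=[
            ca.TableSpec(name=name,
                         columns=[ca.ColumnSpec(name=c) for c in cols])
            for name, cols in tables
        ],
    )
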