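import numpy as np
import pandas as pd
import pytest

from nnpi.core_data import Dataset
from nnpi.synthetic import SimConfig, generate_dataset


def make_traits(rows):
    """rows: (taxon_id, native_status, growth_habit, wis-or-None)."""
    df = pd.DataFrame(rows, columns=["taxon_id", "native_status", "growth_habit", "wis"])
    from nnpi.core_data import wis_numeric

    df["wis_value"] = wis_numeric(df["wis"])
    return df


def make_cover(rows):
    """rows: (site_id, plot_id, taxon_id, cover)."""
    df = pd.DataFrame(rows, columns=["site_id", "plot_id", "taxon_id", "cover"])
    df["visit_no"] = 1
    return df


def make_sites(site_ids, **overrides):
    n = len(site_ids)
    base = dict(
        x=np.linspace(0, 1, n), y=np.linspace(0, 1, n), weight=[1.0] * n,
        ecoregion=["CPL"] * n, wetland_type=["PRLH"] * n,
        is_probability=[True] * n, visit_no=[1] * n, bareground=[0.0] * n,
    )
    base.update(overrides)
    return pd.DataFrame({"site_id": site_ids, **base})


@pytest.fixture
def toy_dataset():
    """Two sites, three taxa (one nonnative), hand-checkable numbers."""
    traits = make_traits(
        [
            ("N1", "NATIVE", "FORB", "OBL"),
            ("N2", "NATIVE", "TREE", "UPL"),
            ("E1", "INTRODUCED", "GRAMINOID", "FAC"),
        ]
    )
    cover = make_cover(
        [
            ("A", 1, "N1", 10.0), ("A", 2, "N1", 10.0), ("A", 3, "N1", 10.0),
            ("A", 4, "N1", 10.0), ("A", 5, "N1", 10.0),
            ("A", 1, "E1", 50.0),
            ("B", 1, "N2", 30.0), ("B", 2, "N2", 30.0),
        ]
    )
    sites = make_sites(["A", "B"], weight=[2.0, 3.0])
    return Dataset(cover=cover, traits=traits, sites=sites, n_plots=5)


@pytest.fixture(scope="session")
def synth_dataset():
    """A moderate synthetic dataset shared by read-only tests."""
    return generate_dataset(SimConfig(n_sites=80, seed=42))


@pytest.fixture
def tmp_dataset_dir(tmp_path, synth_dataset):
    from nnpi.core_data import write_dataset

    write_dataset(synth_dataset, tmp_path / "data")
    return tmp_path / "data"
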