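import numpy as np
import pandas as pd
import pytest

from zoopkit import synthetic
from zoopkit.tables import make_asv_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_asv_table():
    """Two stations x two fractions, four ASVs, hand-checkable numbers."""
    counts = {
        ("S1", "0.5-1"): {"a1": 100, "a2": 900},
        ("S1", "1-2"): {"a1": 2000, "a2": 2000},
        ("S2", "0.5-1"): {"a1": 10, "a2": 30, "a3": 1},
        ("S2", "1-2"): {"a4": 50},
    }
    lineages = {
        "a1": "p__Arthropoda;c__Copepoda;o__Calanoida;f__Calanidae;g__Calanus;s__Calanus glacialis",
        "a2": "p__Arthropoda;c__Copepoda;o__Calanoida;f__Calanidae;g__Calanus;s__Calanus hyperboreus",
        "a3": "p__Bacillariophyta;c__;o__;f__;g__;s__",
        "a4": "p__Chaetognatha;c__Sagittoidea;o__Aphragmophora;f__;g__;s__",
    }
    return make_asv_table("COI", counts, lineages)


@pytest.fixture(scope="session")
def small_scenario():
    return synthetic.default_scenario(seed=7, n_stations=5)


@pytest.fixture(scope="session")
def small_pool():
    return synthetic.make_taxon_pool(8, seed=7)


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory):
    """Default 12-station, 20-taxon synthetic dataset (seed 1)."""
    path = tmp_path_factory.mktemp("dataset")
    scenario = synthetic.default_scenario(seed=1, n_stations=12)
    synthetic.generate_dataset(scenario, path, n_taxa=20)
    return path


@pytest.fixture(scope="session")
def dataset_dir_equal(tmp_path_factory):
    """Equal-amplification-efficiency variant (seed 2) for recovery tests."""
    path = tmp_path_factory.mktemp("dataset_eq")
    scenario = synthetic.default_scenario(seed=2, n_stations=12)
    synthetic.generate_dataset(scenario, path, n_taxa=20, equal_efficiency=True)
    return path


@pytest.fixture
def station_meta():
    return pd.DataFrame({"filtered_volume": {"S1": 100.0, "S2": 100.0}})
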