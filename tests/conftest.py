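import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sednitrate.simulate import SimulationParams

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def default_params():
    return SimulationParams(seed=1)


@pytest.fixture
def small_params():
    """Reduced study design for fast CLI/pipeline round-trips."""
    return SimulationParams(months=4, replicates=2, slices=5, seed=7)


@pytest.fixture
def mat_fixture():
    """Diatom-mat summary (replicate means) shipped with the package."""
    from importlib.resources import files

    path = files("sednitrate.data") / "mat_table2.csv"
    df = pd.read_csv(path, comment="#")
    return df[df["statistic"] == "mean"].drop(columns="statistic")
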