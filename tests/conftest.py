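import numpy as np
import pandas as pd
import pytest

from clonemem import CountMatrix, SimConfig, simulate_counts
from clonemem.diffexpr import run_contrasts

SMALL_CLASSES = {
    "tmg3_up": 60,
    "tmg3_down": 60,
    "tmg2_only_up": 30,
    "tmg2_only_down": 30,
    "transient": 40,
    "fluctuating": 40,
}


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A scaled-down default scenario used by the slower integration tests."""
    return SimConfig(n_genes=800, class_counts=SMALL_CLASSES, seed=11)


@pytest.fixture(scope="session")
def sim_data(small_cfg):
    return simulate_counts(small_cfg)


@pytest.fixture(scope="session")
def de_results(sim_data):
    counts, samples, _ = sim_data
    return run_contrasts(CountMatrix(counts, samples))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


def random_direction_table(rng, n_genes: int) -> pd.DataFrame:
    dirs = rng.choice(["up", "down", "ns"], size=(n_genes, 4), p=[0.25, 0.25, 0.5])
    return pd.DataFrame(
        dirs,
        columns=["d_P1", "d_P2", "d_P3", "d_P4"],
        index=[f"g{i}" for i in range(n_genes)],
    )
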