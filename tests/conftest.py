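import numpy as np
import pytest

from setkit import SimulationConfig, simulate_experiment


def small_config(**overrides) -> SimulationConfig:
    """A fast, reduced-size experiment used across the unit tests."""
    params = dict(
        seed=11,
        n_pairs=60,
        n_genes=150,
        n_marker_genes_per_cluster=20,
        genome=(("chr1", 2_000_000), ("chr2", 1_000_000)),
        frag_depth_mean=1500,
        expr_mean=3.0,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_experiment(small_config())


@pytest.fixture(scope="session")
def mid_dataset():
    """Larger simulation for clustering/concordance checks."""
    return simulate_experiment(
        small_config(seed=5, n_pairs=150, n_genes=300, n_marker_genes_per_cluster=30,
                     genome=(("chr1", 3_000_000), ("chr2", 3_000_000)),
                     frag_depth_mean=3000)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
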