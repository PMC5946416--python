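import numpy as np
import pytest

from ginifano import CountMatrix, Partition, SimulationConfig, simulate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_counts():
    """2 genes x 3 cells with known entries."""
    return CountMatrix(
        np.array([[1, 0, 2], [0, 0, 5]]),
        ("gA", "gB"),
        ("c1", "c2", "c3"),
    )


def small_sim(seed=0, cluster_sizes=(120, 60, 5, 4, 3), n_genes=5000,
              n_low_sig=30, n_high_sig=30, full_output=False):
    """Scaled-down simulation used by unit tests (proportions near the
    defaults, sizes small enough for fast suites)."""
    cfg = SimulationConfig(
        cluster_sizes=cluster_sizes,
        n_genes=n_genes,
        n_low_sig=n_low_sig,
        n_high_sig=n_high_sig,
        seed=seed,
    )
    return simulate_counts(cfg, full_output=full_output), cfg


@pytest.fixture(scope="session")
def small_sim_default():
    (cm, truth), cfg = small_sim(seed=11)
    return cm, truth, cfg


def random_partition(rng, n, k, cell_ids=()):
    labels = rng.integers(1, k + 1, size=n)
    labels[:k] = np.arange(1, k + 1)  # ensure every cluster non-empty
    return Partition(labels, tuple(cell_ids))
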