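import numpy as np
import pytest

from scwound.qc import normalize_log
from scwound.simulate import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """One-population dataset with planted pseudotime-dependent genes."""
    cfg = SimConfig(n_cells=600, n_genes=150, frac_dep_genes=0.2,
                    dep_amplitude=2.0, seed=42)
    m, meta, truth = simulate_counts(cfg)
    return m, meta, truth


@pytest.fixture(scope="session")
def small_expr(small_sim):
    m, meta, truth = small_sim
    return normalize_log(m), meta, truth


@pytest.fixture(scope="session")
def four_type_sim():
    """Four well-separated populations for clustering tests."""
    cfg = SimConfig(n_cells=800, n_genes=250, n_types=4, seed=7)
    m, meta, truth = simulate_counts(cfg)
    return m, meta, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
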