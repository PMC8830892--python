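import numpy as np
import pytest

from ebvar import pseudobulk, synthetic


@pytest.fixture(scope="session")
def small_cfg():
    return synthetic.default_config(n_genes=80, cells_per_group=30, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(counts, cell_table, truth) for a small default-scenario run."""
    return synthetic.simulate_counts(small_cfg)


@pytest.fixture(scope="session")
def small_weighted(small_sim):
    """Pseudobulk -> TMM -> voom chain on the small simulation."""
    counts, cells, _ = small_sim
    pb = pseudobulk.make_pseudobulk(counts, cells)
    pseudobulk.tmm_factors(pb)
    return pb, pseudobulk.voom_weights(pb)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
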