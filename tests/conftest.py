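import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tissueatlas import SimConfig, simulate_atlas, simulate_ppi

settings.register_profile("deterministic", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_sim():
    """An 800-gene noisy atlas with planted modules and PPI cliques."""
    cfg = SimConfig(n_genes=800, seed=11, n_modules=4,
                    module_size_range=(12, 25), ppi_background_edges=400,
                    ppi_clique_fraction=1.0)
    atlas, counts, truth = simulate_atlas(cfg)
    ppi = simulate_ppi(truth, cfg)
    return cfg, atlas, counts, truth, ppi


@pytest.fixture(scope="session")
def default_sim():
    """The full default study design (5,000 genes, 10 tissues x 2 replicates)."""
    cfg = SimConfig(seed=7)
    atlas, counts, truth = simulate_atlas(cfg)
    return cfg, atlas, counts, truth


@pytest.fixture(scope="session")
def noiseless_sim():
    cfg = SimConfig(seed=7, noise_log2_sd=0.0)
    atlas, counts, truth = simulate_atlas(cfg)
    return cfg, atlas, counts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_profile(values, tissues=None):
    """genes x tissues DataFrame from a list of per-gene tissue-mean tuples."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if tissues is None:
        tissues = [f"t{i:02d}" for i in range(values.shape[1])]
    return pd.DataFrame(values, columns=tissues,
                        index=[f"g{i}" for i in range(values.shape[0])])
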