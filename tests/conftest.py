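import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import proteoscreen as ps

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_screen():
    """A small screen with a handful of strong true effects."""
    params = ps.ScreenSimParams(
        n_genes=60, guides_per_gene=5, n_nt_guides=120, frac_nonnull=0.1,
        effect_mean=3.0, cells_per_guide=120, reads_per_bin=200_000, seed=11)
    counts, truth = ps.simulate_screen(params)
    return params, counts, truth


@pytest.fixture(scope="session")
def small_screen_results(small_screen):
    _, counts, _ = small_screen
    return ps.SortedBinScreen(counts).fit(n_perm=2000, seed=7)


@pytest.fixture(scope="session")
def lipidome():
    params = ps.LipidSimParams(seed=5)
    table, phenotype, truth = ps.simulate_lipidome(params)
    return params, table, phenotype, truth


@pytest.fixture()
def gene_stats_table():
    return pd.DataFrame({
        "gene": ["a", "b", "c", "d"],
        "lfc": [1.0, -0.5, -2.0, 0.0],
        "p": [0.001, 0.2, 0.0005, 0.9],
        "fdr": [0.05, 0.2, 0.01, 1.0],
        "n_guides": [5, 5, 5, 5],
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
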