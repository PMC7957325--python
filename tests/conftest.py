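import numpy as np
import pandas as pd
import pytest

from germfate.expression import CountMatrix
from germfate.synthdata import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study design for fast end-to-end style tests."""
    return SimConfig(
        n_genes=400,
        n_elements=60,
        n_chroms=6,
        chrom_length=400_000,
        library_size=1_000_000,
        atac_background_fragments=20_000,
        n_meth_regions=60,
        cells_per_condition=12,
        seed=11,
    )


def make_count_matrix(counts: dict, lengths=None, index=None) -> CountMatrix:
    df = pd.DataFrame(counts, index=index)
    if lengths is None:
        lengths = pd.Series(1000, index=df.index)
    else:
        lengths = pd.Series(lengths, index=df.index)
    meta = pd.DataFrame(
        {"cell_type": "x", "stage": "s", "replicate": range(len(df.columns))},
        index=df.columns)
    return CountMatrix(df, lengths, meta)


@pytest.fixture
def nb_counts():
    """Negative-binomial count tables with known planted fold changes."""
    def build(n_features, n_per_group, dispersion, fold=1.0, n_planted=0,
              seed=0, base_mean=200.0):
        rng = np.random.default_rng(seed)
        mu = rng.lognormal(np.log(base_mean), 1.0, n_features)
        mu_b = mu.copy()
        mu_b[:n_planted] *= fold

        def draw(mean):
            if dispersion == 0:
                return rng.poisson(mean)
            return rng.poisson(rng.gamma(1 / dispersion, mean * dispersion))

        cols = {f"a{i}": draw(mu) for i in range(n_per_group)}
        cols.update({f"b{i}": draw(mu_b) for i in range(n_per_group)})
        cm = make_count_matrix(cols, index=[f"f{i}" for i in range(n_features)])
        return cm, [f"a{i}" for i in range(n_per_group)], \
            [f"b{i}" for i in range(n_per_group)]
    return build
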