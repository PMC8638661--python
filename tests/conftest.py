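import numpy as np
import pandas as pd
import pytest

import crossgp as cg


@pytest.fixture(scope="session")
def small_config():
    return cg.SimConfig(
        n_chromosomes=5,
        n_markers=20,
        n_f2=120,
        n_ril=140,
        n_qtl=20,
        h2=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return cg.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def f2_matrix(small_dataset):
    """Complete encoded F2 genotype matrix and its map."""
    gm = cg.impute(small_dataset.genotypes_f2)
    return gm, small_dataset.marker_map


@pytest.fixture(scope="session")
def two_locus_map():
    """Two markers 10 cM apart on one chromosome."""
    return pd.DataFrame(
        {"marker": ["m1", "m2"], "chrom": ["C01", "C01"], "pos_cm": [0.0, 10.0]}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_instance(seed, n=60, m=150):
    """A random complete genotype matrix and phenotype for model tests."""
    gen = np.random.default_rng(seed)
    gm = pd.DataFrame(
        gen.choice([-1.0, 0.0, 1.0], size=(n, m), p=[0.25, 0.5, 0.25]),
        index=[f"L{i:03d}" for i in range(n)],
        columns=[f"M{j:03d}" for j in range(m)],
    )
    effects = gen.normal(0, 0.3, size=m)
    signal = gm.to_numpy() @ effects
    y = pd.Series(
        signal + gen.normal(0, np.std(signal) + 1e-9, size=n),
        index=gm.index,
    )
    return gm, y
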