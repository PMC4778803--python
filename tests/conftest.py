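import numpy as np
import pandas as pd
import pytest

from gxelmm import GenotypeMatrix, SimulationConfig, simulate_dataset


def make_genotypes(n, m, rng, ids=None, miss_frac=0.0):
    """Random unstructured genotype matrix for plumbing tests."""
    p = rng.uniform(0.1, 0.9, size=m)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    if miss_frac > 0:
        mask = rng.random((n, m)) < miss_frac
        dos[mask] = np.nan
    samples = ids if ids is not None else [f"s{i:04d}" for i in range(n)]
    variants = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, m + 1), "a1": "A", "a2": "B"},
        index=pd.Index([f"v{j:04d}" for j in range(m)], name="id"),
    )
    return GenotypeMatrix(samples, variants, dos)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim():
    """One structured study draw shared by read-only tests."""
    cfg = SimulationConfig(n_per_pop=80, m_variants=600, seed=42)
    return simulate_dataset(cfg)
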