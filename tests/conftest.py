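import numpy as np
import pytest

from strandbias import SyntheticGenomeSpec, generate


@pytest.fixture(scope="session")
def biased_fixture():
    """Strongly biased replichore genome (delta=0.1) with genes; shared
    across recovery and index tests."""
    spec = SyntheticGenomeSpec(L=500_000, delta=0.1, gene_count=300,
                               gene_len_mean=900, orientation_bias=0.8,
                               seed=3)
    return generate(spec)


@pytest.fixture(scope="session")
def unbiased_fixture():
    """Null genome: no compositional or orientation bias, no genes."""
    spec = SyntheticGenomeSpec(L=200_000, delta=0.0, mode="unbiased",
                               gene_count=0, seed=7)
    return generate(spec)


@pytest.fixture(scope="session")
def small_annotated():
    """Small annotated genome for IO round-trips and gene-level checks."""
    spec = SyntheticGenomeSpec(L=30_000, delta=0.05, gene_count=20,
                               gene_len_mean=600, seed=4)
    return generate(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
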