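import numpy as np
import pytest

from rhoshrink.data import CountMatrix
from rhoshrink.synthdata import block_spec, make_taxonomy, simulate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def toy_counts():
    """Hand-sized 4 samples x 6 taxa count matrix."""
    counts = np.array([
        [0, 5, 12, 3, 0, 80],
        [2, 7, 9, 0, 1, 41],
        [1, 0, 30, 6, 2, 61],
        [4, 9, 2, 1, 0, 104],
    ])
    return CountMatrix(counts, [f"S{j}" for j in range(4)],
                       [f"T{i}" for i in range(6)])


@pytest.fixture(scope="session")
def block_sim():
    """Moderate synthetic dataset with 4 latent blocks (session-scoped)."""
    spec = block_spec(p=40, n=300, n_blocks=4, within=0.6, seed=11,
                      zero_inflation=0.05)
    return simulate_counts(spec)


@pytest.fixture(scope="session")
def block_tax(block_sim):
    return make_taxonomy(block_sim.spec)
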