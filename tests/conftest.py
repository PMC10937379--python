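import numpy as np
import pytest

from sigdecon.matrices import l1_normalize_columns
from sigdecon.simulate import (
    SimulationSpec,
    flat_signature,
    random_separated_signatures,
    simulate_lda,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_3ch():
    """3-channel cohort from interior planted signatures (each strictly inside
    the simplex, so plain NMF is maximally non-unique)."""
    W_true = np.array([[0.6, 0.2, 0.2], [0.2, 0.6, 0.2], [0.2, 0.2, 0.6]])
    spec = SimulationSpec(W_true, n_samples=200, alpha=0.1, mean_burden=5000, seed=2)
    X, H = simulate_lda(spec)
    return W_true, X, H


@pytest.fixture(scope="session")
def planted_96ch():
    """96-channel cohort from 3 well-separated planted signatures."""
    W_true = random_separated_signatures(96, 3, seed=42)
    spec = SimulationSpec(W_true, n_samples=200, alpha=0.1, mean_burden=5000, seed=7)
    X, H = simulate_lda(spec)
    return W_true, X, H


@pytest.fixture(scope="session")
def toy_catalog():
    """Small catalog mixing peaked and flat signatures (p=20, r=6)."""
    peaked = random_separated_signatures(20, 4, seed=3, sparsity=2.0)
    flat = flat_signature(20)[:, None]
    near_flat = l1_normalize_columns(
        (flat[:, 0] * (1 + 0.25 * np.cos(np.arange(20))))[:, None]
    )
    return np.column_stack([peaked, flat, near_flat])
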