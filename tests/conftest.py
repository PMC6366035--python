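import numpy as np
import pytest

from mirimpact.synthetic import make_dataset


@pytest.fixture(scope="session")
def recovery_dataset():
    """Planted-signal study: 3000 transcripts, 150 miRNAs, 30 active."""
    return make_dataset(3000, 150, n_active=30, r_squared=0.35, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """Small noisy study for fast split/ranking tests."""
    return make_dataset(800, 20, n_active=5, sparsity=0.1, r_squared=0.6, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
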