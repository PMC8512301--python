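import numpy as np
import pytest

from fuzzyoc.synce import generate_splits


@pytest.fixture(scope="session")
def tiny_splits():
    """Small SYN-CE dataset shared by pipeline/training tests."""
    return generate_splits(n_certain=60, n_fuzzy=30, subset_mode="fuzzy", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
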