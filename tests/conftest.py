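import numpy as np
import pytest

from necrosim import dsbms as D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small, fast simulator configuration for unit tests."""
    return D.DsbmsConfig(L=12, K=200_000)


@pytest.fixture
def tiny_lesion(rng):
    """A pre-grown miniature lesion for post-treatment unit tests."""
    config = D.desk_config(L=24, K=10_000)
    grid, _ = D.grow_to_diagnosis(config, 0.02, rng)
    return grid, config
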