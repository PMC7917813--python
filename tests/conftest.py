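import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_patch(rng):
    """One random 64x32 grayscale patch in [0, 1]."""
    return rng.random((32, 64))
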