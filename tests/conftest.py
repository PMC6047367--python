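import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240611)


@pytest.fixture
def random01(rng):
    """Factory for random 0/1 matrices."""

    def make(K, N):
        return rng.integers(0, 2, size=(K, N), dtype=np.uint8)

    return make
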