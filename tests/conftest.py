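import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def canonical_params():
    """Reference decay-law triple used across oracle checks."""
    return dict(A=100.0, B=10.0, C=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
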