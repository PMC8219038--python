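import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from leafgas import synthetic as syn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def noise_free_truth():
    """Default generating truth with noise switched off."""
    return syn.make_truth(noise_cv=0.0, seed=42)


@pytest.fixture
def default_truth():
    """Default generating truth at the standard 2% flux noise."""
    return syn.make_truth(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
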