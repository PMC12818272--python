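import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def four_row_set():
    """The worked 4-observation dataset: BS = 0.145, ȳ = 0.5."""
    from brierlab import PredictionSet

    return PredictionSet(p=[0.2, 0.8, 0.5, 0.5], y=[0, 1, 1, 0])


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
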