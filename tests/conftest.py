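import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_cohort():
    """A 22-patient synthetic cohort under the default study conditions."""
    from ffrsim import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture
def noiseless_cohort():
    """Exact forward-model cohort (no measurement noise)."""
    from ffrsim import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(seed=7, noise_sd=0.0))
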