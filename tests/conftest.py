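import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calibrated():
    """Calibrated gut-model parameters (deterministic, computed once)."""
    from gutenergy.gut_model import calibrated_params

    return calibrated_params()


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort at the default configuration, seed 0."""
    from gutenergy.cohort import GeneratorConfig, generate_cohort

    return generate_cohort(GeneratorConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
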