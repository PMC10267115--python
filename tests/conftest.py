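import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crossconn.simulate import SimulationConfig, generate_study

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """Desk-scale cross-over study with the default (non-null) drug effect."""
    cfg = SimulationConfig(n_subjects=10, n_regions=8, n_timepoints=120, seed=42)
    return generate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
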