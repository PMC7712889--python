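import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neurostates.synth import SimulationConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A fast cohort: 12 subjects, 3 states, 6 parcels, 120 volumes."""
    return SimulationConfig(n_subjects=12, n_timepoints=120, n_parcels=6,
                            n_states=3, n_report_components=3,
                            n_wellbeing_subjects=8, seed=7)
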