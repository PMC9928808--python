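import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kneekin import SyntheticCohortConfig, simulate_cohort

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Three identical participants generated exactly by the 2-DOF model."""
    cfg = SyntheticCohortConfig(
        n_participants=3,
        participant_effect_sd=0.0,
        noise_sd_rotation=0.0,
        noise_sd_translation=0.0,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def heterogeneous_cohort():
    """Three participants with coefficient heterogeneity and noise."""
    cfg = SyntheticCohortConfig(
        n_participants=3,
        participant_effect_sd=0.05,
        noise_sd_rotation=0.5,
        noise_sd_translation=0.5,
        samples_per_trial=101,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
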