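import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import reachdecode as rd

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def basis():
    return rd.BasisSet()


@pytest.fixture(scope="session")
def design():
    """Full-size session design: 6 runs x (40 reach + 5 rest), 12 s trials."""
    return rd.generate_design(seed=11)


@pytest.fixture(scope="session")
def noise_free_data(design):
    """Noise-free responses of 60 voxels (half tuned) with ground truth."""
    gt = rd.generate_ground_truth(60, noise_sd=0.0, seed=7)
    return rd.generate_trial_responses(design, gt), gt


@pytest.fixture(scope="session")
def noisy_data(design):
    """Responses at the default (calibrated) noise level."""
    gt = rd.generate_ground_truth(100, seed=13)
    return rd.generate_trial_responses(design, gt), gt
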