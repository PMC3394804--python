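import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import snarekin as sk


@pytest.fixture(scope="session")
def fundamental():
    return sk.fundamental_subsystem()


@pytest.fixture(scope="session")
def near_irreversible_rates():
    """Rate vector with dissociation 1e-4 of association (min-rule regime)."""
    return np.array([0.7, 0.7e-4, 0.4, 0.4e-4])


@pytest.fixture(scope="session")
def default_truth():
    return sk.ground_truth("default")


@pytest.fixture(scope="session")
def noiseless_trace(default_truth):
    return sk.generate_trace(default_truth, n_points=50, noise_sd_rel=0.0, seed=1)


@pytest.fixture(scope="session")
def recovery_protocol(default_truth):
    """Fit configuration of the synthetic recovery studies: literature-style
    initial guess at twice the truth, admissible box a factor 2.5 around it."""
    guess = 2.0 * default_truth.params.values
    return sk.RegularizationConfig(
        init_guess=guess,
        bounds=tuple((g / 2.5, g * 2.5) for g in guess),
        ftol=1e-12,
        phase2_iters=150,
    )
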