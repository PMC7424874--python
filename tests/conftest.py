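import numpy as np
import pytest

from cuedmotion import (
    baseline_correct,
    make_basis,
    make_ground_truth,
    make_localizer_design,
    simulate_epochs,
)


@pytest.fixture(scope="session")
def basis():
    return make_basis()


@pytest.fixture(scope="session")
def small_gt():
    """A 16-sensor participant with unit-variance correlated noise."""
    return make_ground_truth(n_sensors=16, noise_sd=1.0, seed=7)


@pytest.fixture(scope="session")
def quiet_gt():
    """A 16-sensor participant with (numerically) noise-free recordings."""
    return make_ground_truth(n_sensors=16, noise_sd=1e-12, seed=7)


@pytest.fixture(scope="session")
def localizer_design():
    return make_localizer_design(n_blocks=2, seed=11)


@pytest.fixture(scope="session")
def quiet_localizer(quiet_gt, localizer_design):
    ep = simulate_epochs(localizer_design, quiet_gt, (-200.0, 200.0))
    return baseline_correct(ep, (-200.0, 0.0))
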