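import numpy as np
import pytest

from motionprior import (
    BayesParams,
    TaskConfig,
    generate_schedule,
    simulate_session,
)
from motionprior.fitting import FitSettings


@pytest.fixture(scope="session")
def default_observer() -> BayesParams:
    """The package's default synthetic observer (moderate-noise regime)."""
    return BayesParams(theta_p=32.0, sigma_p=15.0, sigma_s=12.0,
                       alpha_p=0.1, sigma_m=8.0)


@pytest.fixture(scope="session")
def default_schedule():
    return generate_schedule(TaskConfig(), seed=0)


@pytest.fixture(scope="session")
def default_session(default_schedule, default_observer):
    return simulate_session(default_schedule, default_observer, seed=1)


@pytest.fixture(scope="session")
def small_task() -> TaskConfig:
    """A shortened design for cheap end-to-end tests."""
    return TaskConfig(n_zero=30, n_low_2_1=20, n_low_4_1=40, n_high=25)


@pytest.fixture(scope="session")
def fast_fit() -> FitSettings:
    """Reduced-start optimizer settings for unit-level fitting tests."""
    return FitSettings(polish_top=2, maxiter=80)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
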