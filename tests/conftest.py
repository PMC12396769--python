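import numpy as np
import pytest

from popbp import ModelParams, Schedule, build_coefficients
from popbp.simulate import BruteForceConfig


@pytest.fixture(scope="session")
def two_obs_model():
    """The workhorse configuration: lambda=1, p=0.6, times (0.4, 1)."""
    params = ModelParams(1.0, 0.6)
    schedule = Schedule((0.4, 1.0))
    return params, schedule


@pytest.fixture(scope="session")
def two_obs_coeffs(two_obs_model):
    params, schedule = two_obs_model
    return build_coefficients(params, schedule)


@pytest.fixture(scope="session")
def two_obs_bf_cfg(two_obs_model):
    params, schedule = two_obs_model
    return BruteForceConfig.for_model(params, schedule, tail_bound=1e-13)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
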