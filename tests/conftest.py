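import numpy as np
import pytest

from sirews import ModelParams

# Measles-like reference parameter set used throughout: birth rate 2e5/y,
# life expectancy 50 y, 22-day infectious period, R0 = 17, weak sparking.
REFERENCE = dict(b=2e5, mu=0.02, gamma=365.0 / 22.0, eta=2e-5, nu=0.0, R0=17.0)


@pytest.fixture
def ref_params() -> ModelParams:
    """Reference parameter set with sparking (open model)."""
    return ModelParams(**REFERENCE)


@pytest.fixture
def ref_closed() -> ModelParams:
    """Reference parameter set without sparking (closed model)."""
    return ModelParams(**{**REFERENCE, "eta": 0.0})


@pytest.fixture
def slow_params() -> ModelParams:
    """A slower, strongly-damped disease at small population size.

    Chosen so the infected count at equilibrium is large relative to its
    stationary fluctuations (linear-noise theory accurate) while event rates
    stay low enough for fast exact simulation.
    """
    return ModelParams(b=5e3, mu=0.05, gamma=2.0, eta=1e-4, nu=0.0, R0=5.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
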