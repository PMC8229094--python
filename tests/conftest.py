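import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from halbachsim import (
    Channel,
    Fluid,
    build_alternating,
    build_halbach,
)
from halbachsim.optimize import default_span

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def channel():
    return Channel()


@pytest.fixture(scope="session")
def fluid():
    return Fluid()


@pytest.fixture(scope="session")
def span(channel):
    return default_span(channel)


@pytest.fixture(scope="session")
def optimized_halbach(span):
    """1-mm N52 Halbach with 2.75/2 mm heights (the optimized build)."""
    return build_halbach(1e-3, 2.75e-3, 2e-3, 1.45, span)


@pytest.fixture(scope="session")
def stock_halbach(span):
    """1 x 1.5 mm N45 stock-magnet Halbach."""
    return build_halbach(1e-3, 1.5e-3, 1.5e-3, 1.35, span)


@pytest.fixture(scope="session")
def alternating_array(span):
    """Width-optimized alternating array (2.0 mm wide, 2.375 mm high)."""
    return build_alternating(2e-3, 2.375e-3, 1.45, span)
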