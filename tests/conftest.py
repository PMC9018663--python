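import pytest

from asapscreen import default_registry
from asapscreen.synthetic import SimulationParams, default_profiles, reference_library


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def profiles(registry):
    return default_profiles(registry)


@pytest.fixture(scope="session")
def library(registry):
    """Default synthetic reference library (17 compounds, 4 channels)."""
    return reference_library(registry)


@pytest.fixture(scope="session")
def sim_params():
    return SimulationParams()
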