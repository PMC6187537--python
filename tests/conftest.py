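import pytest

from spiralsort import build_default_device, primary_flow, stress_summary, water_at_20c


@pytest.fixture(scope="session")
def channel():
    return build_default_device()


@pytest.fixture(scope="session")
def fluid():
    return water_at_20c(1.0)


@pytest.fixture(scope="session")
def base_flow(channel, fluid):
    """Default-resolution primary duct flow, shared across tests."""
    return primary_flow(channel, fluid, resolution=64)


@pytest.fixture(scope="session")
def summary(channel, fluid):
    """Full stress chain at the printed device and flow condition."""
    return stress_summary(channel, fluid)
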