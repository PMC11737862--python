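import pytest

from wchomeo import WCParams, SimConfig, HomeostasisSpec


@pytest.fixture(scope="session")
def defaults() -> WCParams:
    """Canonical parameter table of the node."""
    return WCParams()


@pytest.fixture(scope="session")
def spec() -> HomeostasisSpec:
    return HomeostasisSpec()


@pytest.fixture(scope="session")
def short_sim() -> SimConfig:
    """A cheap run for tests that only need qualitative dynamics."""
    return SimConfig(dt=0.1, duration=1000.0)
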