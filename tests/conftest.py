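import numpy as np
import pytest

from gazekit.events import EventConfig
from gazekit.geometry import ScreenGeometry
from gazekit.synth import default_geometry


@pytest.fixture(scope="session")
def geometry() -> ScreenGeometry:
    return default_geometry()


@pytest.fixture(scope="session")
def event_config() -> EventConfig:
    return EventConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
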