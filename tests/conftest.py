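import numpy as np
import pytest

from coopgis.room import RoomGeometry, default_room


@pytest.fixture
def room():
    return default_room()


@pytest.fixture
def bare_room():
    return RoomGeometry(6.0, 4.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240806)
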