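import numpy as np
import pytest
from hypothesis import settings

from cabvort import boundary, geometry

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")

# short entry/exit extensions keep test builds small; the tube sections that
# measurements probe are unchanged
SHORT = dict(entry_length=2 * 6.5e-3, ica_exit_length=3 * 4.55e-3,
             eca_exit_length=3 * 4.55e-3)


@pytest.fixture(scope="session")
def fluid():
    return boundary.BLOOD_ANALOG


@pytest.fixture(scope="session")
def waveform():
    return boundary.make_waveform()


@pytest.fixture(scope="session")
def healthy_geom():
    return geometry.build_geometry(geometry.healthy_parameters(**SHORT),
                                   resolution=110)


@pytest.fixture(scope="session")
def predisposed_geom():
    return geometry.build_geometry(geometry.predisposed_parameters(**SHORT),
                                   resolution=110)


@pytest.fixture
def rng():
    return np.random.default_rng(20230903)
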