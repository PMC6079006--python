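import numpy as np
import pytest

from freqtag.simulate import make_sensor_array


@pytest.fixture(scope="session")
def sensor_array():
    return make_sensor_array(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
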