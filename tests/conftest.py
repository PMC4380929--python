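import numpy as np
import pytest

from hepg1s import default_network, default_parameters


@pytest.fixture(scope="session")
def network():
    return default_network()


@pytest.fixture(scope="session")
def truth():
    return default_parameters()


@pytest.fixture(scope="session")
def coarse_times():
    return np.linspace(0.0, 72.0, 25)
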