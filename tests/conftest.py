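import numpy as np
import pytest

from landgen import build_grid_habitat


@pytest.fixture(scope="session")
def grid10():
    """The default forecasting landscape: 10 x 10 demes of 50 diploids."""
    return build_grid_habitat(10, 10, 50, 0.01)


@pytest.fixture(scope="session")
def grid3():
    return build_grid_habitat(3, 3, 20, 0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
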