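import numpy as np
import pytest

from coldclock.profiles import default_clock_panel


@pytest.fixture(scope="session")
def shoot_panel():
    return default_clock_panel("shoot")


@pytest.fixture(scope="session")
def root_panel():
    return default_clock_panel("root")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
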