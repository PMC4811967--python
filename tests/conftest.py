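import numpy as np
import pytest

from hdmea import ArrayGeometry


@pytest.fixture
def small_geometry():
    """An 8x8 grid with one central stimulation site."""
    return ArrayGeometry(n_rows=8, n_cols=8, stim_sites=((4, 4),))


@pytest.fixture
def full_geometry():
    """The standard 64x64 (4096-electrode) array with two stimulation sites."""
    return ArrayGeometry(stim_sites=((16, 16), (48, 48)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
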