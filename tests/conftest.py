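import numpy as np
import pytest

from icsearch import ColorRange, ICSConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def uniform_gray():
    """A flat mid-gray image: no edges, every pixel identical."""
    return np.full((24, 32, 3), 120, dtype=np.uint8)


@pytest.fixture
def permissive_cfg():
    """Config whose color range admits the uniform_gray image everywhere."""
    return ICSConfig(cell_diameter=6.0, color_range=ColorRange((120, 120, 120), 200.0))
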