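import numpy as np
import pytest

from axoncontact import make_axon_trace, make_scene
from axoncontact.core import PixelImage


@pytest.fixture()
def straight_trace():
    return make_axon_trace(30, 500, 0, seed=7)


@pytest.fixture()
def small_scene(straight_trace):
    return make_scene(straight_trace, 200, 0.45, 30, 50, seed=3)


@pytest.fixture()
def uniform_image():
    return PixelImage(np.full((8, 8), 5.0), 20.0)
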