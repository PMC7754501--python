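import numpy as np
import pytest

from fibsemseg.preprocess import ImageVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def textured_volume(rng):
    """Small volume with spatial texture, safely inside [0.2, 0.8]."""
    data = 0.5 + 0.3 * np.sin(np.linspace(0, 20, 24))[:, None, None] * rng.uniform(
        0.2, 1.0, size=(24, 20, 12)
    )
    return ImageVolume(np.clip(data, 0.0, 1.0))
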