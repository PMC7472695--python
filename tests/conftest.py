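import numpy as np
import pytest
from PIL import Image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def save_png(tmp_path):
    """Save an RGB array as PNG under tmp_path and return the path."""

    def _save(arr, name="img.png"):
        path = tmp_path / name
        path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(np.asarray(arr, dtype=np.uint8)).save(path)
        return path

    return _save


def random_rgb(rng, h, w):
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
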