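import numpy as np
import pytest

from tubemap import CrownCircle, TubePhantomSpec, make_tube_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def annulus_slice(size=32, cx=16.0, cy=16.0, r=10.0, w=3.0, amplitude=100.0):
    """Noise-free binary annulus exactly filling the crown of (cx, cy, r, w)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    d = np.hypot(yy - cy, xx - cx)
    img = np.zeros((size, size))
    img[(d >= r - w / 2) & (d <= r + w / 2)] = amplitude
    return img


@pytest.fixture
def straight_phantom():
    """Noiseless straight constant-radius tube with its ground truth."""
    spec = TubePhantomSpec(
        n_slices=16,
        image_size=(48, 48),
        radius_profile=12.0,
        center_profile=(24.0, 24.0),
        n_cells=0,
        seed=7,
    )
    vol, truth = make_tube_phantom(spec)
    return spec, vol, truth


@pytest.fixture
def init_circle():
    return CrownCircle(z=0, cx=22.0, cy=26.0, r=13.0, crown_width=3.0)
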