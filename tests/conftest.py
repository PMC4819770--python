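import numpy as np
import pytest

from nanofish.core import Emitter, FrameGeometry, NoiseModel, OpticsModel
from nanofish.detect import extract_roi
from nanofish.synthetic import render_spot

# the reference acquisition geometry: 200-nm pixels, 1.45-NA objective,
# red/far-red emission channels
PIXEL_NM = 200.0
NA = 1.45
LAMBDA_A = 615.0
LAMBDA_B = 684.0


@pytest.fixture
def frame():
    return FrameGeometry(32, 32, PIXEL_NM)


@pytest.fixture
def big_frame():
    return FrameGeometry(128, 128, PIXEL_NM)


@pytest.fixture
def optics_a():
    return OpticsModel(LAMBDA_A, NA)


@pytest.fixture
def optics_b():
    return OpticsModel(LAMBDA_B, NA)


@pytest.fixture
def optics_pair(optics_a, optics_b):
    return {"A": optics_a, "B": optics_b}


@pytest.fixture
def noiseless():
    return NoiseModel.noiseless()


def spot_roi(x_nm, y_nm, photons, frame, optics, noise, seed=None,
             shot_noise=True, half_width=4, rng=None):
    """Render one spot and cut its ROI around the nearest pixel."""
    em = Emitter(x_nm, y_nm, photons, "A")
    img = render_spot(em, frame, optics, noise, seed=seed, rng=rng,
                      shot_noise=shot_noise)
    i = int(y_nm / frame.pixel_size_nm)
    j = int(x_nm / frame.pixel_size_nm)
    return extract_roi(img, (i, j), half_width)
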