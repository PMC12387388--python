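import numpy as np
import pytest

from planim.phantom import PhantomSpec, render_phantom
from planim.video_io import explicit_calibration


@pytest.fixture(scope="session")
def cal_01():
    """0.1 cm/px on both axes (pixel area 0.01 cm²)."""
    return explicit_calibration(0.1, 0.1)


@pytest.fixture
def square_hole_mask():
    """All-ones 20×20 mask with a 10×10 hole of zeros."""
    mask = np.ones((20, 20), dtype=np.uint8)
    mask[5:15, 5:15] = 0
    return mask


@pytest.fixture(scope="session")
def mild_phantom():
    """A rendered phantom with MVA 2.5 cm² (mild stenosis), reused
    read-only across tests."""
    spec = PhantomSpec(diastolic_mva_cm2=2.5, n_frames=12, seed=11)
    frames, truth = render_phantom(spec)
    return spec, frames, truth


def gray_frame(values):
    """Build an RGB frame whose luminance equals ``values`` exactly
    (all three channels equal; weights sum to 0.9999 so the rounded
    luminance reproduces the channel value)."""
    v = np.asarray(values, dtype=np.uint8)
    return np.stack([v, v, v], axis=-1)
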