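import numpy as np
import pytest

from myoseg import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A deterministic 128x128 scene with tubes and overlapping nuclei."""
    spec = SceneSpec(height=128, width=128, n_tubes=2, tube_width_range=(5, 11),
                     n_nuclei=12, nucleus_radius_range=(3, 6), overlap_fraction=0.2,
                     noise_sigma=0.03, background_gradient=0.2, seed=42)
    image, gt = generate_scene(spec)
    return spec, image, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def straight_tube_mask(width_px: int, shape=(40, 80), row=None, margin=5):
    """Constant-width horizontal stroke rendered the same way the generator
    renders tubes (distance-to-axis thresholding)."""
    from scipy import ndimage as ndi

    axis = np.zeros(shape, bool)
    axis[shape[0] // 2 if row is None else row, margin : shape[1] - margin] = True
    dt = ndi.distance_transform_edt(~axis)
    return (dt <= width_px / 2).astype(np.uint8)
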