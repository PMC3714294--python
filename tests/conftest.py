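import math

import numpy as np
import pytest

from tlmquant import RenderParams, ScenarioParams, SyntheticCell


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def noiseless_optics():
    return RenderParams(phase_noise_sd=0.0, fluor_noise_sd=0.0)


@pytest.fixture
def small_params():
    """A compact homogeneous field that segments in well under a second."""
    return ScenarioParams.preset(
        "homogeneous", seed=42, n_seed_cells=12, field_shape=(256, 256)
    )


def make_rod(cell_id, center, intensity=60.0, length=20.0, orientation=math.pi / 2):
    return SyntheticCell(
        id=cell_id,
        center=center,
        orientation=orientation,
        length=length,
        width=5.0,
        true_intensity=intensity,
    )


@pytest.fixture
def touching_pair():
    """Two collinear rods overlapping end-on by ~4 px: one merged object."""
    return [make_rod(1, (60.0, 50.0)), make_rod(2, (60.0, 66.0))]


@pytest.fixture
def separated_pair():
    return [make_rod(1, (60.0, 40.0)), make_rod(2, (60.0, 85.0))]


def random_mask_and_fluor(rng, shape=(48, 48), fg_fraction=0.2, fluor_max=254):
    """A random 0/255 mask plus an independent random fluorescence image.

    ``fluor_max`` 254 avoids saturated pixels (the inverted measurement
    drops them by construction); pass 255 to include the quirk.
    """
    mask = np.where(rng.random(shape) < fg_fraction, 255, 0).astype(np.uint8)
    fluor = rng.integers(0, fluor_max + 1, shape).astype(np.uint8)
    return mask, fluor
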