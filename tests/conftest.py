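import numpy as np
import pytest

from angioquant import SimulationConfig
from angioquant.segment import BinaryMask, GrayImage

# conditions for "clean network" ground-truth recovery: noiseless render,
# thin well-separated tubes, at most 20 segments
CLEAN_NETWORK_KWARGS = dict(
    image_size_px=(384, 384), sprout_count=3, branching_prob=0.04,
    n_steps=30, step_length_um=22.0, diameter_mean_um=9.0,
    diameter_sd_um=1.0, anastomosis_radius_um=16.0, psf_sigma_px=0.0,
    read_noise_sd=0.0, max_segments=20)

# mask-extraction settings matched to those thin tubes
CLEAN_MASK_KWARGS = dict(sigma_px=2.0, min_object_area_px=30,
                         max_hole_area_px=30)


def clean_network_config(seed: int) -> SimulationConfig:
    return SimulationConfig(seed=seed, **CLEAN_NETWORK_KWARGS)


@pytest.fixture
def bar_mask() -> BinaryMask:
    """Solid 100x10 px horizontal bar: one branch, two endpoints."""
    data = np.zeros((30, 120), dtype=bool)
    data[10:20, 10:110] = True
    return BinaryMask(data, 1.0)


@pytest.fixture
def plus_mask() -> BinaryMask:
    """Two crossing 3 px bars: 4 branches around one junction."""
    data = np.zeros((61, 61), dtype=bool)
    data[29:32, 5:56] = True
    data[5:56, 29:32] = True
    return BinaryMask(data, 1.0)


@pytest.fixture
def ladder_mask() -> BinaryMask:
    """Two rails and three rungs: 11 branches, 6 junctions, 4 endpoints."""
    data = np.zeros((120, 60), dtype=bool)
    data[10:110, 10:13] = True
    data[10:110, 47:50] = True
    for y in (30, 60, 90):
        data[y:y + 3, 10:50] = True
    return BinaryMask(data, 1.0)


@pytest.fixture
def small_field():
    """One rendered default-condition field at 0 Gy (module-scoped cache
    would hide rng bugs; cheap enough to rebuild)."""
    from angioquant import render_field, simulate_network
    cfg = SimulationConfig(seed=3, image_size_px=(256, 256), sprout_count=3,
                           n_steps=25)
    truth = simulate_network(cfg)
    return render_field(truth, cfg), cfg


def gray(data, ps=1.0, channel="test") -> GrayImage:
    return GrayImage(np.asarray(data, dtype=float), ps, channel)
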