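"""Channel rendering: mask set identities, rasterization oracle, leakage
forward model."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from angioquant import SimulationConfig, render_field, render_leakage_series
from angioquant.network import NetworkTruth, Segment
from angioquant.render import (WindowAmbiguityError, rasterize_tubes,
                               straight_vessel_truth)

from conftest import clean_network_config


def test_determinism_byte_identical_images():
    cfg = clean_network_config(3).replace(read_noise_sd=10.0)
    from angioquant import generate_network
    net = generate_network(cfg)
    f1, f2 = render_field(net, cfg), render_field(net, cfg)
    for ch in f1.channels:
        np.testing.assert_array_equal(f1[ch].data, f2[ch].data)


def test_laminin_mask_contains_factin_and_dextran_within_factin():
    cfg = SimulationConfig(seed=6, dose_gy=8.0, image_size_px=(256, 256),
                           sprout_count=3, n_steps=20)
    from angioquant import simulate_network
    net = simulate_network(cfg)
    f = render_field(net, cfg)
    m = f.truth.masks
    assert not (m["factin"] & ~m["laminin"]).any()
    assert not (m["dextran"] & ~m["factin"]).any()


def test_no_regression_means_laminin_equals_factin():
    cfg = clean_network_config(1)
    from angioquant import generate_network
    net = generate_network(cfg)
    assert not any(s.regressed for s in net.segments)
    f = render_field(net, cfg)
    np.testing.assert_array_equal(f.truth.masks["laminin"],
                                  f.truth.masks["factin"])


def test_blocked_branch_excluded_from_dextran_mask():
    """An open trunk with one blocked side branch: the dextran truth mask
    is exactly the trunk's lumen."""
    cfg = SimulationConfig(seed=0, image_size_px=(128, 128),
                           read_noise_sd=0.0, psf_sigma_px=0.0)
    trunk = Segment(np.array([[0.0, 64.0], [128.0, 64.0]]), 10.0)
    branch = Segment(np.array([[64.0, 64.0], [64.0, 120.0]]), 10.0,
                     blocked=True)
    # split trunk at the branch point so segments are graph edges
    left = Segment(np.array([[0.0, 64.0], [64.0, 64.0]]), 10.0)
    right = Segment(np.array([[64.0, 64.0], [128.0, 64.0]]), 10.0)
    net = NetworkTruth([left, right, branch], (128.0, 128.0))
    f = render_field(net, cfg)
    trunk_only = rasterize_tubes([left, right], (128, 128), 1.0)
    np.testing.assert_array_equal(f.truth.masks["dextran"], trunk_only)
    assert f.truth.masks["factin"].sum() > trunk_only.sum()


def test_rasterization_matches_per_pixel_distance_oracle():
    """Noiseless, PSF 0: foreground equals an independent shapely-based
    point-to-centerline distance test at every pixel."""
    seg = Segment(np.array([[10.0, 20.0], [50.0, 40.0], [70.0, 15.0]]), 9.0)
    shape = (80, 90)
    mask = rasterize_tubes([seg], shape, 1.0)
    line = LineString(seg.points)
    oracle = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            oracle[r, c] = line.distance(Point(c + 0.5, r + 0.5)) <= 4.5
    np.testing.assert_array_equal(mask, oracle)


# ----------------------------------------------------------------------
# leakage forward model
# ----------------------------------------------------------------------

def leak_config(seed=0, **kw):
    base = dict(image_size_px=(160, 160), read_noise_sd=0.0,
                psf_sigma_px=0.0, background_intensity=0.0)
    base.update(kw)
    return SimulationConfig(seed=seed, **base)


def window_mean(frame, window):
    r0, c0, h, w = window
    return frame.data[r0:r0 + h, c0:c0 + w].mean()


def test_zero_permeability_means_constant_frames():
    cfg = leak_config()
    truth = straight_vessel_truth(cfg, diameter_um=36.0)
    s = render_leakage_series(truth, 0.0, (40, 40, 80, 80), cfg)
    means = [window_mean(f, s.window) for f in s.frames]
    assert np.allclose(means, means[0])


def test_window_mean_follows_closed_form():
    """I1 = 100, Ib = 0, d = 36, pd = 0.01 µm/s: the window mean at 90 s is
    exactly 110 (window half vessel, half background at doubled vessel
    intensity gives I1 = 100)."""
    cfg = leak_config(vessel_intensity=200.0)
    truth = straight_vessel_truth(cfg, diameter_um=36.0)
    # window rows 44..79: 18 background rows + 18 vessel rows → half filled
    window = (44, 40, 36, 80)
    s = render_leakage_series(truth, 0.01, window, cfg)
    i1 = window_mean(s.frames[0], window)
    assert i1 == pytest.approx(100.0)
    assert window_mean(s.frames[-1], window) == pytest.approx(110.0)


def test_slope_linear_in_permeability():
    cfg = leak_config()
    truth = straight_vessel_truth(cfg, diameter_um=36.0)
    window = (40, 40, 80, 80)
    slopes = []
    for pd_true in (0.01, 0.02):
        s = render_leakage_series(truth, pd_true, window, cfg)
        means = np.array([window_mean(f, window) for f in s.frames])
        slopes.append(np.polyfit(s.timestamps_s, means, 1)[0])
    assert slopes[1] == pytest.approx(2 * slopes[0])


def test_window_with_zero_or_two_vessels_is_ambiguous():
    cfg = leak_config()
    truth = straight_vessel_truth(cfg, diameter_um=36.0)
    with pytest.raises(WindowAmbiguityError):
        render_leakage_series(truth, 0.01, (0, 0, 20, 20), cfg)  # off-vessel
    two = NetworkTruth(
        [Segment(np.array([[0.0, 40.0], [160.0, 40.0]]), 20.0),
         Segment(np.array([[0.0, 120.0], [160.0, 120.0]]), 20.0)],
        (160.0, 160.0))
    with pytest.raises(WindowAmbiguityError):
        render_leakage_series(two, 0.01, (10, 10, 140, 140), cfg)


def test_nuclei_focus_and_death_labels_are_recorded():
    cfg = SimulationConfig(seed=8, dose_gy=16.0, image_size_px=(256, 256),
                           sprout_count=3, n_steps=20)
    from angioquant import simulate_network
    net = simulate_network(cfg)
    f = render_field(net, cfg)
    t = f.truth
    n = len(t.nuclei_px)
    assert n > 0
    assert t.live.shape == (n,) and t.focus_counts.shape == (n,)
    assert t.masks["gh2ax"].any() == (t.focus_counts.sum() > 0)
    # dead fraction at 16 Gy should be clearly above the 0 Gy baseline
    assert (~t.live).mean() > 0.3
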