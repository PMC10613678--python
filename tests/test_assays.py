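"""Permeability, window diameter, perfused and regressed fractions."""

import numpy as np
import pytest

from angioquant import (SimulationConfig, estimate_permeability,
                        measure_window_diameter, perfused_fraction,
                        regressed_fraction, render_leakage_series)
from angioquant.assays import (UndefinedFractionError,
                               UndefinedPermeabilityError,
                               WindowDiameterError)
from angioquant.render import TimeLapseSeries, straight_vessel_truth
from angioquant.segment import BinaryMask, GrayImage


def series_from_means(means, times, d=36.0, ib=0.0):
    frames = [GrayImage(np.full((8, 8), m), 1.0) for m in means]
    return TimeLapseSeries(frames, np.asarray(times, dtype=float),
                           (0, 0, 8, 8), d, ib)


def test_two_point_formula_hand_arithmetic():
    s = series_from_means([100.0, 110.0], [0.0, 90.0])
    r = estimate_permeability(s, "two-point")
    assert r.pd_um_s == pytest.approx((10 / 100) / 90 * 9, rel=1e-12)
    assert r.pd_cm_s == pytest.approx(r.pd_um_s * 1e-4, rel=1e-12)


def test_equal_endpoint_intensities_give_zero_pd():
    s = series_from_means([100.0, 100.0], [0.0, 90.0])
    assert estimate_permeability(s, "two-point").pd_um_s == 0.0


def test_i1_not_above_background_is_undefined():
    s = series_from_means([10.0, 20.0], [0.0, 90.0], ib=10.0)
    with pytest.raises(UndefinedPermeabilityError):
        estimate_permeability(s)


def test_two_point_doubles_when_interval_halves():
    a = estimate_permeability(series_from_means([100, 110], [0, 90]),
                              "two-point")
    b = estimate_permeability(series_from_means([100, 110], [0, 45]),
                              "two-point")
    assert b.pd_um_s == pytest.approx(2 * a.pd_um_s)


def test_pd_invariant_to_affine_intensity_rescaling():
    means = [100.0, 102.0, 105.0, 106.0, 109.0]
    times = [0, 10, 20, 30, 40]
    base = estimate_permeability(series_from_means(means, times))
    scaled = estimate_permeability(series_from_means(
        [3 * m + 50 for m in means], times, ib=3 * 0.0 + 50))
    assert scaled.pd_um_s == pytest.approx(base.pd_um_s, rel=1e-12)


def test_pd_linear_in_diameter():
    means = [100.0, 105.0, 110.0]
    a = estimate_permeability(series_from_means(means, [0, 10, 20], d=18.0))
    b = estimate_permeability(series_from_means(means, [0, 10, 20], d=36.0))
    assert b.pd_um_s == pytest.approx(2 * a.pd_um_s)


def test_regression_mode_recovers_simulated_truth():
    cfg = SimulationConfig(seed=0, image_size_px=(160, 160),
                           read_noise_sd=0.0, psf_sigma_px=0.0)
    truth = straight_vessel_truth(cfg, diameter_um=36.0)
    s = render_leakage_series(truth, 0.02, (40, 40, 80, 80), cfg)
    r = estimate_permeability(s, "regression")
    assert r.pd_um_s == pytest.approx(0.02, rel=0.01)
    assert r.r_squared > 0.999


def test_series_requires_increasing_times_and_two_frames():
    with pytest.raises(ValueError):
        series_from_means([1.0], [0.0])
    with pytest.raises(ValueError):
        series_from_means([100.0, 101.0], [10.0, 10.0])


# ------------------------------------------------------------- diameter

def test_window_diameter_of_straight_bar():
    data = np.zeros((60, 120), dtype=bool)
    data[20:40, :] = True  # 20 px wide tube
    d = measure_window_diameter(BinaryMask(data, 1.0), (10, 40, 40, 40))
    assert d == pytest.approx(20.0, abs=1.5)


def test_window_diameter_off_vessel_is_ambiguous():
    data = np.zeros((60, 120), dtype=bool)
    data[20:40, :] = True
    with pytest.raises(WindowDiameterError):
        measure_window_diameter(BinaryMask(data, 1.0), (45, 0, 10, 10))


def test_window_diameter_recovers_synthetic_truth_within_5_percent():
    cfg = SimulationConfig(seed=1, image_size_px=(160, 160),
                           read_noise_sd=0.0, psf_sigma_px=0.0)
    truth = straight_vessel_truth(cfg, diameter_um=36.0)
    from angioquant.render import rasterize_tubes
    mask = BinaryMask(rasterize_tubes(truth.segments, (160, 160), 1.0), 1.0)
    d = measure_window_diameter(mask, (40, 40, 80, 80))
    assert d == pytest.approx(36.0, rel=0.05)


# ------------------------------------------------------------- fractions

def checkerboard_masks():
    vessel = np.zeros((40, 50), dtype=bool)
    vessel[5:25, :] = True  # 1000 px
    dex = np.zeros_like(vessel)
    dex[5:25, :20] = True   # 400 of them
    return BinaryMask(dex, 1.0), BinaryMask(vessel, 1.0)


def test_perfused_fraction_direct_ratio():
    dex, ves = checkerboard_masks()
    r = perfused_fraction(dex, ves)
    assert r.fraction == 0.40
    assert r.numerator_um2 == 400.0 and r.denominator_um2 == 1000.0


def test_perfused_fraction_capped_by_intersection():
    dex, ves = checkerboard_masks()
    everywhere = BinaryMask(np.ones_like(ves.data), 1.0)
    assert perfused_fraction(everywhere, ves).fraction == 1.0


def test_perfused_fraction_empty_vessel_mask_is_undefined():
    dex, ves = checkerboard_masks()
    with pytest.raises(UndefinedFractionError):
        perfused_fraction(dex, BinaryMask(np.zeros_like(ves.data), 1.0))


def test_regressed_fraction_set_arithmetic():
    laminin = np.zeros((40, 50), dtype=bool)
    laminin[0:20, :] = True          # 1000 px
    factin = np.zeros_like(laminin)
    factin[0:14, :] = True           # overlap 700 px
    r = regressed_fraction(BinaryMask(laminin, 1.0), BinaryMask(factin, 1.0))
    assert r.fraction == pytest.approx(0.30)


def test_regressed_fraction_zero_when_masks_equal():
    m = np.zeros((20, 20), dtype=bool)
    m[5:15, 5:15] = True
    r = regressed_fraction(BinaryMask(m, 1.0), BinaryMask(m.copy(), 1.0))
    assert r.fraction == 0.0


@pytest.mark.parametrize("transform", [np.rot90, np.fliplr, np.flipud])
def test_fractions_invariant_to_rotation_and_reflection(transform):
    dex, ves = checkerboard_masks()
    base = perfused_fraction(dex, ves).fraction
    t = perfused_fraction(BinaryMask(transform(dex.data), 1.0),
                          BinaryMask(transform(ves.data), 1.0)).fraction
    assert t == base


def test_fractions_invariant_to_pixel_size():
    dex, ves = checkerboard_masks()
    base = perfused_fraction(dex, ves).fraction
    big = perfused_fraction(BinaryMask(dex.data, 2.5),
                            BinaryMask(ves.data, 2.5)).fraction
    assert big == base


def test_perfused_fraction_matches_simulator_truth():
    cfg = SimulationConfig(seed=12, dose_gy=8.0, image_size_px=(384, 384),
                           sprout_count=4, n_steps=30, read_noise_sd=0.0,
                           psf_sigma_px=0.0)
    from angioquant import render_field, simulate_network
    net = simulate_network(cfg)
    f = render_field(net, cfg)
    t = f.truth.masks
    r = perfused_fraction(BinaryMask(t["dextran"], 1.0),
                          BinaryMask(t["factin"], 1.0))
    assert r.fraction == pytest.approx(net.perfused_area_fraction(), abs=0.03)


def test_regressed_fraction_matches_simulator_truth():
    cfg = SimulationConfig(seed=13, dose_gy=16.0, image_size_px=(384, 384),
                           sprout_count=4, n_steps=30, read_noise_sd=0.0,
                           psf_sigma_px=0.0)
    from angioquant import render_field, simulate_network
    net = simulate_network(cfg)
    f = render_field(net, cfg)
    t = f.truth.masks
    r = regressed_fraction(BinaryMask(t["laminin"], 1.0),
                           BinaryMask(t["factin"], 1.0))
    assert r.fraction == pytest.approx(net.regressed_area_fraction(),
                                       abs=0.05)
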