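"""Nuclei segmentation, focus counting, positivity and viability calls."""

import numpy as np
import pytest

from angioquant import (SimulationConfig, classify_positive, count_foci,
                        measure_viability, render_field, segment_nuclei,
                        simulate_network)
from angioquant.cells import NoCellsError, NucleiLabels
from angioquant.segment import GrayImage


def disk_image(centres, radius, shape=(128, 128), value=120.0, bg=0.0):
    rr, cc = np.mgrid[:shape[0], :shape[1]]
    data = np.full(shape, bg)
    for r0, c0 in centres:
        data[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2] = value
    return GrayImage(data, 1.0, "dapi")


def labels_from(centres, radius, shape=(128, 128)) -> NucleiLabels:
    rr, cc = np.mgrid[:shape[0], :shape[1]]
    lab = np.zeros(shape, dtype=int)
    for i, (r0, c0) in enumerate(centres, start=1):
        lab[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2] = i
    areas = np.array([(lab == i).sum() for i in range(1, len(centres) + 1)],
                     dtype=float)
    return NucleiLabels(lab, 1.0, np.asarray(centres, dtype=float), areas)


def test_blank_image_yields_no_nuclei():
    with pytest.warns(UserWarning):
        out = segment_nuclei(GrayImage(np.zeros((64, 64)), 1.0))
    assert out.count == 0


def test_two_disjoint_disks_found_with_centroids():
    img = disk_image([(30, 30), (90, 95)], 9)
    out = segment_nuclei(img)
    assert out.count == 2
    got = sorted(map(tuple, np.round(out.centroids_px).astype(int)))
    assert got[0] == pytest.approx((30, 30), abs=1)
    assert got[1] == pytest.approx((90, 95), abs=1)


def test_touching_disks_split_by_watershed():
    img = disk_image([(60, 50), (60, 68)], 10)
    out = segment_nuclei(img, peak_min_distance_px=5)
    assert out.count == 2


def test_nucleus_count_recovered_on_simulated_fields():
    """Non-overlapping simulated nuclei: detected count within 2% of truth
    over many seeded fields."""
    total_truth = total_found = 0
    for seed in range(50):
        cfg = SimulationConfig(seed=seed, image_size_px=(256, 256),
                               sprout_count=2, n_steps=20)
        truth = simulate_network(cfg)
        f = render_field(truth, cfg)
        total_truth += len(f.truth.nuclei_px)
        total_found += segment_nuclei(f["dapi"]).count
    assert total_truth > 200
    assert abs(total_found - total_truth) / total_truth <= 0.02


# ------------------------------------------------------------------ foci

def test_zero_signal_means_zero_foci():
    nuclei = labels_from([(40, 40)], 10)
    foci = count_foci(GrayImage(np.zeros((128, 128)), 1.0), nuclei)
    assert foci.total_count == 0 and foci.total_area_um2 == 0.0


def test_three_rendered_foci_counted_with_area():
    nuclei = labels_from([(60, 60)], 14)
    rr, cc = np.mgrid[:128, :128]
    sig = np.zeros((128, 128))
    centres = [(54, 60), (66, 54), (66, 66)]
    for r0, c0 in centres:
        sig[(rr - r0) ** 2 + (cc - c0) ** 2 <= 4] = 200.0
    foci = count_foci(GrayImage(sig, 1.0), nuclei, tophat_radius_px=4,
                      rel_threshold=0.5)
    one_disk = ((rr - 54) ** 2 + (cc - 60) ** 2 <= 4).sum()
    assert foci.total_count == 3
    assert foci.per_nucleus_counts.tolist() == [3]
    assert foci.total_area_um2 == pytest.approx(3 * one_disk, abs=6)


def test_foci_outside_nuclei_are_excluded():
    nuclei = labels_from([(30, 30)], 10)
    rr, cc = np.mgrid[:128, :128]
    sig = np.zeros((128, 128))
    sig[(rr - 30) ** 2 + (cc - 30) ** 2 <= 4] = 200.0       # inside
    sig[(rr - 100) ** 2 + (cc - 100) ** 2 <= 4] = 200.0     # outside
    foci = count_foci(GrayImage(sig, 1.0), nuclei, tophat_radius_px=4)
    assert foci.total_count == 1


def test_per_nucleus_counts_sum_to_total():
    cfg = SimulationConfig(seed=3, dose_gy=8.0, image_size_px=(256, 256),
                           sprout_count=2, n_steps=20)
    f = render_field(simulate_network(cfg), cfg)
    nuclei = segment_nuclei(f["dapi"])
    foci = count_foci(f["gh2ax"], nuclei)
    assert foci.per_nucleus_counts.sum() == foci.total_count


# ------------------------------------------------------------ positivity

def test_all_dark_signal_gives_zero_fraction():
    nuclei = labels_from([(30, 30), (90, 90)], 8)
    r = classify_positive(nuclei, GrayImage(np.zeros((128, 128)), 1.0))
    assert r.fraction == 0.0


def test_constructed_four_of_ten_positive():
    centres = [(20 + 20 * i, 20 + 10 * (i % 3)) for i in range(10)]
    centres = [(r % 120, c) for r, c in centres]
    nuclei = labels_from(centres, 6, shape=(160, 160))
    sig = np.zeros((160, 160))
    rr, cc = np.mgrid[:160, :160]
    for r0, c0 in centres[:4]:
        sig[(rr - r0) ** 2 + (cc - c0) ** 2 <= 36] = 150.0
    r = classify_positive(nuclei, GrayImage(sig, 1.0))
    assert r.positive == 4 and r.total == 10
    assert r.fraction == pytest.approx(0.4)


def test_fractions_invariant_to_global_intensity_scaling():
    centres = [(30, 30), (30, 90), (90, 30), (90, 90)]
    nuclei = labels_from(centres, 8)
    sig = np.zeros((128, 128))
    rr, cc = np.mgrid[:128, :128]
    for r0, c0 in centres[:2]:
        sig[(rr - r0) ** 2 + (cc - c0) ** 2 <= 64] = 100.0
    a = classify_positive(nuclei, GrayImage(sig, 1.0)).fraction
    b = classify_positive(nuclei, GrayImage(sig * 7.3, 1.0)).fraction
    assert a == b == 0.5


def test_no_cells_raises():
    empty = NucleiLabels(np.zeros((32, 32), dtype=int), 1.0,
                         np.empty((0, 2)), np.empty((0,)))
    with pytest.raises(NoCellsError):
        classify_positive(empty, GrayImage(np.zeros((32, 32)), 1.0))


def test_viability_live_over_classified():
    centres = [(30, 30), (30, 90), (90, 30), (90, 90)]
    nuclei = labels_from(centres, 8)
    rr, cc = np.mgrid[:128, :128]
    calcein = np.zeros((128, 128))
    ethd = np.zeros((128, 128))
    for r0, c0 in centres[:3]:
        calcein[(rr - r0) ** 2 + (cc - c0) ** 2 <= 64] = 120.0
    for r0, c0 in centres[3:]:
        ethd[(rr - r0) ** 2 + (cc - c0) ** 2 <= 64] = 120.0
    r = measure_viability(nuclei, GrayImage(calcein, 1.0),
                          GrayImage(ethd, 1.0))
    assert r.positive == 3 and r.total == 4
    assert r.fraction == pytest.approx(0.75)


def test_damage_readouts_follow_dose_direction():
    """Caspase fraction rises and viability falls with dose on simulated
    replicates (small Monte Carlo; the full grid runs in the acceptance
    suite)."""
    res = {0.0: [], 16.0: []}
    via = {0.0: [], 16.0: []}
    for dose in res:
        for seed in range(4):
            cfg = SimulationConfig(seed=seed, dose_gy=dose,
                                   image_size_px=(256, 256), sprout_count=3,
                                   n_steps=20)
            f = render_field(simulate_network(cfg), cfg)
            nuclei = segment_nuclei(f["dapi"])
            if nuclei.count == 0:
                continue  # a fully destroyed field carries no cells to score
            res[dose].append(classify_positive(nuclei, f["nucview"]).fraction)
            via[dose].append(measure_viability(nuclei, f["calcein"],
                                               f["ethd"]).fraction)
    assert np.mean(res[16.0]) > np.mean(res[0.0])
    assert np.mean(via[16.0]) < np.mean(via[0.0])
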