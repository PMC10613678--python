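"""Cell-level damage assays: nuclei, γH2AX foci, caspase-3, viability.

Nuclei are segmented from the nuclear counterstain (DAPI/Hoechst) by
Gaussian blur → Otsu threshold → distance-transform watershed (to split
touching nuclei) → minimum-area filter.  γH2AX foci are detected inside
nucleus masks with a white top-hat followed by a threshold relative to the
brightest in-nucleus top-hat response, and counted per nucleus and per
field.  Positivity calls (caspase-3 reporter, calcein, ethidium
homodimer-1) compare each nucleus's mean signal to a fraction of the
field's robust maximum (99.5th percentile), which makes all fractions
invariant to global intensity scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk, white_tophat
from skimage.segmentation import relabel_sequential, watershed

from .segment import GrayImage, otsu_separates


@dataclass
class NucleiLabels:
    """Labelled nuclei: 0 = background, k = nucleus k (contiguous 1..K)."""

    labels: np.ndarray
    pixel_size_um: float
    centroids_px: np.ndarray        # (K, 2) float (row, col)
    areas_um2: np.ndarray           # (K,)
    flags: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        return int(self.labels.max())


@dataclass
class FociResult:
    total_count: int
    total_area_um2: float
    per_nucleus_counts: np.ndarray  # (K,) aligned with nucleus labels 1..K
    count_per_field_area_mm2: float


@dataclass
class CellFractionResult:
    positive: int
    total: int
    fraction: float
    assay: str


class NoCellsError(ValueError):
    """No nuclei available to normalize a per-cell fraction."""


# ----------------------------------------------------------------------

def segment_nuclei(dapi: GrayImage, min_area_px: int = 30,
                   blur_sigma_px: float = 2.0,
                   peak_min_distance_px: int = 5,
                   min_contrast_sigmas: float = 4.0) -> NucleiLabels:
    """Segment nuclei from the nuclear counterstain channel.

    Deterministic given its inputs.  An image whose Otsu split does not
    separate its classes by ``min_contrast_sigmas`` within-class SDs is
    treated as nucleus-free (Otsu on a signal-free channel would otherwise
    shred background noise into spurious nuclei); an empty labelling with a
    warning flag is returned.
    """
    data = dapi.data
    smoothed = gaussian(data, sigma=blur_sigma_px, preserve_range=True)
    if smoothed.min() == smoothed.max():
        warnings.warn("no nuclei found: constant image")
        return _empty_labels(dapi, {"no_nuclei": True})
    if min_contrast_sigmas > 0 and not otsu_separates(smoothed,
                                                      min_contrast_sigmas):
        warnings.warn("no nuclei found: channel has no real signal")
        return _empty_labels(dapi, {"no_nuclei": True})
    thr = threshold_otsu(smoothed)
    fg = smoothed > thr
    if not fg.any():
        warnings.warn("no nuclei found above threshold")
        return _empty_labels(dapi, {"no_nuclei": True})
    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=peak_min_distance_px,
                           labels=fg, exclude_border=False)
    markers = np.zeros_like(data, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = cc_label(fg, connectivity=2)
    else:
        labels = watershed(-dist, markers, mask=fg)
    # area filter and relabel to contiguous 1..K
    sizes = np.bincount(labels.ravel())
    drop = np.nonzero(sizes < min_area_px)[0]
    labels[np.isin(labels, drop[drop > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    if labels.max() == 0:
        warnings.warn("no nuclei survived the area filter")
        return _empty_labels(dapi, {"no_nuclei": True})
    props = regionprops(labels)
    centroids = np.array([p.centroid for p in props])
    areas = np.array([p.area for p in props]) * dapi.pixel_size_um ** 2
    return NucleiLabels(labels=labels, pixel_size_um=dapi.pixel_size_um,
                        centroids_px=centroids, areas_um2=areas)


def _empty_labels(img: GrayImage, flags: dict) -> NucleiLabels:
    return NucleiLabels(labels=np.zeros(img.data.shape, dtype=int),
                        pixel_size_um=img.pixel_size_um,
                        centroids_px=np.empty((0, 2)),
                        areas_um2=np.empty((0,)), flags=flags)


# ----------------------------------------------------------------------

def count_foci(gh2ax: GrayImage, nuclei: NucleiLabels,
               tophat_radius_px: int = 5,
               rel_threshold: float = 0.5) -> FociResult:
    """Count DNA damage foci inside nuclei.

    White top-hat (structuring disk of the given radius) isolates puncta
    from diffuse nuclear signal; pixels above ``rel_threshold`` × the
    maximum in-nucleus top-hat response become focus candidates, and
    8-connected components inside nucleus masks are counted.  Foci outside
    every nucleus are ignored.  Counts are reported per nucleus, per field,
    and per mm² of field area.
    """
    if gh2ax.data.shape != nuclei.labels.shape:
        raise ValueError("signal and labels differ in shape")
    k = nuclei.count
    field_area_mm2 = (gh2ax.data.size * gh2ax.pixel_size_um ** 2) / 1e6
    if k == 0:
        return FociResult(0, 0.0, np.zeros(0, dtype=int), 0.0)
    inside = nuclei.labels > 0
    th = white_tophat(gh2ax.data, footprint=disk(tophat_radius_px))
    peak = th[inside].max()
    if peak <= 0:
        return FociResult(0, 0.0, np.zeros(k, dtype=int), 0.0)
    fmask = (th > rel_threshold * peak) & inside
    comps = cc_label(fmask, connectivity=2)
    per_nucleus = np.zeros(k, dtype=int)
    for p in regionprops(comps):
        r, c = (int(round(x)) for x in p.centroid)
        r = np.clip(r, 0, nuclei.labels.shape[0] - 1)
        c = np.clip(c, 0, nuclei.labels.shape[1] - 1)
        owner = nuclei.labels[r, c]
        if owner == 0:  # centroid off-nucleus: assign via any member pixel
            rr, cc = p.coords[0]
            owner = nuclei.labels[rr, cc]
        if owner > 0:
            per_nucleus[owner - 1] += 1
    total = int(per_nucleus.sum())
    area = float(fmask.sum()) * gh2ax.pixel_size_um ** 2
    return FociResult(total_count=total, total_area_um2=area,
                      per_nucleus_counts=per_nucleus,
                      count_per_field_area_mm2=total / field_area_mm2)


# ----------------------------------------------------------------------

def _positive_cells(cells: NucleiLabels, signal: GrayImage,
                    rel_threshold: float) -> np.ndarray:
    """Boolean positivity per nucleus: background-subtracted mean in-nucleus
    signal above rel_threshold × the field's robust dynamic range.

    Background is the field median (stains cover a minority of pixels);
    the robust max is the 99.5th percentile, which resists hot pixels.
    Both the subtraction and the relative threshold make the call invariant
    to affine intensity rescaling."""
    if signal.data.shape != cells.labels.shape:
        raise ValueError("signal and labels differ in shape")
    if not (0.0 < rel_threshold <= 1.0):
        raise ValueError("rel_threshold must be in (0, 1]")
    background = float(np.median(signal.data))
    robust_max = float(np.percentile(signal.data, 99.5))
    if robust_max <= background:
        return np.zeros(cells.count, dtype=bool)
    means = ndi.mean(signal.data, labels=cells.labels,
                     index=np.arange(1, cells.count + 1))
    return (np.asarray(means) - background) > rel_threshold * (robust_max
                                                               - background)


def classify_positive(cells: NucleiLabels, signal: GrayImage,
                      rel_threshold: float = 0.3,
                      assay: str = "caspase3") -> CellFractionResult:
    """Fraction of cells positive for a reporter channel (e.g. caspase-3
    normalized by nucleus count)."""
    if cells.count == 0:
        raise NoCellsError("no nuclei to classify")
    positive = int(_positive_cells(cells, signal, rel_threshold).sum())
    return CellFractionResult(positive=positive, total=cells.count,
                              fraction=positive / cells.count, assay=assay)


def measure_viability(cells: NucleiLabels, calcein: GrayImage,
                      ethd: GrayImage, rel_threshold: float = 0.3,
                      denominator: str = "classified") -> CellFractionResult:
    """Live/dead viability from calcein-AM and ethidium homodimer-1.

    Default: viability = live / (live + dead) over cells classified by
    either stain; ``denominator='nuclei'`` instead normalizes live cells by
    all counterstained nuclei.
    """
    if cells.count == 0:
        raise NoCellsError("no nuclei to classify")
    live = _positive_cells(cells, calcein, rel_threshold)
    dead = _positive_cells(cells, ethd, rel_threshold)
    # a cell bright in both stains is called dead (membrane compromise wins)
    live = live & ~dead
    n_live, n_dead = int(live.sum()), int(dead.sum())
    if denominator == "classified":
        total = n_live + n_dead
        if total == 0:
            raise NoCellsError("no cell classified by either stain")
    elif denominator == "nuclei":
        total = cells.count
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return CellFractionResult(positive=n_live, total=total,
                              fraction=n_live / total, assay="viability")
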