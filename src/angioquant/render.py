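"""Render synthetic fluorescence channels and leakage time-series.

Channels are rendered from the ground-truth network as ideal per-pixel masks
(tube membership by exact point-to-centerline distance), then degraded with a
Gaussian PSF and read/shot noise.  Every render returns the clean truth masks
and per-cell labels alongside the noisy images, so downstream quantification
can be scored against truth.

Channel semantics
-----------------
factin    tubes of all non-regressed segments (endothelial cytoskeleton)
laminin   tubes of all segments, regressed included (basement membrane persists)
dapi      nuclear disks placed along non-regressed segments
dextran   lumens of perfused segments (open and reachable from the inlet edge)
gh2ax     DNA double-strand-break foci inside nuclei, Poisson per nucleus
calcein   cell bodies of live cells;  ethd: nuclei of dead cells
nucview   nuclei of caspase-3-positive (apoptotic) cells

Pixel (r, c) samples the physical point ((c+0.5)·ps, (r+0.5)·ps) µm, x right,
y down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import SimulationConfig
from .network import NetworkTruth, Segment
from .segment import GrayImage

CHANNELS = ("factin", "laminin", "dapi", "dextran", "gh2ax",
            "calcein", "ethd", "nucview")


@dataclass
class FieldTruth:
    """Clean per-pixel masks and per-cell labels backing a rendered field."""

    masks: dict[str, np.ndarray]          # boolean, pre-PSF/noise
    nuclei_px: np.ndarray                 # (N, 2) float (row, col) centres
    live: np.ndarray                      # (N,) bool
    caspase_positive: np.ndarray          # (N,) bool
    focus_counts: np.ndarray              # (N,) int
    network: NetworkTruth
    dose_gy: float


@dataclass
class MultiChannelField:
    """A registered set of single-channel images with shared pixel size."""

    channels: dict[str, GrayImage]
    pixel_size_um: float
    truth: FieldTruth | None = None

    def __getitem__(self, name: str) -> GrayImage:
        return self.channels[name]


@dataclass
class TimeLapseSeries:
    """Dextran leakage frames with timestamps and the measuring window."""

    frames: list[GrayImage]
    timestamps_s: np.ndarray
    window: tuple[int, int, int, int]     # (row0, col0, height, width) px
    vessel_diameter_um: float
    background_intensity: float
    pd_true_um_s: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps_s, dtype=float)
        if len(self.frames) < 2:
            raise ValueError("a time-lapse series needs at least 2 frames")
        if len(t) != len(self.frames):
            raise ValueError("timestamps and frames differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        self.timestamps_s = t


# ----------------------------------------------------------------------
# rasterization
# ----------------------------------------------------------------------

def _segment_distance_field(points: np.ndarray, xs: np.ndarray,
                            ys: np.ndarray) -> np.ndarray:
    """Min distance from grid points (xs, ys broadcastable) to a polyline."""
    dmin = np.full(np.broadcast(xs, ys).shape, np.inf)
    p = points
    for i in range(len(p) - 1):
        ax, ay = p[i]
        bx, by = p[i + 1]
        ux, uy = bx - ax, by - ay
        denom = ux * ux + uy * uy
        if denom == 0:
            d = np.hypot(xs - ax, ys - ay)
        else:
            t = np.clip(((xs - ax) * ux + (ys - ay) * uy) / denom, 0.0, 1.0)
            d = np.hypot(xs - (ax + t * ux), ys - (ay + t * uy))
        np.minimum(dmin, d, out=dmin)
    return dmin


def rasterize_tubes(segments: list[Segment], shape: tuple[int, int],
                    pixel_size_um: float) -> np.ndarray:
    """Boolean mask of pixels whose centre lies within diameter/2 of a
    segment centreline.  Exact (no sampling) per-pixel distance test,
    restricted to each segment's bounding box for speed."""
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    ps = pixel_size_um
    for seg in segments:
        r = seg.diameter_um / 2.0
        x0 = seg.points[:, 0].min() - r
        x1 = seg.points[:, 0].max() + r
        y0 = seg.points[:, 1].min() - r
        y1 = seg.points[:, 1].max() + r
        c0 = max(int(math.floor(x0 / ps - 0.5)), 0)
        c1 = min(int(math.ceil(x1 / ps + 0.5)), w - 1)
        r0 = max(int(math.floor(y0 / ps - 0.5)), 0)
        r1 = min(int(math.ceil(y1 / ps + 0.5)), h - 1)
        if c1 < c0 or r1 < r0:
            continue
        cols = (np.arange(c0, c1 + 1) + 0.5) * ps
        rows = (np.arange(r0, r1 + 1) + 0.5) * ps
        xs = cols[None, :]
        ys = rows[:, None]
        d = _segment_distance_field(seg.points, xs, ys)
        mask[r0:r1 + 1, c0:c1 + 1] |= d <= r
    return mask


def _disk(shape: tuple[int, int], centre_rc: tuple[float, float],
          radius_px: float) -> np.ndarray:
    h, w = shape
    r0 = max(int(math.floor(centre_rc[0] - radius_px - 1)), 0)
    r1 = min(int(math.ceil(centre_rc[0] + radius_px + 1)), h - 1)
    c0 = max(int(math.floor(centre_rc[1] - radius_px - 1)), 0)
    c1 = min(int(math.ceil(centre_rc[1] + radius_px + 1)), w - 1)
    mask = np.zeros(shape, dtype=bool)
    if r1 < r0 or c1 < c0:
        return mask
    rr = np.arange(r0, r1 + 1)[:, None]
    cc = np.arange(c0, c1 + 1)[None, :]
    mask[r0:r1 + 1, c0:c1 + 1] = (
        (rr - centre_rc[0]) ** 2 + (cc - centre_rc[1]) ** 2 <= radius_px ** 2)
    return mask


def _apply_optics(clean: np.ndarray, config: SimulationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    img = clean.astype(float)
    if config.psf_sigma_px > 0:
        img = gaussian_filter(img, config.psf_sigma_px)
    noise = np.zeros_like(img)
    if config.read_noise_sd > 0:
        noise += rng.normal(0.0, config.read_noise_sd, img.shape)
    if config.shot_noise_scale > 0:
        noise += rng.normal(0.0, 1.0, img.shape) * np.sqrt(
            config.shot_noise_scale * np.maximum(img, 0.0))
    return np.clip(img + noise, 0.0, None)


# ----------------------------------------------------------------------
# field rendering
# ----------------------------------------------------------------------

def _place_nuclei(truth: NetworkTruth, config: SimulationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Nucleus centres (row, col) px along non-regressed centrelines.

    Placement rejects candidates closer than 2.2 nuclear radii to any
    accepted nucleus, so rendered nuclei never merge and counts stay
    recoverable by segmentation."""
    ps = config.pixel_size_um
    rad_um = config.nucleus_radius_um
    min_sep_um = 2.2 * rad_um
    h, w = config.image_size_px
    accepted: list[np.ndarray] = []
    for seg in truth.segments:
        if seg.regressed:
            continue
        length = seg.length_um()
        n = max(1, int(round(length / config.nucleus_spacing_um)))
        cum = np.concatenate([[0.0], np.cumsum(
            np.hypot(*(np.diff(seg.points, axis=0).T)))])
        for k in range(n):
            s = (k + rng.uniform(0.2, 0.8)) / n * length
            i = int(np.searchsorted(cum, s, side="right") - 1)
            i = min(i, len(seg.points) - 2)
            span = cum[i + 1] - cum[i]
            frac = 0.0 if span == 0 else (s - cum[i]) / span
            pt = seg.points[i] * (1 - frac) + seg.points[i + 1] * frac
            # lateral jitter keeps the nucleus inside the tube
            max_off = max(seg.diameter_um / 2.0 - rad_um, 0.0)
            ang = rng.uniform(0, 2 * math.pi)
            off = rng.uniform(0, max_off)
            pos = pt + off * np.array([math.cos(ang), math.sin(ang)])
            rc = np.array([pos[1] / ps - 0.5, pos[0] / ps - 0.5])
            if not (rad_um / ps <= rc[0] <= h - 1 - rad_um / ps
                    and rad_um / ps <= rc[1] <= w - 1 - rad_um / ps):
                continue
            if any(np.hypot(*(rc - q)) * ps < min_sep_um for q in accepted):
                continue
            accepted.append(rc)
    if not accepted:
        return np.empty((0, 2))
    return np.asarray(accepted)


def render_field(truth: NetworkTruth,
                 config: SimulationConfig) -> MultiChannelField:
    """Render every assay channel of a field from its ground-truth network."""
    shape = config.image_size_px
    ps = config.pixel_size_um
    dose = truth.dose_gy
    rng = np.random.default_rng([config.seed, 0x7266])  # stage tag: render

    factin_mask = rasterize_tubes(truth.channel_segments("factin"), shape, ps)
    laminin_mask = rasterize_tubes(truth.channel_segments("laminin"), shape, ps)
    dextran_mask = rasterize_tubes(truth.channel_segments("dextran"), shape, ps)

    nuclei = _place_nuclei(truth, config, rng)
    n_cells = len(nuclei)
    p_dead = 1.0 - (1.0 - config.death_baseline) * math.exp(
        -config.death_rate * dose)
    p_casp = 1.0 - (1.0 - config.caspase_baseline) * math.exp(
        -config.caspase_rate * dose)
    live = rng.random(n_cells) >= p_dead
    caspase = rng.random(n_cells) < p_casp
    focus_counts = rng.poisson(config.focus_baseline
                               + config.focus_rate * dose, size=n_cells)

    nuc_r_px = config.nucleus_radius_um / ps
    body_r_px = config.cell_body_radius_um / ps
    dapi_mask = np.zeros(shape, dtype=bool)
    calcein_mask = np.zeros(shape, dtype=bool)
    ethd_mask = np.zeros(shape, dtype=bool)
    nucview_mask = np.zeros(shape, dtype=bool)
    gh2ax_mask = np.zeros(shape, dtype=bool)
    for i, rc in enumerate(nuclei):
        nd = _disk(shape, tuple(rc), nuc_r_px)
        dapi_mask |= nd
        if live[i]:
            calcein_mask |= _disk(shape, tuple(rc), body_r_px)
        else:
            ethd_mask |= nd
        if caspase[i]:
            nucview_mask |= nd
        # foci: non-overlapping small disks inside the nucleus
        placed: list[np.ndarray] = []
        attempts = 0
        while len(placed) < focus_counts[i] and attempts < 200:
            attempts += 1
            ang = rng.uniform(0, 2 * math.pi)
            rr = rng.uniform(0, nuc_r_px - config.focus_radius_px - 1)
            cand = rc + rr * np.array([math.sin(ang), math.cos(ang)])
            # keep puncta separated enough to survive PSF blur as distinct
            if any(np.hypot(*(cand - q)) < 2 * config.focus_radius_px + 3.0
                   for q in placed):
                continue
            placed.append(cand)
            gh2ax_mask |= _disk(shape, tuple(cand), config.focus_radius_px)
        focus_counts[i] = len(placed)

    intensities = {
        "factin": factin_mask * config.vessel_intensity,
        "laminin": laminin_mask * config.vessel_intensity,
        "dextran": dextran_mask * config.vessel_intensity,
        "dapi": dapi_mask * config.nucleus_intensity,
        "gh2ax": (dapi_mask * 0.1 * config.nucleus_intensity
                  + gh2ax_mask * config.focus_intensity),
        "calcein": calcein_mask * config.nucleus_intensity,
        "ethd": ethd_mask * config.nucleus_intensity,
        "nucview": nucview_mask * config.nucleus_intensity,
    }
    channels = {
        name: GrayImage(
            data=_apply_optics(img + config.background_intensity, config, rng),
            pixel_size_um=ps, channel=name)
        for name, img in intensities.items()
    }
    field_truth = FieldTruth(
        masks={"factin": factin_mask, "laminin": laminin_mask,
               "dextran": dextran_mask, "dapi": dapi_mask,
               "gh2ax": gh2ax_mask, "calcein": calcein_mask,
               "ethd": ethd_mask, "nucview": nucview_mask},
        nuclei_px=nuclei, live=live, caspase_positive=caspase,
        focus_counts=focus_counts, network=truth, dose_gy=dose)
    return MultiChannelField(channels=channels, pixel_size_um=ps,
                             truth=field_truth)


# ----------------------------------------------------------------------
# leakage time series
# ----------------------------------------------------------------------

class WindowAmbiguityError(ValueError):
    """The measuring window covers zero or more than one vessel segment."""


def render_leakage_series(truth: NetworkTruth, pd_true_um_s: float,
                          window: tuple[int, int, int, int],
                          config: SimulationConfig) -> TimeLapseSeries:
    """Forward-model a dextran leakage movie over a measuring window.

    The window-average intensity evolves linearly as
    ``I(t) = I1 + pd·(4/d)·(I1 − Ib)·t`` where ``I1`` is the initial window
    mean, ``Ib`` the background level and ``d`` the diameter of the single
    vessel crossing the window; the added intensity is laid out as an
    extravascular halo hugging the vessel wall so frames look like a real
    leak while the window mean obeys the closed form exactly (before noise).
    """
    if pd_true_um_s < 0:
        raise ValueError("pd_true_um_s must be >= 0")
    shape = config.image_size_px
    ps = config.pixel_size_um
    r0, c0, wh, ww = window
    if not (0 <= r0 and 0 <= c0 and r0 + wh <= shape[0]
            and c0 + ww <= shape[1] and wh > 0 and ww > 0):
        raise ValueError("window must lie within the frame")
    win = (slice(r0, r0 + wh), slice(c0, c0 + ww))

    hit = [s for s in truth.segments
           if rasterize_tubes([s], shape, ps)[win].any()]
    if len(hit) != 1:
        raise WindowAmbiguityError(
            f"window covers {len(hit)} vessel segments; need exactly 1")
    vessel = hit[0]
    d_um = vessel.diameter_um

    vessel_mask = rasterize_tubes([vessel], shape, ps)
    ib = config.background_intensity
    base = np.where(vessel_mask, config.vessel_intensity + ib, ib).astype(float)
    i1 = float(base[win].mean())
    if i1 <= ib:
        raise ValueError("window holds no vessel signal above background")

    halo = gaussian_filter(vessel_mask.astype(float), config.leak_halo_sigma_px)
    halo[vessel_mask] = 0.0
    win_mean = float(halo[win].mean())
    if win_mean <= 0:
        raise WindowAmbiguityError("window has no extravascular pixels")
    halo /= win_mean  # window-mean of halo is exactly 1

    slope = pd_true_um_s * (4.0 / d_um) * (i1 - ib)  # intensity / s
    times = np.arange(config.leak_n_frames) * config.leak_frame_interval_s
    rng = np.random.default_rng([config.seed, 0x6C6B])  # stage tag: leak
    frames = []
    for t in times:
        clean = base + slope * t * halo
        noisy = clean
        if config.read_noise_sd > 0:
            noisy = np.clip(clean + rng.normal(0.0, config.read_noise_sd,
                                               clean.shape), 0.0, None)
        frames.append(GrayImage(data=noisy, pixel_size_um=ps, channel="dextran"))
    return TimeLapseSeries(frames=frames, timestamps_s=times, window=window,
                           vessel_diameter_um=d_um, background_intensity=ib,
                           pd_true_um_s=pd_true_um_s)


def straight_vessel_truth(config: SimulationConfig,
                          diameter_um: float = 36.0) -> NetworkTruth:
    """A single horizontal vessel across the field — the standard leakage
    scene for permeability measurements."""
    h_um, w_um = config.domain_um
    pts = np.array([[0.0, h_um / 2.0], [w_um, h_um / 2.0]])
    seg = Segment(points=pts, diameter_um=diameter_um)
    return NetworkTruth(segments=[seg], domain_um=(h_um, w_um), dose_gy=0.0)
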