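"""Functional vessel assays: diffusive permeability, perfusion, regression.

Permeability
------------
With a circular vessel cross-section and negligible convection, the
diffusive permeability coefficient follows from the rise of window-averaged
tracer fluorescence:

    Pd = (1 / (I1 − Ib)) · ((I2 − I1) / Δt) · (d / 4)

where ``I1`` is the window-average initial intensity, ``Ib`` the background
fluorescence, ``I2`` the window average after ``Δt`` seconds, and ``d`` the
vessel diameter.  *Two-point* mode applies the formula to the first and last
frames exactly; *regression* mode (default) replaces ``(I2−I1)/Δt`` with the
least-squares slope of window mean versus time over all frames, which is far
less noise-sensitive.  Results are reported in both µm/s and cm/s
(1 µm/s = 10⁻⁴ cm/s).

Perfusion and regression fractions
----------------------------------
Perfused fraction = area(dextran ∩ vessel) / area(vessel): the share of
F-actin vessel area actually reached by tracer (low values mean lumen
blockage).  Regressed fraction = area(laminin \\ F-actin) / area(laminin):
basement-membrane sleeves left behind after endothelial regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from scipy.ndimage import distance_transform_edt

from .morphometry import skeletonize_mask
from .segment import BinaryMask
from .render import TimeLapseSeries


class UndefinedPermeabilityError(ValueError):
    """Initial window intensity does not exceed background."""


class UndefinedFractionError(ValueError):
    """Denominator mask is empty."""


class WindowDiameterError(ValueError):
    """The window does not isolate exactly one vessel branch."""


@dataclass
class PermeabilityResult:
    pd_um_s: float
    pd_cm_s: float
    i1: float
    ib: float
    slope_per_s: float
    diameter_um: float
    r_squared: float
    n_frames: int
    method: str
    flags: dict = field(default_factory=dict)


@dataclass
class FractionResult:
    numerator_um2: float
    denominator_um2: float
    fraction: float
    kind: str = ""


# ----------------------------------------------------------------------

def window_mean(data: np.ndarray,
                window: tuple[int, int, int, int]) -> float:
    r0, c0, h, w = window
    return float(data[r0:r0 + h, c0:c0 + w].mean())


def estimate_permeability(series: TimeLapseSeries, method: str = "regression",
                          diameter_um: float | None = None,
                          signal_floor: float = 0.0) -> PermeabilityResult:
    """Estimate Pd (µm/s and cm/s) from a leakage time-lapse.

    ``diameter_um`` overrides the diameter carried by the series.
    ``signal_floor``: minimum required I1 − Ib (e.g. 5× the expected noise
    SD); below it the estimate is refused as undefined.
    """
    if method not in ("two-point", "regression"):
        raise ValueError(f"unknown method {method!r}")
    d = series.vessel_diameter_um if diameter_um is None else diameter_um
    if d is None or d <= 0:
        raise ValueError("vessel diameter must be known and > 0")
    t = series.timestamps_s
    means = np.array([window_mean(f.data, series.window)
                      for f in series.frames])
    i1 = float(means[0])
    ib = float(series.background_intensity)
    if i1 - ib <= max(signal_floor, 0.0):
        raise UndefinedPermeabilityError(
            f"I1 ({i1:.3g}) does not exceed Ib ({ib:.3g}) by the required "
            f"floor ({signal_floor:.3g})")
    flags: dict = {}
    if method == "two-point":
        slope = float((means[-1] - means[0]) / (t[-1] - t[0]))
        r2 = float("nan")
    else:
        fit = sstats.linregress(t, means)
        slope = float(fit.slope)
        r2 = float(fit.rvalue ** 2)
    pd_um_s = slope / (i1 - ib) * d / 4.0
    if pd_um_s < 0:
        flags["low_signal"] = True  # negative estimate: noise-dominated
    return PermeabilityResult(pd_um_s=pd_um_s, pd_cm_s=pd_um_s * 1e-4,
                              i1=i1, ib=ib, slope_per_s=slope,
                              diameter_um=d, r_squared=r2,
                              n_frames=len(means), method=method, flags=flags)


def measure_window_diameter(mask: BinaryMask,
                            window: tuple[int, int, int, int],
                            prune_px: float = 5.0) -> float:
    """Vessel diameter (µm) in a window: 2 × mean distance-transform value
    over the skeleton pixels inside it.

    Requires the window to contain exactly one skeleton branch; otherwise the
    diameter is ambiguous and must be supplied by the caller.
    """
    graph = skeletonize_mask(mask, prune_px=prune_px)
    r0, c0, h, w = window

    def in_window(p):
        return r0 <= p[0] < r0 + h and c0 <= p[1] < c0 + w

    hit_edges = [e for e in graph.edges if any(in_window(p) for p in e.path)]
    if len(hit_edges) != 1:
        raise WindowDiameterError(
            f"window contains {len(hit_edges)} skeleton branches; supply the "
            "diameter explicitly")
    edt = distance_transform_edt(mask.data)
    vals = [edt[p] for p in hit_edges[0].path if in_window(p)]
    return float(2.0 * np.mean(vals) * mask.pixel_size_um)


# ----------------------------------------------------------------------

def _check_shapes(a: BinaryMask, b: BinaryMask) -> None:
    if a.data.shape != b.data.shape:
        raise ValueError("masks differ in shape")
    if a.pixel_size_um != b.pixel_size_um:
        raise ValueError("masks differ in pixel size")


def perfused_fraction(dextran_mask: BinaryMask,
                      vessel_mask: BinaryMask) -> FractionResult:
    """Share of vessel (F-actin) area reached by dextran.

    The numerator is the intersection, so extravascular tracer cannot push
    the fraction above 1.
    """
    _check_shapes(dextran_mask, vessel_mask)
    denom = vessel_mask.area_um2()
    if denom == 0:
        raise UndefinedFractionError("vessel mask is empty")
    num = float((dextran_mask.data & vessel_mask.data).sum()) \
        * vessel_mask.pixel_size_um ** 2
    return FractionResult(num, denom, num / denom, kind="perfused")


def regressed_fraction(laminin_mask: BinaryMask, factin_mask: BinaryMask,
                       denominator: str = "laminin") -> FractionResult:
    """Share of vasculature that has regressed: laminin-positive area not
    covered by F-actin, over total laminin area (or over F-actin area with
    ``denominator='factin'``)."""
    _check_shapes(laminin_mask, factin_mask)
    ps2 = laminin_mask.pixel_size_um ** 2
    num = float((laminin_mask.data & ~factin_mask.data).sum()) * ps2
    if denominator == "laminin":
        denom = laminin_mask.area_um2()
    elif denominator == "factin":
        denom = factin_mask.area_um2()
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise UndefinedFractionError(f"{denominator} mask is empty")
    return FractionResult(num, denom, num / denom, kind="regressed")
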