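"""Diffusive permeability from a dextran leakage movie.

Renders a 10-frame time-lapse (one frame every 10 s) of tracer leaking from
a single 36 µm vessel, then estimates the permeability coefficient

    Pd = (1 / (I1 - Ib)) * ((I2 - I1) / dt) * (d / 4)

both in strict two-point form (first and last frames) and by least-squares
regression of the window mean over all frames.
"""

from angioquant import (SimulationConfig, estimate_permeability,
                        render_leakage_series)
from angioquant.render import straight_vessel_truth

pd_true = 0.015  # µm/s ground truth
cfg = SimulationConfig(seed=5, image_size_px=(160, 160), read_noise_sd=10.0)
vessel = straight_vessel_truth(cfg, diameter_um=36.0)
series = render_leakage_series(vessel, pd_true, window=(40, 40, 76, 80),
                               config=cfg)

for method in ("two-point", "regression"):
    r = estimate_permeability(series, method=method)
    extra = "" if method == "two-point" else f"  R^2={r.r_squared:.4f}"
    print(f"{method:<11} Pd = {r.pd_um_s:.5f} um/s "
          f"({r.pd_cm_s:.2e} cm/s){extra}")
print(f"truth       Pd = {pd_true:.5f} um/s")
print(f"window I1 = {series and estimate_permeability(series).i1:.1f}, "
      f"Ib = {series.background_intensity:.1f}, d = "
      f"{series.vessel_diameter_um:.0f} um, {len(series.frames)} frames")
# At imaging noise around SNR 10 the regression estimate is typically within
# a few percent of truth; the two-point form, which uses only two frames, is
# noisier but reproduces the formula exactly on clean data.
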