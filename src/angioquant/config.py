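"""Simulation configuration for the synthetic vascular-field generator.

A single flat dataclass holds every knob of the generator: geometry of the
stochastic tip-growth process, rendering parameters (PSF, noise, channel
intensities), and the parametric dose-injury model.  Identical
``(seed, config)`` pairs produce bit-identical networks, images and truth
records.

Injury-model defaults are calibrated so that the simulated dose grid
0/4/8/16 Gy reproduces the dose-response endpoints reported for irradiated
microvasculature chips: permeability fold-increases of ~2.3/2.8/3.05,
γH2AX focus-count fold-increases of ~3.3/5.3/9.6, caspase-3 folds of
~2.2/5.2, viability falling from ~70% to ~36%, and roughly 40% of vessel
area still perfused at 16 Gy.  See docs/methods.md for the derivations.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass
class SimulationConfig:
    # --- reproducibility ---
    seed: int = 0

    # --- field geometry ---
    image_size_px: tuple[int, int] = (512, 512)  # (rows, cols)
    pixel_size_um: float = 1.0  # microscope magnification is not fixed by the assay; 1 um/px assumed

    # --- tip-growth network model ---
    sprout_count: int = 5
    step_length_um: float = 20.0
    n_steps: int = 40
    branching_prob: float = 0.08          # per tip per step
    branch_angle_deg: float = 55.0
    min_junction_angle_deg: float = 30.0  # rejected fusions below this incidence angle
    angle_jitter_deg: float = 12.0
    anastomosis_radius_um: float = 45.0
    min_branch_steps: int = 2             # steps before a tip may branch/anastomose
    min_tube_gap_um: float = 4.0          # enforced wall-to-wall clearance between distinct vessels
    max_segments: int = 200
    diameter_mean_um: float = 36.8        # day-7 chip average
    diameter_sd_um: float = 8.0
    diameter_range_um: tuple[float, float] = (5.0, 70.0)  # microvessel calibre range

    # --- rendering ---
    psf_sigma_px: float = 1.0
    read_noise_sd: float = 10.0           # additive Gaussian; vessel SNR ~ 10
    shot_noise_scale: float = 0.0         # variance per unit signal
    vessel_intensity: float = 100.0
    background_intensity: float = 40.0   # autofluorescence floor; keeps read noise off the clip rail
    nucleus_radius_um: float = 9.0
    nucleus_spacing_um: float = 30.0      # mean along-vessel spacing
    nucleus_intensity: float = 120.0
    focus_radius_px: float = 1.0
    focus_intensity: float = 200.0
    cell_body_radius_um: float = 9.0      # calcein cytoplasmic stain extent

    # --- leakage (permeability) forward model ---
    leak_frame_interval_s: float = 10.0
    leak_n_frames: int = 10               # t = 0, 10, ..., 90 s
    leak_halo_sigma_px: float = 8.0

    # --- dose-injury model (per Gy unless noted) ---
    dose_gy: float = 0.0
    pruning_rate: float = 0.05            # terminal branch removal, p = 1-exp(-rate*dose)
    shrink_rate: float = 0.02             # diameter factor exp(-rate*dose)
    regression_rate: float = 0.03         # segment regressed, Bernoulli(1-exp(-rate*dose))
    blockage_rate: float = 0.02           # segment blocked, Bernoulli(1-exp(-rate*dose))
    focus_baseline: float = 0.5           # foci per nucleus at 0 Gy
    focus_rate: float = 0.27              # extra foci per nucleus per Gy
    death_baseline: float = 0.30          # dead-cell probability at 0 Gy
    death_rate: float = 0.0412            # p_dead = 1-(1-baseline)*exp(-rate*dose)
    caspase_baseline: float = 0.08
    caspase_rate: float = 0.0288
    # permeability dose response: pd(dose) = pd0 * (1 + amp*(1-exp(-rate*dose)))
    pd0_um_s: float = 0.01
    pd_fold_amplitude: float = 2.043
    pd_fold_rate: float = 0.2563

    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if min(self.image_size_px) <= 0:
            raise ConfigurationError("image_size_px must be positive")
        if self.step_length_um <= 0:
            raise ConfigurationError("step_length_um must be > 0")
        if self.sprout_count < 1:
            raise ConfigurationError("sprout_count must be >= 1")
        if not (0.0 <= self.branching_prob <= 1.0):
            raise ConfigurationError("branching_prob must be in [0, 1]")
        lo, hi = self.diameter_range_um
        if not (0 < lo <= hi):
            raise ConfigurationError("diameter_range_um must satisfy 0 < lo <= hi")
        for name in ("pruning_rate", "shrink_rate", "regression_rate",
                     "blockage_rate", "focus_rate", "death_rate",
                     "caspase_rate", "dose_gy", "pd0_um_s"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("focus_baseline",):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("death_baseline", "caspase_baseline"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")

    # ------------------------------------------------------------------
    @property
    def domain_um(self) -> tuple[float, float]:
        """Physical field size (height, width) in µm."""
        return (self.image_size_px[0] * self.pixel_size_um,
                self.image_size_px[1] * self.pixel_size_um)

    def dose_permeability_um_s(self, dose_gy: float | None = None) -> float:
        """True permeability implied by the dose-response model, µm/s."""
        import math
        d = self.dose_gy if dose_gy is None else dose_gy
        return self.pd0_um_s * (1.0 + self.pd_fold_amplitude
                                * (1.0 - math.exp(-self.pd_fold_rate * d)))

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    # ------------------------------------------------------------------
    @classmethod
    def from_toml(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from a flat TOML key-value file.

        Unknown keys are preserved in ``extras`` rather than rejected, so
        pipeline-level settings can live in the same file.
        """
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)} - {"extras"}
        kwargs, extras = {}, {}
        extras.update(raw.get("extras") or {})
        for key, value in raw.items():
            if key == "extras":
                continue
            if key in known:
                if key in ("image_size_px", "diameter_range_um"):
                    value = tuple(value)
                kwargs[key] = value
            else:
                extras[key] = value
        return cls(extras=extras, **kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["image_size_px"] = list(self.image_size_px)
        out["diameter_range_um"] = list(self.diameter_range_um)
        return out
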