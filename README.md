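# angioquant

Quantitative image analysis for microvasculature-on-a-chip experiments, in
particular radiation-injury studies: HUVEC networks self-assemble in a
microfluidic chip, are irradiated (0–16 Gy), and everything we know about
the outcome comes from multi-channel fluorescence micrographs.  angioquant
turns those micrographs into numbers — and ships a ground-truthed synthetic
image generator so every stage of the analysis can be validated without
access to a microscope.

## What it measures

**Network morphometry** (from an F-actin channel): the binary vessel mask is
extracted by contrast enhancement → Otsu thresholding → Gaussian smoothing
(σ = 5 px) → small-object/hole cleanup, then thinned to a one-pixel
skeleton whose pixel graph gives the standard structural metrics —
vasculature area *A*, branch count, total branch length *L*, junction count,
effective diameter *d*<sub>eff</sub> = *A*/*L*, and maximum sprouting length
past a reference line.

**Diffusive permeability** (from a dextran time-lapse, one frame every 10 s
for 90 s): assuming a circular cross-section and no convection,

&nbsp;&nbsp;&nbsp;&nbsp;*P*<sub>d</sub> = (1/(I₁ − I_b)) · ((I₂ − I₁)/Δt) · (d/4)

with I₁ the initial window-average intensity, I_b the background, I₂ the
window average after Δt seconds and d the vessel diameter.  Both the strict
two-point form and a regression over all frames are provided; results are
reported in µm/s and cm/s.

**Perfusion and regression**: perfused fraction
= area(dextran ∩ F-actin)/area(F-actin) — the share of vessel lumen the
tracer actually reaches (low values mean blockage) — and regressed fraction
= area(laminin \ F-actin)/area(laminin), basement-membrane sleeves left
behind after endothelial loss.

**Cell damage**: nuclei segmentation (Otsu + distance-transform watershed),
γH2AX focus counts and areas per nucleus (white top-hat + relative
threshold), caspase-3-positive fraction, and calcein/EthD-1 viability,
summarized per dose with mean ± SD/SEM and unpaired two-tailed Student's
t-tests (stars at p < 0.05/0.01/0.001/0.0001).

**Synthetic generator**: stochastic tip growth with branching and
anastomosis produces vascular networks with known geometry; a parametric
injury model prunes, thins, regresses and blocks vessels dose-dependently
and sets per-cell focus counts, apoptosis and death probabilities.  Every
rendered field carries its full ground truth.

## Worked example

```bash
python examples/03_permeability.py
```

```
two-point   Pd = 0.01502 um/s (1.50e-06 cm/s)
regression  Pd = 0.01490 um/s (1.49e-06 cm/s)  R^2=0.9974
truth       Pd = 0.01500 um/s
window I1 = 87.4, Ib = 40.0, d = 36 um, 10 frames
```

A leakage movie was simulated with a true permeability of 0.015 µm/s at
imaging noise around SNR 10; both estimators recover it, the regression
estimate within 1%.  `examples/04_fractions_and_cells.py` does the same for
a whole irradiated field:

```
perfused fraction:  0.630 (truth 0.636)
regressed fraction: 0.325 (truth 0.326)
nuclei: 29 (truth 29)
gH2AX foci: 134 total, 4.62 per nucleus (truth 4.66)
viability: 0.34 (truth 0.34)
```

The other examples cover field simulation (`01`), skeleton morphometry
against ground truth (`02`), and the full dose-response pipeline with
statistics (`05`).

## Command line

A thin CLI wraps the same functions:

```bash
angioquant simulate --out fields/ --seed 3 --dose 8
angioquant mask --channel fields/field_s3_d8_factin.tif --out mask.tif
angioquant morpho --mask mask.tif --out metrics.csv
angioquant run --config study.toml --out report/
```

`run` executes simulate → segment → morphometry → functional assays → cell
assays → statistics for a whole dose grid and writes
`metrics_per_field.csv`, `group_summary.csv`, `comparisons.csv` and a
`provenance.json` sufficient to re-run bit-identically.

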