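# Methods

## Scope and coordinate conventions

All analysis is 2D, on projected/stitched single-channel images with a known
pixel size (µm/px).  The pixel size is not fixed by the assay; the default
is 1 µm/px and every length/area is reported in physical units so other
magnifications only require passing the correct pixel size.  Simulator
coordinates are (x, y) in µm with x rightward and y downward; pixel (r, c)
samples the point ((c+0.5)·ps, (r+0.5)·ps).  Image foreground is
8-connected throughout.

## Synthetic vascular fields

### Growth model

The generator is a stochastic tip-growth process: `sprout_count` sprouts
start on the left field edge (the medium-channel side) heading right; each
step a tip advances `step_length_um` with Gaussian heading jitter
(`angle_jitter_deg`, clipped at 2.5 σ and capped at 70° of total turning
per four steps so a tip cannot hairpin onto its own tube), may branch with
probability `branching_prob` (closing the parent polyline and spawning two
children ±`branch_angle_deg`/2 apart), and fuses with the first segment or
other growing tip that comes within `anastomosis_radius_um` — splitting the
target at the join vertex so that **segments are exactly the edges of the
truth graph**.  That identity is what lets branch and junction counts of a
skeletonized render be compared 1:1 against truth.

Several geometric guards keep the rendered geometry resolvable:

* fusions are rejected when the join would sit within 1.5 capture radii of
  the tip's own origin or of any existing node (junctions closer than ~2
  tube diameters would merge into one blob), or when the incidence angle is
  below `min_junction_angle_deg` (a tangential fusion is indistinguishable
  from the target itself);
* a tip that comes within `diameter_mean_um + min_tube_gap_um` of a tube it
  may not join retracts its last step and stops, so distinct vessels never
  blur together in the mask;
* tips die half a step before the right/top/bottom border (border-clipped
  half-tubes are not scoreable);
* after growth, terminal stubs too short to protrude past their
  neighbours' tubes (length < (r₁+r₂)/sin θ + 4 µm for the closest-angle
  neighbour θ) are removed, and degree-2 nodes left by stub removal or
  head-on fusion are contracted (or, if the two runs meet at a sharp
  corner, the shorter run is dropped — a kinked merge would rasterize as a
  junction blob).

Segment diameters are drawn from N(36.8, 8²) µm clipped to [5, 70] µm — the
day-7 mean calibre and the physiological microvessel range.  Truth metrics
(area as the shapely union of round-capped tube buffers, total centreline
length, degree census for junctions) are computed from geometry,
independently of any rasterization.

### Dose-injury model

Injury at dose D (Gy) is the simplest monotone dose-response family:

* every terminal branch is pruned with p = 1 − exp(−`pruning_rate`·D)
  (default 0.05/Gy);
* surviving diameters shrink by exp(−`shrink_rate`·D) (0.02/Gy), clipped to
  the calibre range;
* surviving segments are flagged **regressed** (basement membrane without
  endothelium; p = 1 − exp(−0.03·D)) or **blocked** (p = 1 − exp(−0.02·D)).

Tracer perfusion is reachability: dextran fills segments connected to the
left edge through open (non-blocked, non-regressed) vessels only.  The
blockage rate was fixed once so that the mean truth perfused fraction at
16 Gy is ≈ 0.40 (Monte Carlo over 30 replicates: 1.00/0.83/0.61/0.39 across
the dose grid), matching the observed near-40% perfusion of heavily
irradiated networks.

Cell-level injury: per-nucleus γH2AX focus counts are
Poisson(0.5 + 0.27·D), i.e. fold-changes of ≈ 3.2/5.3/9.6 at 4/8/16 Gy;
death probability is 1 − 0.70·exp(−0.0412·D) (viability 70% → 36% at
16 Gy); caspase-3 positivity is 1 − 0.92·exp(−0.0288·D) (folds ≈ 2.2/5.2 at
4/16 Gy).  The true permeability follows a saturating dose response
Pd(D) = Pd₀·(1 + 2.043·(1 − e^(−0.2563·D))) with Pd₀ = 0.01 µm/s
(≈ 10⁻⁶ cm/s, typical for 70 kDa dextran in such chips), giving folds of
2.31/2.78/3.01.  These coefficients were obtained by inverting the target
endpoints once, analytically; they are configuration, not claims about
mechanism.

### Rendering

Channels are ideal per-pixel masks (exact point-to-centreline distance
test, so a capsule's mask equals its analytic rasterization) degraded by a
Gaussian PSF (σ = 1 px) and additive read noise (σ = 10 at a vessel
intensity of 100 → SNR ≈ 10), on a background of 40 (an autofluorescence
floor; it also keeps the read noise away from the zero clip, which would
otherwise bias intensity statistics).  F-actin renders non-regressed tubes;
laminin all tubes; dextran perfused lumens; DAPI nuclear disks (radius
9 µm) placed along non-regressed centrelines with a 2.2-radius minimum
separation (nuclei never merge, so counts are recoverable); γH2AX foci are
small non-overlapping disks inside nuclei; calcein marks live cell bodies,
EthD-1 dead nuclei, NucView488 caspase-positive nuclei.  The clean masks
and per-cell labels are returned with the images as the truth record.

The leakage forward model renders the window-average intensity exactly as
I(t) = I₁ + Pd·(4/d)·(I₁ − I_b)·t by distributing the added signal over an
extravascular halo normalized to unit window mean, at t = 0, 10, …, 90 s.

### What the generator does not emulate

Uneven illumination, stitching seams, out-of-focus light from other z
planes, cell-shape texture inside vessels, tracer advection, photobleaching
and focus drift over the time-lapse, and segmentation-confusing debris.
Passing recovery tests on these images therefore validates the *logic and
numerics* of the measurement chain — not robustness to every real-world
artifact, which must be assessed on real data.

## Measurement chain

**Masking.**  Contrast enhancement clips the outer `saturated_fraction`/2
quantiles and rescales to [0, 1]; thresholding is Otsu by default (the
assay's own tool applies an unspecified threshold; a fixed value is
available for strict reproducibility); the thresholded mask is Gaussian
blurred (σ = 5 px, reading the "5-unit" blur as a sigma; the alternative
kernel-radius reading is accommodated by the exposed parameter) and
re-binarized at 0.5; components < 64 px are dropped and holes < 64 px
filled.  Blur-and-rebinarize acts like a curvature flow, so re-applying the
chain to its own output can still move ~1% of boundary pixels; the property
test asserts near-idempotence (IoU ≥ 0.98) rather than exact fixity.
Because Otsu always returns a threshold even on a signal-free channel
(splitting noise roughly in half, class separation ≈ 2.7 within-class SD),
the pipeline requires an Otsu class separation ≥ 4 SD before accepting a
channel as containing signal — a fully blocked field's dextran channel then
yields an empty mask rather than noise shreds.  The same guard protects
nuclei segmentation.

**Skeleton graph.**  scikit-image topology-preserving thinning, then a
hand-built pixel graph: degree-1 pixels are endpoints, degree-≥3 pixels are
junction pixels and 8-connected clusters of them collapse to one junction
node; edges are maximal chains with geodesic length 1 px per orthogonal and
√2 px per diagonal step.  Two artifact clean-ups, both standard in skeleton
analysis: spur edges < 5 px hanging off a junction are removed (with
re-thinning, since a pruned spur can leave redundant cluster pixels) and
junction–junction edges < 10 px are contracted (thinning a thick multi-way
joint leaves a small web that is physically one junction).  Both lengths
are parameters; 0 disables them, and pruned and unpruned counts are both
obtainable.

**Effective diameter** is area / total skeleton length (a mean-width
estimator; the metric's name is standard but its formula is rarely stated —
this definition is the natural one and is documented prominently).  An
alternative, 2× the mean distance-transform value over skeleton pixels, is
available via `diameter_method="distance_transform"`, and the same
estimator restricted to a window is how the per-window vessel diameter for
permeability is measured when not supplied.

**Permeability estimation** defaults to the regression slope over all
frames (two-point estimation uses 2 of 10 frames and is noise-dominated;
the two-point form is retained and reproduces the formula exactly).  I₁ is
the first-frame window mean; I_b is supplied or taken from a background
ROI.  A negative estimate is returned with a `low_signal` flag rather than
clamped.

**Fractions.**  The perfused numerator is the dextran ∩ F-actin
intersection so extravascular tracer cannot push the fraction above 1.  The
regressed denominator is the laminin area (total vasculature ever formed);
the F-actin denominator is available behind a flag, since only the
numerator is dictated by the assay's definition.

**Cells.**  Nuclei: Gaussian blur (σ = 2 px) → Otsu → distance-transform
watershed seeded at EDT peaks ≥ 5 px apart → area ≥ 30 px.  Foci: white
top-hat (disk radius 5 px) → threshold at 0.5× the maximum in-nucleus
top-hat response → 8-connected components inside nuclei; counts are
reported per nucleus, per field and per mm².  Positivity: a cell is
positive when its background-subtracted mean signal exceeds 0.3× the
field's robust dynamic range (99.5th percentile minus median) — invariant
to affine intensity rescaling.  Viability defaults to live/(live + dead)
over cells classified by either stain, with cells bright in both called
dead; normalization by all counterstained nuclei is available behind a
flag.  Whether real counts were normalized per nucleus or per field area is
not derivable from the assay description, so both are emitted.

## Statistics and the pipeline

Replicates are fields (one field = one replicate; whether published "n"
means fields, chips or cells is not stated, and this choice is documented
rather than guessed).  Groups are summarized as mean ± sample SD (n−1) with
SEM alongside; comparisons use the unpaired two-tailed pooled-variance
Student's t (Welch behind a flag); stars at p < 0.05/0.01/0.001/0.0001
with no multiple-testing correction by default (Holm available), matching
per-comparison starring conventions.

The pipeline's dose groups are **matched replicates**: the per-field seed
depends on the field index but not the dose, so each simulated chip is
grown once and injured at every dose with common random numbers.  This is
the standard variance-reduction coupling for simulation dose-response
studies — contrasts measure the injury model, not between-network growth
variability.  (In independent sampling the same expectations hold, but at
10 fields per dose the between-network noise in branch counts is comparable
to the 4-vs-8 Gy contrast.)  Permeability is measured per chip on a
dedicated straight-vessel leakage window (d = 36 µm), mirroring how leakage
movies are acquired over a single vessel.

Problem sizes: default fields are 512×512 px at 1 µm/px with 5 sprouts;
the dose grid runs 10 fields per dose at 0/4/8/16 Gy; leakage scenes are
160×160 px.  Ground-truth recovery tests use sparse noiseless networks
(≤ 20 segments, 9 µm tubes, 384×384 px) where exact branch/junction
recovery is geometrically well-posed.

## Numerical and degenerate-input choices

Empty masks yield zero metrics, not exceptions; an empty denominator mask
raises a typed `UndefinedFractionError`; I₁ ≤ I_b raises
`UndefinedPermeabilityError`; a window covering zero or several vessels
raises an ambiguity error telling the caller to supply the diameter.  Zero
pooled variance in a t-test returns p = 1 (equal means) or p = 0 with a
`degenerate` flag.  Effective diameter on a zero-length skeleton with
nonzero area is flagged undefined.  All simulator randomness flows from a
single integer seed through per-stage child streams; identical
(seed, config) gives byte-identical images, truth records and CSVs.

## Known limitations

2D projection only (no z-stack lumen reconstruction); no flow or
advection; injury flags are independent Bernoulli draws per segment (no
spatial correlation of damage); nuclei placement avoids overlaps, so
clumped-nuclei splitting is exercised only lightly; skeleton length runs a
few percent short of truth centreline length because thinning insets free
ends by about one tube radius; discrete thinning is not exactly
rotation-equivariant (counts survive 90° rotation exactly, geodesic lengths
to ~1%).
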