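# Methods

This note documents the models, estimator conventions, synthetic-data
assumptions and numerical choices behind the package. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Perfusion slope cartography

The inflow of a fluorescent dye bolus is summarized per pixel by the slope

    slope = (I_peak − I_baseline) / t_peak    [1/s, normalized units]

where `I_baseline` is the mean of the first 5 (unsmoothed) frames, the curve
is smoothed by a centered moving average (default window 5 frames, shrinking
at the edges), `I_peak` is the smoothed maximum and `t_peak` the time of the
*first* frame attaining it. "First attainment" is deterministic and matches
the time-to-reach-maximum semantics; a relative guard of `1e-9·|I_peak|`
protects the tie-break against cumulative-sum rounding on flat plateaus,
which would otherwise push the detected peak arbitrarily far into the
plateau. Pixels whose smoothed rise above baseline stays below `min_delta`
(default 0.02 in normalized units — background and reference-card pixels)
or that peak in frame 0 are invalid, not errors. Frame 0 of the stack is
taken as the injection time; no bolus-arrival detection is attempted.

Reference normalization divides each frame by that frame's mean intensity
over the reference-card mask. This cancels any per-frame multiplicative
factor — distance attenuation, illumination drift — which is why the
synthetic generator models attenuation as a single scene-level factor
rather than per-pixel depth: the normalization contract
`slope(k·video) = slope(video)` is asserted as a test, and a per-pixel
depth field would be invisible to every downstream quantity anyway.

The vectorized cartography and the scalar per-pixel path share one code
path (a cumulative-sum moving average applied along the time axis), so the
map equals a brute-force per-pixel loop bit-exactly; this equivalence is a
test, not an assumption.

Absolute slope values depend on an arbitrary intensity unit and are treated
as such: only orderings, ratios and correlations are asserted anywhere.

## Zone classification

Manual region annotation is replaced by StO2 thresholds: ischemic below
33%, vital at or above 63%, transition in between, each mask cleaned by
small-object removal (default minimum 16 px). The defaults are the
midpoints between the per-zone reference StO2 means (76.5 / 48.8 / 16.5%).
An empty class after cleanup is a hard error naming the class, since every
downstream per-zone statistic would otherwise silently degenerate.

## Moving-least-squares registration

For an evaluation point v the affine map minimizing
`Σ_i w_i |A(p_i) − q_i|²` with `w_i = 1/|p_i − v|^(2α)` (default α = 1) is
solved in closed form from the weighted centroids and a 2×2 normal matrix.
Distances are floored at 1e-8 px, and evaluation points within 0.5 px of a
source landmark inherit that landmark's exact displacement — the
interpolation limit of the weights. Near-collinear source configurations
(smallest singular value of the centered points below 1e-6 of the largest)
are rejected as degenerate.

Warping is backward: the map built from the reversed pairs gives, for each
target pixel, its source-space position; sampling is bilinear and target
pixels mapping outside the source grid are flagged invalid. The dense field
is evaluated on a coarse grid (default every 4 px) and bilinearly
upsampled; because an affine field is linear in v, this is *exact* for any
globally affine deformation, which the tests exploit. The affine MLS
variant was chosen as the simplest member of the family that already
reproduces global affine motion exactly; similarity/rigid variants would
only constrain the deformation further without changing any tested
property.

## Capillary density index

Segmentation is a fixed minimal operator chain: Gaussian blur (σ = 1), Otsu
threshold restricted to the circular field of view, connected components
filtered by elongation (major/minor axis ratio ≥ 3) and area (≥ 50 px²),
centerline by morphological thinning, per-point diameter as twice the
Euclidean distance transform at skeleton pixels. Skeleton length counts
axial neighbor steps as 1 and diagonal steps as √2, skipping diagonals that
shortcut an existing axial pair. The index is

    FCD-A = mean diameter × total length / FOV area,

with the mean diameter weighted by skeleton length (the mean over skeleton
pixels), and is reported per frame; a region's value is the mean over its
frames. The reported per-zone magnitudes (0.26 / 0.247 / 0.122) come from a
vendor tool with unstated normalization, so phantoms are calibrated to
reproduce those values *by construction* (chord layouts whose analytic
`d·L/πr²` hits the target) and the tests assert recovery of the analytic
value, ratios and orderings — not agreement of the original software.

Vessel phantoms are rasterized with a pixel-footprint convention: a tube of
diameter d centered on an integer row occupies exactly d pixel rows
(threshold at (d−1)/2 between pixel centers), which makes the
distance-transform diameter estimator unbiased on axis-aligned tubes.

## Lactate models and statistics

Normalized LCL is `LCL − systemic lactate`, kept as-is when non-positive.
The calibration `y ≈ exp(−a·x + b)` is fitted by Levenberg–Marquardt on the
raw scale (the objective is the raw-scale squared error), initialized from
a log-linear fit on `max(y, 1e-3)`; non-positive y values therefore enter
the fit but not the initialization. A log-scale fit is available behind a
flag. Up to 5 perturbed restarts precede a fit-failure error carrying
diagnostics. Cross-validation leaves one *subject* out (all of its regions
together), matching the experimental unit.

The error summary reports mean/SD/median of held-out absolute errors plus
`q95_threshold`, implemented as the 95th percentile (linear interpolation)
of the observed LCL values carrying the errors; the phrase "95% of errors
occur below an LCL of X" admits other readings, so this interpretation is
documented rather than asserted against any external number.

The paired Wilcoxon signed-rank test drops zero differences, uses average
ranks, and computes the exact null by convolution over sign assignments for
n ≤ 25 (average ranks are doubled onto an integer grid), switching to a
tie-corrected normal approximation beyond; all differences equal to zero
yield p = 1 by convention. Spearman correlation and its t-approximation
p-value are delegated to scipy. The sample-size formula is the Fisher-z
method, `n = ⌈((z_{1−α/2}+z_{power})/C)² + 3⌉` with `C = ½ln((1+r)/(1−r))`;
it reproduces the anchor value n = 13 at r = 0.78, α = 0.05, power = 0.9
and is cross-checked against a simulated power search in the tests.

## Synthetic-data generator

The generator emulates the study conditions, not optical physics:

- **Zones.** StO2 ~ Normal per zone with means/SDs 76.5 ± 6.0, 48.8 ± 8.1,
  16.5 ± 4.76%, clipped to [0, 100]. Per-zone slope draws use the reported
  6.79 ± 4.43, 5.67 ± 4.93, 0.94 ± 0.6 (truncated positive). Inflow timing
  has no published anchor; defaults are delay/time-to-peak of 2/8 s
  (vital), 3/14 s (transition), 6/30 s (ischemic) with peak intensities
  120/90/35 — fast filling in vital tissue, slow collateral trickle in
  ischemic tissue — chosen once as plausible bolus kinetics.
- **Inflow curve.** A logistic rise rescaled to hit 0 at the delay and 1 at
  the time-to-peak exactly, then a flat plateau: monotone, smooth, with an
  unambiguous analytic first-maximum for tests. The slope metric depends
  only on peak timing and height, not on the curve family.
- **Video.** 40 s at 25 fps by default; constant reference card (intensity
  50), one global attenuation factor, additive Gaussian noise (SD 1
  intensity unit), background level 2.
- **Cohort.** One systemic lactate per subject ~ Normal(1.87, 0.869)
  truncated positive; per region,
  `LCL = exp(−a·x + b)·exp(ε) + systemic` with the StO2 model
  (a = 0.0343, b = 2.72) as the default generator (the slope model
  a = 0.403, b = 2.32 selectable), and ε ~ Normal(0, 0.3) on the log scale —
  multiplicative log-normal noise keeps lactate positive.
- **Confocal phantoms.** Straight-chord tubes of known diameter/length in a
  circular FOV (radius 120 px, diameter 6 px by default), with analytic
  length, diameter, area and density index as ground truth.

All randomness flows through one explicitly seeded `numpy.random.Generator`
per call; identical parameters and seed give bit-identical outputs.

What the generator does **not** emulate: photon transport and spectra,
breathing/motion artifacts, laparoscope distortion, fluorescein pooling,
per-pixel depth variation, spatial StO2 autocorrelation, or inter-subject
kinetic variability. Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to every
artifact of real intraoperative data.

## Problem sizes and determinism

Default scenes are 96×129 px (1000 frames at 25 fps), cohorts 6 subjects ×
3 regions, Monte-Carlo checks 200–500 replicates, and the parameter-recovery
study 60 subjects × 200 replicates — sizes at which every acceptance
property is stable while the whole suite and the acceptance script each run
in well under a minute on a laptop-class machine. End-to-end reports are
reproducible bit-identically from config + seed, and each report embeds a
hash of its configuration.

## Known limitations

- Slope values are in normalized units per second; absolute comparability
  across instruments is out of scope.
- The segmentation chain is tuned for tube-like phantoms; real capillary
  beds with crossing or leaking vessels would need a dedicated detector.
- The exact-Wilcoxon convolution is quadratic in the summed ranks and
  restricted to n ≤ 25, past which the normal approximation takes over.
- The 18-record default cohort makes the small-sample statistics
  (correlation magnitudes, Wilcoxon p) strongly seed-dependent; only signs
  and orderings are stable at that scale.
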