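# Methods

## The measurement chain

The package models a longitudinal rat AVF study sampled at days
{−1, 1, 3, 7, 14, 21, 42, 84}, where day −1 codes the sham (pre-fistula)
controls and day 0 the moment of fistula creation. Three measurement arms
share this grid:

* a hemodynamic arm (6 rats/day) with pulsatile flow recordings,
* an immunofluorescence (IF) arm (4 rats/day) with marker / primary-control
  image pairs,
* a PLA arm (4 rats/day) with spot-field z-stacks and matched negative
  controls.

### Wall shear stress

Shear is estimated with the Poiseuille relation τ = 4ηQ/(πR³). Pulsatile
traces are reduced to their trapezoidal time-average before the formula is
applied: transit-time flow probes report mean flow, and one shear value per
session is what the time-course statistics consume. Womersley decomposition,
oscillatory shear indices and turbulence are out of scope. Blood viscosity
defaults to η = 0.04 dyn·s/cm² (4 cP, typical rat whole blood) and is
configurable; because synthetic vessel radii are obtained by *inverting* the
same relation against the target shear trend, the default cancels in every
calibrated recovery.

### FIU quantification

Marker expression is the mean gray value of an ROI on the maximum-intensity
projection, minus the same measurement on the specimen's primary-antibody
control ("corrected FIU"). Subtraction (not a ratio) is the default because
the correction is an additive background in the image-formation model; a
ratio mode exists behind a flag. Negative corrected values are retained and
flagged, never clamped — clamping would bias group means upward.

### PLA event calling

Z-stacks are max-projected; pixels ≥ 100 gray values (8-bit) form the signal
mask; 8-connected components are extracted (4-connectivity available).
Components below 2 px are discarded. A component of 2–50 px is one
interaction event; a larger blob is a merger contributing
`round(area / 10)` events (ties round up; a fractional mode exists for
sensitivity analysis). Sizes are pixel *areas* throughout: an area reading
is the only one under which the 2–50 gate, the median event size of 10 px
and the area/10 rule are mutually coherent. Densities are events per mm² of
ROI, averaged over the three ROIs of a compartment, and corrected by
subtracting the same-specimen negative-control density measured with
identical rules. Components are labeled on the full image and assigned to
the ROI containing their centroid — clipping components at the ROI edge
would contradict the centroid-assignment convention and truncate the areas
of boundary spots.

### ROI geometry

Six ROIs per image: three polygon bands hugging the lumen boundary and
extending round(5 µm / pixel size) px into the tunica intima (the
endothelium), and three circles centered on the local mid-media radius, all
at 120° spacing from a caller-chosen angular anchor. The anchor is an
explicit parameter rather than an orientation estimated from the
segmentation: on near-circular vessels an estimated orientation is
ill-defined, while an explicit anchor makes the engine exactly rotation-
equivariant. ROI areas are checked against configurable bounds. The
protocol's stated 0.5–1.0 mm² range cannot be realized by a 5-µm-deep band
around any single vessel profile (it would require a ~10 cm lumen
perimeter; the original range evidently refers to ROIs enveloping many
nidus vessel profiles at low magnification), so the bounds default to the
protocol values only for imported hand-drawn ROIs and are phantom-scaled
inside the synthetic pipeline.

### Statistics

Groups are summarized as mean ± SE (SE undefined and flagged at n = 1; the
time-course layer refuses n < 2). Baseline comparisons use the pooled
two-tailed unpaired t-test (Welch behind a flag). With ≥ 3 groups, Levene's
test (center = median, α = 0.05) gates between one-way ANOVA (variances
equal) and pairwise two-sided Mann–Whitney tests against baseline.
Correlations are Pearson r on per-day *group means* (n = number of days),
with two-tailed p from the t transform and optional least-squares slope and
intercept; shear- and flow-vs-time correlations use days 0–42 (the rising
limb), measure-vs-time correlations use the post-formation days, and
measure-vs-shear correlations use all shared days. No multiple-testing
correction is applied by default (a Holm helper is provided).

## The synthetic study generator

### Calibration

The generator's defaults are the study conditions:

* flow: 5.2 mL/min carotid baseline; ×2.4 at day 0 (the +140% jump at
  fistula creation); linear rise to 11× the day-0 fistula flow at day 42;
  flat to day 84;
* shear: linear from 3.5 dyn/cm² (day 0) to 46 dyn/cm² (day 42), flat to
  day 84. The day −1 baseline keeps the day-0 radius, so baseline shear is
  3.5 × (5.2/12.48) ≈ 1.46 dyn/cm². Radii solve R = (4ηQ/(πτ))^(1/3)
  against the noise-free day-mean flow, so the forward computation
  reproduces the trend exactly at zero replicate noise, and the reported
  day-42/day-0 fold is the computed 46/3.5 ≈ 13.1;
* marker effects (percent change of endothelial expression vs baseline):
  anchored at the printed values — caspase3 +10% (day 1) peaking at +35%
  (day 42); Notch1 +81% at day 3, sustained; Notch4 +45% at day 21 after a
  3-week delay; Delta1/Delta4 peaking day 84 at +61%/+74%; Jagged1
  responding two weeks earlier and peaking day 42 at +58%; Hes1 +64% at
  day 42; CD31 flat. Days between anchors interpolate monotonically;
* interaction effects (percent change of PLA event density): Notch1–Delta1
  +23% at day 84; Notch1–Delta4 +31% at day 42; Notch1–Jagged1 +22% at
  day 84; Notch4–Delta4 and Notch4–Jagged1 rising from day 3 into the
  +21–35% range; Notch4–Delta1 a steady time-correlated rise. Effects apply
  to both wall compartments (receptors and ligands are expressed in
  endothelium and media); analyses read the endothelium.

Replicate (rat-to-rat) variation is one multiplicative lognormal factor per
specimen with CV 0.05, applied to the flow mean, the marker levels and the
PLA rates. Pulsatility is a 6 Hz sinusoidal modulation (amplitude 0.3)
sampled over whole cycles.

### Phantom images

A specimen is an 8-bit z-stack of a concentric lumen/intima/media
cross-section. The IF phantom images one dilated vessel (lumen radius
360 µm) at 1 µm/px in a 1024² field; the PLA phantom images a larger vessel
(radius 400 µm, intima 10 µm) at 0.5 µm/px in a 2048² field — PLA is
acquired at higher magnification, and the finer pixel grid gives the 5-µm
endothelial band enough area (~570 expected events per specimen at
baseline) for stable counting statistics. Both use 6 slices × 2 µm = 12 µm
of z.

Marker channels are annuli of mean gray = background (20) + level, with
Gaussian read noise (σ = 5) per slice; the primary-control image is the
same specimen at level 0, so control subtraction removes both the
background and the projection's max-of-noise offset exactly in expectation.
Doubling a marker level doubles the background-subtracted ring signal.

PLA channels scatter discrete spots: per compartment, N ~ Poisson(rate ×
area) true events, each a connected blob of exact pixel area drawn from a
discretized lognormal (median 10 px, σ_log = 0.45, truncated to 2–50 px so
an isolated spot never trips the merge rule), stamped into one random z
slice with pixel values ≥ 120 over a noisy background (mean 30, σ = 8,
never reaching the threshold). Isolated spots keep a ≥ 2 px Chebyshev gap
(enforced by a dilated occupancy mask), so they never merge by accident and
noise-free counting is exact — verified against ground truth over hundreds
of phantoms. A configurable fraction (default 0.10) of events is placed as
overlapping clusters whose union exceeds 50 px, exercising the area/10
path; cluster unions recover ~60% of their member events under that rule,
a density-independent shortfall of ~4% of all events that cancels in
percent changes. Negative controls carry only the nonspecific rate
(400 events/mm², also added to the signal channel), so background
subtraction is exercised end to end. Placement raises a descriptive error
when a requested rate cannot fit.

One root seed drives everything; each (arm, name, rat, day) gets an
independent stream via CRC-32-keyed `SeedSequence` spawning, so adding an
arm never perturbs existing images, and identical (profile, seed) yield
byte-identical datasets.

### What the phantoms do not emulate

Real confocal data have spatially varying illumination, optical blur and
bleed-through, irregular (non-annular) vessel geometry, autofluorescence
texture, section-to-section registration differences, and PLA spots with
diffraction-limited intensity profiles rather than uniform-bright blobs.
Passing recovery tests therefore demonstrates that the *measurement rules*
are implemented correctly and are unbiased under known ground truth — not
that the rules are robust to those real-data artifacts.

## Sampling error of the calibrated recoveries

A percent change estimated from 4-rat group means with per-specimen CV
0.05 has, by the delta method, SE ≈ 100·(1+f)·0.05·√2/2 ≈ 4.8 points at
f = 0.35 and ≈ 6.4 at f = 0.81; the PLA recovery adds a Poisson counting
term (≈ 570 events/specimen) giving ≈ 5.7 points at f = 0.23. Empirically,
across independent seeds the PLA estimator is centered on the true effect
with a seed-to-seed spread somewhat above the delta-method figure (the
ratio-of-small-group-means estimator is heavier-tailed than its linearized
approximation). These magnitudes are the irreducible sampling error of the
study design itself — a 4-rat-per-day design cannot pin a +23% effect much
tighter than ±10 points — and the acceptance tests therefore check recovery
at two delta-method SEs. The problem sizes used by the test suite (reduced
256² phantoms for properties, full-scale phantoms for the calibrated
recoveries) were chosen so the whole suite exercises every path at full
fidelity where it matters.

## Numerical and design choices

* 8-bit images and a fixed threshold of 100: a fixed gray threshold is only
  portable on a known intensity scale; both are configurable.
* Merged-event rounding: nearest integer, ties up; fractional mode for
  sensitivity analysis.
* Geometry inversion sanity window: calibrated radii must fall in
  0.01–0.5 cm.
* Percent changes against a non-positive baseline mean are reported as NaN
  rather than raised mid-pipeline.
* Degenerate two-group tests (both variances zero) return t = 0, p = 1 when
  means agree and p = 0 otherwise rather than NaN.
* The IF and PLA arms are independent rat sets (no cross-arm pairing), and
  the per-compartment density is the mean of its three per-ROI densities
  (pooling counts over ROIs is the obvious alternative; with near-equal ROI
  areas the two differ negligibly).
* Statistics in the orchestrated run are always computed from the saved CSV
  tables, so an isolated re-run of the stats stage reproduces the report
  byte for byte.

## Known limitations

Single-vessel annular phantoms only; no hand-drawn ROI *drawing* UI (import
of polygon/circle geometry is supported); the Mann–Whitney branch reports
unadjusted pairwise p-values (headline p is their minimum); densities are
2-D (per max-projected mm²), not per volume; the pipeline is single-process.
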