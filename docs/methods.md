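# Methods

This note documents the models, estimators and numerical choices behind
`smstoich`, and what the simulator-based validation does and does not show
about real data.

## The measurement model

A surface-immobilised fluorescent molecule appears as a diffraction-limited
spot whose intensity decreases in discrete steps as its fluorophores
photobleach irreversibly. If every subunit carries (on average) f̄
fluorophores of unit brightness I_step, the molecule's initial intensity is
proportional to its subunit count, and

  subunits = (I_initial / I_step) / f̄

estimates that count. I_initial is the mean of the first 20 frames of the
background-corrected trajectory (trajectories shorter than 20 frames are
rejected); I_step is the median over a cohort of the sizes of *final*
bleaching steps — the last drop to baseline is the one drop guaranteed to
come from a single fluorophore; f̄ is measured on a denatured-monomer
control as the mean number of detected bleach steps per molecule.

Two biases are inherent to the estimator and deliberately left in place:
fluorophores that bleach inside the 20-frame window depress I_initial by
roughly 9.5 × (per-frame bleach hazard), and the median of a lognormal
step-height distribution with CV 0.2 sits ~2% below its mean. Both are
small at realistic hazards (≲ 0.005/frame) and partially cancel; the
recovered-vs-true regression slope of ~0.97 measured on simulated cohorts
reflects them.

## Synthetic data

The generator emulates an EMCCD TIRF acquisition: 160 nm pixels, 0.5 s
exposure, 600–1000 frames per stack (defaults; all configurable).

* **Photobleaching**: each fluorophore's bleach frame is geometric with a
  per-frame hazard (continuous-exposure integration within a frame is not
  modelled; at 0.5 s frames the error is sub-frame timing only).
* **Brightness**: per-fluorophore step heights are lognormal with mean
  `i_step_mean` and CV `i_step_cv` — strictly positive, with the right-
  skewed shape observed in measured step-height distributions.
* **Noise**: Poisson shot noise on the total signal plus Gaussian read
  noise. EM-gain excess noise is not modelled; it would inflate the
  effective shot noise by ~√2 without changing any estimator's structure.
* **Blinking**: a two-state telegraph process per fluorophore, off by
  default — the counting method assumes monotone staircases, and blinking
  is an opt-in stress test.
* **Rendering**: spots are integrated Gaussian PSFs (error-function pixel
  integrals, truncated at 5σ, < 0.1% flux loss); complexes are one spot per
  channel at the same (transformed) position; a minimum-separation
  parameter (default 4 × PSF σ) prevents partial PSF overlap between
  distinct molecules. Spot density per field is kept low enough that fewer
  than 1% of placements violate the separation threshold; violations are
  counted in the manifest.
* **Labelling**: fluorophores per monomer are drawn i.i.d. per subunit from
  a discrete distribution (e.g. {1: 0.5, 2: 0.5} for a protein with two
  reactive cysteines).
* **Populations**: a preset defines, per incubation timepoint, the fraction
  of clients in complexes and the size distributions. Subunit counts are
  discretised lognormals; a complex's chaperone count is its client count
  times a lognormal ratio whose median is the preset's molar-ratio median,
  so the true median ratio is recovered by construction (used to verify
  the summarisation machinery independently of the imaging chain). The
  `aBc-FLUC` preset's ratio median rises 0.08 → 2.5 over one hour and
  `Hsp27-rhodanese` rises 0.15 → 0.67 over seven hours, matching the
  behaviour the pipeline is meant to resolve; the interior timepoints are
  monotone interpolations. The `negative-control` preset has no true
  complexes.
* **Alternate excitation**: when enabled, channel B bleaches in the first
  half of the stack and channel A in the second, mirroring the
  alternate-excitation scheme used to avoid FRET between channels;
  counting always operates on a trajectory's own bleaching frame range.
* **Coordinates** are 0-based pixels; a position is a continuous centre
  with pixel (0,0) spanning [0,1)².

What passing simulator tests does **not** show: robustness to stage drift,
non-uniform focus, EM-gain excess noise, spectral cross-talk, aggregated
fluorescent impurities, or surface-immobilisation artefacts. The
synthetic populations also make independence assumptions (labelling i.i.d.
per subunit, molecules placed independently) that real samples may violate.

## Change-point detection

Default: exact penalised least squares. For a trace x₁…xₙ the segmentation
minimises the within-segment sum of squares plus β σ̂² log n per change
point, solved exactly by O(n²) optimal-partitioning dynamic programming.
σ̂ is a robust noise scale from the median absolute deviation of first
differences (divided by √2; steps are sparse outliers there). β = 4 was
calibrated on simulated traces so that the false-step rate on step-free
segments stays below 2% at SNR 8 (measured 0/1000 constant traces at
n = 300). This formulation admits a brute-force oracle — enumeration of
all change-point sets up to size 4 with vectorised segment costs — which
the tests use as the module's primary correctness anchor: the DP agrees
with the enumeration in ≥ 99% of 500 random short traces, and the rare
disagreements are cases where the DP finds a strictly better solution
with more change points than the enumeration cap.

Alternative (`method="bayes"`): offline Bayesian change-point detection
under a Gaussian observation model with a Normal–Inverse-Gamma conjugate
prior (κ₀ = 0.01, a₀ = 2, b₀ matched to the robust noise scale, prior mean
at the trace median). The same DP minimises negative log marginal
likelihood with a log-odds penalty equivalent to a 1/n change-point hazard.
Both methods coincide on clear staircases; least squares is the default
because its oracle is exact.

Noiseless traces (σ̂ = 0) are segmented exactly at every value change. A
trace must end in a baseline segment whose mean is within 3σ̂ of zero to
contribute a final step; incomplete bleachers are flagged, excluded from
I_step estimation, but still counted (acquisitions run until ~90% of
molecules bleach, so a minority of incomplete traces is expected).

## Trajectory classification

Real pipelines of this kind filter trajectories with a neural network
trained on manually labelled traces. Manual labels are not reproducible, so
training labels here come from the simulator: clean staircases versus four
engineered artefact classes (flat noise, smooth monotone drift,
non-bleaching constant, erratic random-walk). Two interchangeable filters
satisfy the same ≥ 95% validation-accuracy requirement:

* a gradient-boosted classifier over 12 shape features of the resampled
  (length 100), range-normalised trace — monotone trend, step contrast,
  number of change points, largest up/down step ratio, baseline level, and
  a smooth-versus-staircase discriminant;
* a rule-based fallback using the same features with fixed thresholds.

The discriminant that separates staircases from smooth drifts compares the
segmentation's residual with the best smooth monotone fit (straight line or
exponential decay): a genuine staircase beats the smooth model by an order
of magnitude in residual, a drift does not. Both filters accept
incomplete bleachers. Traces shorter than 25 frames are rejected outright.

## Registration, detection, photometry

* Spot detection runs on the average of the first 10 frames (molecules are
  brightest pre-bleach): difference-of-Gaussians band pass (σ 1.0/2.0),
  maxima above 5 robust SDs of the filtered image, sub-pixel refinement by
  background-subtracted centroid (Gaussian least-squares fit for beads),
  duplicate maxima within 3 px collapsed to the brighter.
* The channel transform is fitted by least squares over bead centroids
  matched by mutual nearest neighbour; the default model is affine
  (translation/rotation/scale/shear of split-channel optics), with
  similarity and translation available. Minimum matched beads: 3/2/1.
* Photometry: per frame, the sum over a circular aperture (default radius
  3 px) minus aperture-area × median of an annulus (5–8 px). The annulus
  median is robust to neighbouring spots. A 3 px aperture captures ~98% of
  a σ = 1.1 px PSF; the constant capture fraction cancels exactly in
  I_initial/I_step, so no aperture correction is applied. Spots whose
  annulus leaves the field are excluded with a border flag.

## Colocalisation

Chaperone spots are mapped into the client frame through the inverse
channel transform and paired one-to-one by mutual nearest neighbour within
2 px (≈ 320 nm) — a complex is one spot per channel, so all-neighbour
matching would overcount. Chance coincidence is estimated per field by
rotating the mapped chaperone coordinates 180° about the field centre
(x → W−1−x, y → H−1−y) and re-matching; the chance fraction is subtracted
from the raw colocalised fraction and clamped at zero. Correction is
applied per field, then averaged per replicate. On simulations the
corrected fraction is unbiased to within Monte-Carlo error at densities
≤ 0.002 spots/px², and a zero-complex control stays below 3%.

## Statistics

* Size-distribution comparisons: Kruskal–Wallis with tie correction,
  followed by Dunn's pairwise z-tests on pooled mean ranks with the usual
  tie term. The multiplicity adjustment is Holm by default (family-wise
  control without independence assumptions); Bonferroni and none are
  options. Dunn's procedure is implemented in-package and cross-checked in
  the tests against an independent rank computation.
* Colocalised versus non-colocalised sizes over time: two-way ANOVA
  (state × timepoint, type-II sums of squares) on log₁₀ subunit counts —
  sizes are lognormal-like, and log-scale is how such distributions are
  compared — with Tukey HSD between states within each timepoint. Cells
  with fewer than 2 observations raise an error naming the cell.
* The standard error of a median is a seeded 1000-resample bootstrap.
* Subunit counts are carried as continuous values for ratio statistics;
  the rounded (half-up, floored at 1) integer count is a derived
  convenience only.
* Both batteries are calibrated: type-I error at α = 0.05 lies within
  [0.03, 0.07] over 1000 null simulations each.

## Bulk assays

Percent protection = 100 (Δ − Δ_sHsp)/Δ, where Δ is the maximum
baseline-subtracted light scatter of the client alone. The baseline is the
first reading (minimum-subtraction available). Technical replicates are
averaged first; protection is computed per independent replicate and then
summarised as mean ± SD. Values above 100% or below 0% are reported, not
clamped. Labelled-protein concentration and degree of labelling use the
standard absorbance equations with built-in maleimide-dye constants
(C.F. 0.11/0.03, ε_dye 72 000/83 000 M⁻¹cm⁻¹ for the AF488-/AF647-like
dyes). Bis-ANS kinetics: blank subtraction, first-reading subtraction, then
a nonlinear least-squares one-phase association fit
y = y₀ + (plateau − y₀)(1 − e^(−kt)) with k ≥ 0; decreasing signals fit
with plateau < y₀.

## Pipeline and determinism

`run_pipeline` executes correct → register → detect → extract → classify →
step-fit → unit-step → count → colocalise → complex table → summaries,
writing every intermediate table as schema-versioned CSV and logging
parameter values, seeds and in/out counts of every filter (the counts
balance exactly: spots = border-excluded + too-short + rejected +
accepted). I_step is estimated per channel, pooled over an experiment's
fields, because fluorophore brightness differs between emission channels.
One master seed fans out deterministically to per-stage seeds via SHA-256
of the stage name (kept below 2³¹); two runs with the same config are
byte-identical.

## Problem sizes used in validation

The shipped tests and the acceptance script use: 500-trace cohorts for
stoichiometry recovery (subunits 2–20, SNR 8, labelling {1: 0.5, 2: 0.5});
500 short traces (n ≤ 50, ≤ 3 steps) for oracle equivalence; 20-seed
batches at ~0.002 spots/px² (spot-level fast path, no rendering) for
colocalisation calibration; 10-bead pairs for registration; 1000 null
simulations per statistical test; and 96 px × 250-frame rendered fields for
the end-to-end determinism and integration checks. These sizes give
Monte-Carlo errors comfortably inside the asserted tolerances while the
whole battery runs in minutes on one CPU.

## Known limitations

* No drift, vibration, or evanescent-depth modelling; no EMCCD gain
  calibration; no vendor file formats beyond TIFF.
* The classifier is only as good as the artefact classes it was trained
  on; real data contain artefact modes the simulator does not generate.
* FRET between channels is handled only by the alternate-excitation
  acquisition flag; FRET efficiencies are not quantified.
* Dark-offset and flat-field maps must be supplied (constants or
  calibration images); no automatic estimation is attempted.
* Molecules whose fluorophores all bleach within the first 20 frames are
  systematically undercounted by the I_initial window — a property of the
  estimator itself, shared by any implementation of it.
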