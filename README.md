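# smstoich

Single-molecule TIRF photobleaching analysis for counting the subunits of
small heat-shock protein (sHsp) chaperones and their aggregation-prone
client proteins inside individual chaperone–client complexes.

sHsps such as αB-crystallin (HSPB5) and Hsp27 (HSPB1) bind misfolding
clients (firefly luciferase, rhodanese, CLIC1) and trap them in soluble
complexes. Because these complexes are heterogeneous and evolve over
incubation time, ensemble assays only report averages. Surface-immobilised,
dual-colour TIRF microscopy resolves individual complexes: the client
carries one fluorophore colour (AF647-like), the chaperone another
(AF488-like), a complex appears as a colocalised spot pair, and the number
of subunits of each species follows from photobleaching.

This package implements the full quantification pipeline for such data, for
people building or validating single-molecule stoichiometry analyses:

* **Synthetic data with ground truth** — Gaussian-PSF spot rendering on a
  camera grid (160 nm pixels, 0.5 s exposure, 600–1000 frame stacks),
  stepwise photobleaching with per-frame geometric bleach hazards, lognormal
  step-height dispersion, shot/read noise, optional blinking, incomplete or
  double labelling, bead registration pairs, and complex populations whose
  sHsp:client stoichiometry evolves over incubation time.
* **Registration & detection** — offset/flat-field correction, affine
  channel registration from fiducial beads, difference-of-Gaussians spot
  detection with sub-pixel refinement, and aperture photometry with an
  annulus-median background.
* **Colocalisation with chance correction** — one-to-one mutual-nearest-
  neighbour spot pairing; chance coincidence estimated by rotating one
  channel 180° about the field centre and subtracting the resulting match
  fraction.
* **Step counting** — trajectory classification (simulator-trained shape
  classifier or a rule-based fallback), exact penalised least-squares
  change-point segmentation (with a Bayesian offline alternative), and
  subunit counts from the estimator below.
* **Stoichiometry statistics** — per-complex molar ratios, time-course
  summaries with bootstrap errors, Kruskal–Wallis with Dunn's post-hoc
  procedure, and two-way ANOVA with Tukey HSD on log₁₀ molecule sizes.
* **Bulk assays** — percent protection from light-scatter curves, labelled
  protein concentration and degree of labelling from absorbances, and
  one-phase association fits of bis-ANS hydrophobicity kinetics.

## The estimator

For each accepted photobleaching trajectory, change points are found by
minimising

  Σ_segments Σ_t (I_t − μ_segment)² + β σ² log(n) · (#change points)

exactly (dynamic programming over all partitions). The unit step intensity
of a cohort is

  I_step = median(final photobleaching step sizes),

the initial intensity of a molecule is I_initial = mean of its first 20
frames, and the subunit count is

  subunits = (I_initial / I_step) / f̄,

where f̄ is the mean number of fluorophores conjugated per monomer, measured
from a denatured-monomer control by averaging its bleach-step counts. The
molar ratio of a complex is sHsp subunits divided by client subunits.

## Worked example

`analysis/` contains numbered drivers. `01_simulate_experiment.py` renders
a simulated αB-crystallin + luciferase incubation (four timepoints, two
replicates, dual-channel stacks plus a bead pair) and
`02_run_pipeline.py` analyses it end to end:

```
$ python analysis/01_simulate_experiment.py
$ python analysis/02_run_pipeline.py
registration: 12 beads, residual 0.021 px
unit step per channel: client=214.6, shsp=217.5

time-course summary:
 timepoint_h  n_molecules  percent_colocalised  median_molar_ratio  median_subunits_coloc
         0.0           13                6.378                 NaN                    NaN
         0.3           44               23.077               0.750                  5.165
         0.6           59               35.545               1.382                  7.102
         1.0           68               33.750               2.913                  8.229
```

The percent colocalised is the chance-corrected fraction of client spots
paired with a chaperone spot (mean over replicates); the median molar ratio
rising from 0.75 to 2.9 over the hour reflects the preset's recruitment of
additional chaperone subunits into existing complexes; the median complex
size grows as clients oligomerise. `03_stoichiometry_recovery.py` checks
the estimator against ground truth (regression slope 0.968 on a 500-molecule
cohort at SNR 8 with incomplete labelling), `04`–`06` calibrate the
colocalisation correction, the statistical battery and the bulk-assay fits.

The same stages are scriptable through the `smstoich` CLI
(`simulate`, `register`, `detect`, `count`, `coloc`, `analyze`, `run`,
`assay`) or the library API (`smstoich.pipeline.run_pipeline`).

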