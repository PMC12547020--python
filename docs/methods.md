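# Methods

This note documents the models and procedures `gpcrquant` implements, the
choices made where the underlying analysis left details open, and what the
synthetic-data generators do and do not emulate.

## Peripheral plasma-membrane quantification

The measured quantity is the mean fluorescence of a morphological ring at
each cell's periphery — an operational proxy for receptor abundance at the
plasma membrane (PM).

Given an integer label mask from an external segmenter (e.g. Cellpose run
on DIC images) and a single-plane 16-bit fluorescence image:

1. **Separation erosion.** Every label is eroded independently with a
   diamond (L1-ball) structuring element of radius 1 px so that touching
   cells detach. Per-label erosion is implemented as iterated 4-neighbour
   label agreement, which is exactly diamond erosion applied to each label
   in isolation.
2. **Size filter.** Connected components (8-connectivity) smaller than
   5000 px are removed; survivors are relabeled 1..K. The filter runs
   *after* the separation erosion, matching the stated order of the
   original workflow. At the ~80 px cell diameters the segmenter targets,
   5000 px rejects debris and partial cells.
3. **Ring construction.** ring = cell − erosion(cell, diamond radius 7).
   The ring is therefore at most 7 px deep along any inward normal
   (4.95–7 px in Euclidean terms, because the diamond is an L1 ball).
   Cells that a radius-7 erosion empties entirely are smaller than the
   method's intended cell size; they are flagged "fully peripheral" and
   dropped rather than measured whole.
4. **Pseudo-flat-field subtraction.** output = image − Gaussian(image,
   sigma = 50 px). Boundary handling is reflection, which avoids the dark
   border artifact that zero or nearest padding would introduce on a
   1200-px field. Negative values are retained unclipped: the procedure is
   plain subtraction, and clipping would bias dim cells upward.
5. **Measurement.** The per-cell arithmetic mean of the corrected image
   over the ring pixels, with the ring pixel count recorded.

Properties that hold by construction and are enforced in tests: ring sets
of distinct cells are disjoint; output is invariant under label
permutation and under constant intensity offsets (the blur of a constant
is that constant); scaling the image scales all ring means linearly.

**Known bias.** The subtracted blur at a cell contains roughly half of the
cell's own smeared signal plus that of its neighbours, so absolute ring
means sit well below the rendered membrane amplitude; and a 4-px-wide
membrane inside a ≤7-px ring means the ring mean mixes membrane with
cytoplasm. Both effects are inherent to the method (they are present in
the real measurement too). For the ratio-type quantities the pipeline
reports (treated/control percentages) they largely cancel: recovered
percent changes sit within ~2.5 points of the generator's programmed
effect, and the residual offset is documented by the test suite.

## Group statistics

Per-cell ring means are expressed as percentages of the control group's
mean (within a stratum such as a time point when one is supplied), so the
control group averages 100% by construction. Summaries expose mean, SEM
and a 95% percentile bootstrap CI (B = 1000 resampled means by default,
deterministic per seed) side by side.

- **Two-group comparisons** use Welch's unequal-variance t test with
  Welch–Satterthwaite degrees of freedom; one-tailed variants halve the
  matching-direction p-value.
- **Four-group comparisons** (WT ± rapamycin, mutant ± rapamycin) use a
  one-way ANOVA followed by Tukey's honestly-significant-difference test
  with the classic pooled within-group variance and the studentized-range
  distribution.
- **Rescue categories.** Let p_u and p_t be the mutant-treated group's
  Tukey-adjusted p-values against untreated and treated wild type. With
  sig = p < 0.05: (sig_u, ¬sig_t) → no rescue; (sig_u, sig_t) → partial
  rescue; (¬sig_u, sig_t) → complete rescue. The fourth combination,
  different from neither reference, is reported as "indeterminate" rather
  than forced into a category. Classification runs on percent-normalized
  values (the scale on which the groups are plotted and compared); a raw
  scale option remains available in the library API.
- **Mating efficiency** = 100 × (diploid colonies × diploid dilution) /
  (competent colonies × competent dilution). Diploids are a subset of
  competent cells, so an estimate ordering violation is rejected as a
  counting error. Treated-vs-control comparisons use the one-tailed Welch
  test in the direction "treated mates less".

## Vacuole lumen:membrane classification

A line scan through the largest vacuolar body crosses the vacuolar
membrane twice; the membrane-marker channel (Vph1) therefore shows two
peaks. Peaks are strict local maxima ranked by topographic prominence;
among all pairs separated by at least `min_sep` samples (default 10 px at
0.043 µm/px confocal sampling) the pair with the greatest combined
prominence is chosen. No smoothing is applied before peak-finding by
default. The vacuolar membrane is the six samples at the two peaks ±1
(clipped and logged at series bounds); the lumen is the closed range
strictly between those triplets, [left+2, right−2]. Cells whose peaks are
closer than 4 samples, or whose membrane cargo mean is ≤ 0, are excluded
as unclassifiable.

The phenotype is the cargo (receptor) lumen:membrane ratio: > 1 → "full"
(phenotype 1), < 1 → "empty" (phenotype 2). A ratio of exactly 1 — a
measure-zero event that a deterministic rule must still cover — is
classified full. The classifier is invariant under profile reversal and
under positive scaling of the cargo channel.

Confocal inputs are background-subtracted with a grayscale rolling ball of
radius 50 px before sampling; line sampling is bilinear at unit-pixel
steps. Line endpoints are inputs: vacuole selection and line placement
were manual in the original workflow and are out of scope here.

## Hill dose–response fitting

Reporter fluorescence is divided row-wise by culture density (A600), and
per-dose replicate means are fit ("averages are fit") to

    y(d) = b + Emax · d^n / (EC50^n + d^n)

by bounded least squares with all four parameters bounded below by zero
and unbounded above. The basal term b is required because the assay plates
a 0 µM column, and y(0) = b exactly. Initialization: b = min response,
Emax = max − min, EC50 = dose nearest half-maximum, n = 1 — robust for
sigmoid data on the half-log ladder 0, 0.003, 0.01, 0.03, 0.1 … 300 µM.
95% CIs are asymptotic (Jacobian covariance with a t-quantile at
n_points − 4 df); profile-likelihood intervals are out of scope. Fits are
flagged on non-convergence, on a flat response (Emax CI containing zero,
or Emax negligible relative to the baseline), and when EC50 leaves the
tested positive dose range by more than 10×.

Two fits are compared per parameter by the conservative CI-overlap rule:
significant only if the intervals are disjoint. Flagged fits yield
"indeterminate".

## Synthetic data

The raw microscopy behind the original measurements is not public, so the
generators produce inputs with the statistical structure the pipeline
assumes, with every nuisance parameter recorded as ground truth. Effect
presets store the printed relative changes (e.g. membrane_scale 0.40 for
the 60% rapamycin reduction in Ste2, emax_scale 5.33 for the 433%
ypk1Δ increase, mating probabilities 0.78/0.53); absolute intensity scales
are arbitrary choices and only ratios carry meaning.

- **Fields**: 1200×1200 px, cells as ellipses with semi-axes U(45, 60) px
  on a jittered grid (pitch 150 px, jitter ±5 px), which guarantees ≥ 3 px
  clearance, keeps each cell above the 5000-px filter, and bounds a field
  at 64 cells; larger cohorts split across fields (default 50 cells per
  field, so 300 cells = 6 fields). Each cell: 4-px peripheral membrane
  band at 8000 × membrane_scale AU, cytoplasm 1000 AU, one 1500 AU vacuole
  disc; the vacuole level is a free choice standing in for lumenal
  receptor signal. The background offset is 100 AU. The illumination
  gradient is an additive 500→1500 AU planar ramp — additive so that blur
  subtraction can remove it the way the method intends; noise is Poisson
  counting noise plus Gaussian read noise (sd 20 AU).
- **Line profiles**: marker = 50 AU baseline plus two Gaussian peaks
  (sd 2 px, amplitude 400 AU) near the quarter points with ±5 px jitter;
  cargo = 10 AU baseline, 100 AU membrane shoulders at the peaks, and a
  lumen plateau at 3× (full) or 0.3× (empty) the shoulder level, drawn per
  Bernoulli(empty_vacuole_prob); noise is Gaussian with sd = 5% of signal.
- **Dose–response**: control curve b 50 AU, Emax 1000 AU, EC50 1 µM,
  slope 1.2 (free choices; only the preset multipliers are anchored),
  9 replicates, multiplicative noise CV 10%, and a simulated A600 ~
  U(0.6, 0.8) multiplied into the stored fluorescence so density
  normalization is actually exercised.
- **Mating counts**: competent ~ Poisson(500) per assay, diploids ~
  Binomial(competent, mating_prob), 5 assays per arm.

What the generators do **not** emulate: point-spread blurring, budding
morphology, multi-lobed vacuoles, z-stacks, plate-position effects, or
segmentation errors (masks are exact). Passing recovery tests therefore
demonstrates that the quantification and statistics are correct and
unbiased for data satisfying the method's assumptions — not that the
method is robust to segmentation or optics artifacts.

## Problem sizes and determinism

All generators are deterministic given a seed; pipeline stages are
deterministic throughout. Recovery experiments use 300 cells per arm
across 6 fields for intensity changes, 9-replicate plates for Hill fits,
150 profiles per arm for vacuole phenotypes and 5 assays per arm for
mating — matching the cohort sizes the analyses are designed around.
Single-draw fold-change estimates at 150 cells per arm carry a ~20%
coefficient of variation from binomial sampling alone; the test suite
therefore pools replications when asserting calibration, while reporting
scripts keep the single-cohort experiment.

## Known limitations

- The ring mean is a membrane-plus-cytoplasm mixture; percent changes are
  recovered to within ~2.5 points of the programmed effect, not exactly
  (see "Known bias" above).
- The CI-overlap significance rule is conservative relative to a direct
  test on the parameter difference; it is implemented as specified because
  it is the decision rule the fits are designed for.
- `fit_hill` fits per-dose means; per-replicate weighted fitting is
  available via the library but off by default.
- Rolling-ball subtraction on large images is the slowest step
  (scikit-image's exact algorithm); it is only needed on confocal inputs,
  never in the widefield ring pipeline.
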