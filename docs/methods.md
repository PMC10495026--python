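# Methods

This note documents the models, defaults and design choices behind
murmurbench, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scoring model

### Weighted accuracy

The murmur metric is a class-weighted accuracy over the 3×3 confusion matrix
(rows = model output, columns = expert label, order Present/Unknown/Absent)
with weights 5/3/1. The denominator weights each labelled patient by their
class weight, so the metric is 1 exactly when the matrix is diagonal and
reduces to plain accuracy when the three weights are equal (a property the
test suite checks). The weights are exposed as a parameter but default-locked
to 5/3/1; changing them changes the metric, not merely its scale.

### Cost metric

The outcome metric prices a screening pipeline: algorithmic pre-screening at
10 per patient, expert confirmation of every algorithm-positive at a mean
per-patient cost `g(x) = 25 + 397x − 1718x² + 11296x⁴` for screening fraction
`x`, treatment at 10 000 per confirmed positive, and 50 000 per missed
positive. All currency is abstract units. The quartic has no cubic term by
construction; `CostParameters.expert_poly` therefore holds exactly the
(constant, linear, quadratic, quartic) coefficients.

The "optimal capacity" claim concerns the **per-screening** mean cost
`g(x)/x`, not the per-patient mean `g(x)`: `g` itself is increasing near 0
and has no interior minimum, while `h(x) = g(x)/x = 25/x + 397 − 1718x +
11296x³` has the stationarity condition `h'(x) = −25/x² − 1718 + 33888x² = 0`,
i.e. `33888x⁴ − 1718x² − 25 = 0`, a quadratic in `x²` with the positive root
`x² = (1718 + 2518)/67776 = 1/16`, hence `x = 0.25`.
`optimal_screening_fraction` locates the minimum by a coarse bracketing grid
followed by bounded scalar minimization to absolute tolerance 1e-6; when the
objective is monotone on (0, 1] (e.g. a polynomial with no interior minimum)
the boundary argmin is returned with an explicit `boundary=True` flag rather
than an error.

### Traditional metrics

AUROC is computed as the rank statistic with average (midpoint) ranks on tied
scores; AUPRC as precision-weighted recall increments over distinct score
thresholds (the step-wise definition, not trapezoidal interpolation). For the
three-class murmur task, AUROC/AUPRC/F-measure are one-vs-rest per class and
macro-averaged; a class absent from the labels is excluded from the macro
average with a warning. For the binary outcome task all four metrics are
computed on the Abnormal class. Discrete classes are authoritative for
F-measure/accuracy and the confusion matrices; probabilities are
authoritative for AUROC/AUPRC. Entries may threshold the two independently —
the discrete class is never derived from the probabilities by the scorer.

### Cross-task variants

The outcome-task weighted accuracy `(5·n_TP + n_TN) / (5·(n_TP + n_FN) +
(n_FP + n_TN))` and the murmur-task cost (the cost model applied after
mapping Present/Unknown → referral-positive and Absent → negative on both
labels and outputs) are **reconstructions by this package**. The official
supplementary definitions of these cross-task metrics were never published in
the main text; these variants are flagged as such everywhere they appear and
should not be cited as the official forms.

### Ranking and concordance

Leaderboards use competition ("1224") ranking: tied scores share the best
rank and the next distinct score's rank is 1 + the number of strictly better
entries. Metric concordance reports Spearman's rho (average ranks on ties)
and a robust line fitted by iteratively reweighted least squares with Huber
weights (statsmodels RLM).

## Cohort simulator

The simulator emulates the *structure* of a pediatric auscultation screening
dataset: demographics (age group, sex, height, weight, pregnancy status),
a three-class murmur annotation with locations and per-phase descriptors
(timing, shape, pitch, grade, quality), a binary clinical outcome, one to
four valve-location recordings per patient, and a fraction of patients who
attended two screening campaigns (linked records).

Default probabilities reproduce the published dataset marginals: murmur
(Present 0.195, Unknown 0.076, Absent 0.730 — renormalized, since the printed
values sum to 1.001), age groups (Neonate 0.006, Infant 0.122, Child 0.708,
Adolescent 0.085, missing 0.078), female 0.498, pregnancy ≈ 0.070. The
clinical outcome is sampled **conditionally on the murmur class** — defaults
P(Abnormal | Present) = 0.85, P(Abnormal | Unknown) = 0.5 — with the Absent
conditional solved at validation time so the marginal abnormal rate hits the
configured target (default 0.482). Only the marginals are data-derived; the
conditionals are tunable package conventions. Pregnancy is assigned only to
female patients in the Adolescent or missing age groups (the source data do
not record ages for pregnant individuals); the configured rate is interpreted
per eligible patient and divided by the female fraction internally so the
marginal is preserved.

### Waveform model

The PCG generator is deliberately phenomenological — a test-signal model, not
a hemodynamic one:

- per cardiac cycle, S1 and S2 are Gaussian-windowed tones (50 Hz / σ = 12 ms
  at amplitude 1.0, and 70 Hz / σ = 10 ms at amplitude 0.8) centred at 5% and
  40% of the cycle;
- the systolic murmur window is 10–34% of the cycle and the diastolic window
  46–98%; `timing` selects the whole window (holo-), its first half (early),
  middle half (mid) or second half (late);
- the murmur component is band-limited Gaussian noise (4th-order Butterworth,
  zero-phase) in the pitch band — Low 80–150 Hz, Medium 150–300 Hz, High
  300–600 Hz — normalized to unit peak, multiplied by the shape envelope
  (rising ramp, falling ramp, triangle, or constant, each with a 0.1 floor
  except the plateau) and scaled by the grade gain relative to the S1 peak
  (I 0.1, II 0.25, III 0.5);
- the murmur is injected only into recordings at the murmur's annotated
  locations; murmur-Unknown patients get an Absent-style waveform with heavy
  white noise (sd 0.35 vs the default 0.01), modelling recordings inadequate
  for diagnosis;
- the sum is peak-normalized to at most 0.99 and snapped onto the 16-bit PCM
  grid, so waveforms survive a WAV write/read cycle bit-exactly.

The base signal (transients + measurement noise) and the murmur component are
drawn from independent random streams spawned from the same seed, so
re-rendering a seed without the murmur reproduces the identical base
waveform; paired renderings are what the band-power gating tests compare.

Default sample rate is 4 kHz and recording durations are uniform in
[5, 12] s — values in the range of digital-stethoscope practice, chosen so
that cohorts of a few thousand patients remain cheap to generate while every
recording contains well over the three cardiac cycles the synthesizer
requires. Heart-rate ranges per age group (Neonate 120–160, Infant 100–150,
Child 80–120, Adolescent 60–100 bpm) follow pediatric norms. All of these are
config fields.

What the simulator does **not** capture: real murmur acoustics (no
pathology-specific spectra), respiratory and ambient noise structure,
operator variability, sensor coupling, heart-rate variability within a
recording, and any correlation between demographics and murmur status beyond
the label model. Consequently, passing tests demonstrate correctness of the
*evaluation machinery* and learnability claims on controlled signal, not
clinical performance on real phonocardiograms.

### Splitting

`split_cohort` targets recording-count fractions (default 60/10/30) under the
constraint that linked patients (connected components of the `linked_id`
relation) stay together. Groups are shuffled with the given seed, ordered
largest-first, and each is assigned greedily to the split with the largest
remaining recording deficit; ties prefer train, then validation, then test.
This is deterministic under a fixed seed, exactly grouping-safe, and lands
within a fraction of a percentage point of the targets for cohorts of a few
hundred patients or more.

## Reference entry

The baseline is a random forest (100 trees, unlimited depth, bootstrap — 
conventional defaults, config-exposed) per task over a fixed 25-slot feature
vector: age-group one-hot (5), female indicator, height, weight, pregnancy
indicator, and per valve location (AV, PV, TV, MV) the presence indicator and
the mean, variance and skewness of the raw amplitudes. Choices the feature
definition leaves open were resolved as follows: skewness is the population
Fisher g1 moment estimator, reported as 0 when the variance is below 1e-12;
multiple recordings at one location are averaged per-statistic; "presence"
means presence of a recording at the location, not of a murmur; recordings at
other positions (Phc) contribute to no block — a documented limitation;
missing height/weight are imputed with the training-set median, and a missing
age group occupies its own one-hot slot. Predictions are the argmax of the
tree-vote probabilities with ties broken toward the severer class (Present >
Unknown > Absent; Abnormal > Normal). Single-class training labels trigger a
constant-classifier fallback with a warning instead of an error.

The entry exists to be a minimal, label-sensitive, fully reproducible
reference for the harness, ensemble and audit — not to perform well.

## Voting ensemble

The meta-learner consumes only the one-hot discrete classes of the k
top-ranked entries (3 columns per entry for murmur, 2 for outcome; column
order fixed by entry rank then class order). Entries are ranked best-first by
the task metric on the **training** split; k is scanned from 1 to `max_k`
with a refit per k, scored on the validation split by the same task metric,
and ties prefer the smallest k (simplest model). The test split is never a
parameter of selection. Meta-model defaults: gradient boosting with 100
rounds at depth 3, or a 100-tree random forest; no other hyperparameters are
searched. The fused discrete output is the argmax of the meta-model
probabilities with severity tie-breaking; murmur and outcome ensembles are
fully independent runs whose outputs can be merged with `fuse_outputs`.

## Permutation audit

The audit draws a random subset of the training split (default fraction 0.5 — 
a knob, not a claim), trains the entry twice on that same subset — once with
the original labels, once with the patients' (murmur, outcome) label *pairs*
permuted jointly, which preserves the labels' joint distribution — and scores
both runs on the untouched validation split with the original labels. Using
the same subset for both runs isolates the label signal: a label-blind entry
degrades by exactly zero. Degradation is sign-adjusted to be positive when
permutation hurts (absolute weighted-accuracy drop for the murmur task,
relative cost increase for the outcome task); the default verdict threshold
is 0.05 on either scale. The exact robustness criteria used in the original
competition were intentionally never disclosed, so the subset fraction and
threshold here are explicit, documented knobs. The audit constructs permuted
records in memory and never modifies stored cohort files (checksum-tested).

## Numerical and format conventions

- Entry probability vectors are renormalized on read when their sum deviates
  from 1 by at most 1e-3 (forgiving to float formatting); larger deviations
  are hard validation errors (strict to logic bugs). After reading, vectors
  sum to 1 within 1e-6.
- Cohorts are exchanged as one UTF-8 `key: value` header per patient with
  `nan` as the missing sentinel plus 16-bit PCM mono WAV files; writing is
  byte-deterministic. Both discrete classes and probabilities are mandatory
  in entry outputs.
- Degenerate inputs fail loudly: empty confusion matrices, empty cohorts and
  sub-3-point concordance inputs raise `UndefinedMetricError`; invariant
  violations raise `ValidationError`; malformed files raise `ParseError` with
  file and line.

## Problem sizes in the shipped tests

The suite validates simulator calibration at n = 2000 (3 binomial standard
errors) and the marginal-calibration property at n = 5000 with shortened,
lower-rate recordings; oracle equivalence runs 1000 random micro-cohorts of
at most 12 patients against naive loop-based reimplementations at 1e-12; the
audit and ensemble scenarios use cohorts of 160–500 patients. These sizes were
chosen to make the statistical assertions sharp while keeping a full test run
around a minute on one core.
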