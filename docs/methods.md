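# Methods

`nirspd` implements a screening pipeline that classifies resting-state
functional near-infrared spectroscopy (fNIRS) recordings as Parkinson's
disease (PD) positive or negative.  The pipeline has four stages:
feature extraction, feature standardization, a two-stage feature
selection (ensemble ranking followed by a wrapper or genetic-algorithm
search), and logistic-regression classification assessed with
stratified k-fold cross-validation.  Because the clinical cohort that
motivates the design is external data, the package ships a synthetic
cohort generator that reproduces the recording geometry and the
statistical structure the pipeline assumes, so every stage is testable
end to end.

## Recording model and synthetic cohorts

A recording is a (band × channel × time) array of haemoglobin
concentration changes in µM: three chromophore bands (HbO, HbR and
HbT = HbO + HbR), 22 channels (20 long source–detector separations
over motor regions plus 2 short scalp channels), sampled at 25 Hz for
360 s (9 000 samples).

The generator synthesises each channel as a sum of the standard
spontaneous oscillations plus white noise:

| component   | centre freq (Hz) | amplitude (µM) | in short channels |
|-------------|------------------|----------------|-------------------|
| cardiac     | 1.1              | 0.25           | yes               |
| respiratory | 0.25             | 0.40           | yes               |
| Mayer wave  | 0.10             | 1.00           | yes               |
| slow drift  | 0.008            | 0.60           | no                |

Per channel, each component gets a uniformly random phase and a ±20 %
amplitude jitter; HbR mirrors HbO with opposite sign at 1/3 amplitude
(the typical deoxy/oxy oscillation ratio), and independent white noise
of 0.10 µM SD (0.033 µM for HbR) is added to each chromophore.  HbT is
the exact samplewise sum.  The Mayer wave is deliberately the
largest-amplitude component so that every channel's dominant spectral
peak is known ground truth.  No public amplitude statistics exist for
the motivating recordings, so these values were chosen once as
physiologically plausible resting-state magnitudes and are not
calibrated against any test outcome.

**Class effect.** For a PD-labelled subject, channels in
`effect_channels` (default: the first five long channels) have the
Mayer-wave amplitude scaled by `1 + 0.5·effect_size` and its centre
frequency shifted by `0.01·effect_size` Hz.  This plants signal in both
feature families — amplitude-sensitive temporal features (variance,
max-abs) and spectral features (energy, dominant frequency) — which is
what a recovery test must exercise.  `effect_size = 0` makes the label
exactly independent of the signal distribution.

**Reproducibility.** One root seed per cohort; subject *i* draws from
the *i*-th spawned child of `numpy.random.SeedSequence(seed)`, so
cohorts are bit-reproducible and appending subjects never perturbs
earlier ones.

**Artifacts.** `inject_artifacts` adds Gaussian-shaped spikes (default
peak 10 µM, width 0.4 s) and step baseline shifts at
`round(rate · minutes)` random positions, returning the event list as
ground truth for the motion-correction tests.

What the generator does **not** emulate: task-evoked responses, 1/f
background spectra, inter-subject anatomical variability, optode
sensitivity profiles, systemic confounds correlated across channels,
or realistic artifact morphology.  Passing recovery tests therefore
show that the pipeline finds the kind of localized amplitude/spectral
class differences it was designed for — not that it would reach the
same numbers on clinical data.

## Preprocessing

* **Beer–Lambert conversion** (for optical-density inputs): solves the
  2×2 modified Beer–Lambert system per sample.  Extinction
  coefficients default to Gratzer-style tabulated values at 757/843 nm
  expressed in 1/(µM·cm), differential pathlength factor 6, separation
  3 cm.  The forward model is also exposed, and the inverse is tested
  as its round trip (relative error < 1e-9).
* **Channel pruning**: quality is the absolute Pearson correlation of
  the 0.7–1.5 Hz band-passed HbO and HbR traces — a scalp-coupling
  index applied to the chromophore pair; channels below 0.7 are
  flagged, never deleted or reordered, so the 792-column feature
  layout is stable.  Feature extraction fills flagged channels with
  the cohort column median.
* **Motion correction** (simplified spline + wavelet scheme): samples
  whose moving-SD robust z-score exceeds 5.0 are replaced by
  cubic-spline interpolation of the flanking samples; db4 wavelet
  detail coefficients beyond 5 robust SDs of their level are clamped.
  The threshold 5.0 flags no samples on clean synthetic records
  (keeping the clean-record change below 0.1 % RMS) while
  10×-amplitude spikes give z-scores far above it (recall 1.0 on
  injected ground truth).  HbT is recomputed after correction.
* **Standardization**: per-column centre/scale fitted on a stated row
  subset; the returned statistics transform held-out rows with the
  training distribution (leakage guard).  Zero-variance columns pass
  through centred with unit scale and a warning, rather than crashing.

## Features (792 per subject)

Twelve features per (channel, band) trace — 6 temporal, 6 spectral —
giving 22 × 3 × 12 = 792 columns (396 temporal + 396 spectral), named
`ch{c}_{band}_{t|s}_{feature}`:

* temporal: max |x|, mean, population variance, population skewness,
  mean inter-zero-crossing interval (s), mean zero-crossing-to-peak
  interval (s).  Zero crossings are sign changes of the mean-removed
  trace (a sample exactly at zero counts once); the crossing-to-peak
  interval runs to the next local extremum of the mean-removed trace.
  A trace with no crossings reports the record duration as a flagged
  sentinel.
* spectral: mean, variance, skewness, kurtosis (non-excess) of the
  one-sided DFT magnitude spectrum of the mean-removed, untapered
  trace (DC excluded); energy = Σ|X|², normalised so it equals the
  time-domain energy (Parseval); dominant frequency = argmax bin.

Moment conventions are population (divide-by-N) throughout, stated in
the emitted feature dictionary.  A Welch-style estimator was
considered and rejected for the default: the magnitude-DFT is the
minimal reading of "the frequency spectrum of each band", and the
Parseval-exact normalisation gives the energy feature a clean unit
interpretation.

## Feature selection

**Stage 1 (ensemble, setting A).** Three label-aware/label-free
filters rank all features:

* MAD — mean absolute difference from the column mean (zero-MAD
  features flagged removed);
* MIG — mutual information (bits) with the label, estimated by
  equal-frequency discretisation into min(10, ⌊n/4⌋) bins (a
  neighbour-based continuous estimator is available); the plug-in
  estimator is invariant to monotone feature transforms;
* Fisher score — class-size-weighted between-class variance over
  pooled within-class variance (0/0 := 0; x/0 := +inf so perfectly
  separated features rank first).

Features ranked in the top p % by at least two of the three filters
form a candidate subset; p sweeps 1…10 % (top-set size ⌈p·d/100⌉, so
p=1 keeps ⌈7.92⌉ = 8 of 792), and the subset with the highest
cross-validated logistic accuracy wins (ties → smaller subset, then
smaller p).  Two embedded sparse selectors — elastic-net logistic
regression (l1_ratio 0.5) and an L1-penalised linear SVM, penalty
chosen by an internal stratified accuracy grid over C ∈ {0.01, 0.1, 1}
— contribute their nonzero-coefficient sets.  The three subsets are
**combined by set union**: at n = 40 the intersection of heterogeneous
selectors is typically near-empty, and the union matches the
ensemble's purpose of pooling the strengths of different methods.
(Intersection and majority vote are switchable readings.)

**Stage 2.** A search over the combined candidates (setting A) or over
all 792 features (setting B), driven by the fitness
`mean stratified k-fold CV accuracy of logistic regression on the
masked columns` (empty mask := 0):

* forward wrapper: greedily add the feature that most *strictly*
  improves fitness (ties → lowest index); stop when none does;
* backward wrapper: from the full set, remove the feature whose
  removal most improves or least harms fitness; stop when the best
  removal would strictly lower it;
* genetic algorithm: population 1000, 100 generations, single-point
  crossover with probability 0.05 per parent pair, per-bit mutation
  0.03, tournament-of-two parent selection, elitism 1, initial bit
  probability 0.5.  The crossover probability is unusually low for a
  GA but is retained deliberately as the default.  Tournament
  selection is our reading of
  "two winners of the previous generation"; roulette-wheel is
  switchable.  Elitism 1 gives the monotone best-fitness invariant.
  Fitness values are cached by mask — a pure cost optimisation that
  cannot change results.
* exhaustive search (≤ 16 features) exists purely as the ground-truth
  oracle for testing the heuristics.

The GA evaluates individuals by CV accuracy (not training accuracy),
consistent with accuracy-as-fitness plus CV-based reporting; the
alternative is switchable via a custom evaluator.

## Classification and evaluation

Plain logistic regression (ridge 1e-8 for numerical stability only,
lbfgs, tol 1e-8); folds are stratified and shuffled under a stated
seed — with a balanced 20/20 design stratification is the safe
default.  Per-fold confusion counts give accuracy = (TP+TN)/n,
recall = TP/(TP+FN), precision = TP/(TP+FP), F1 = 2TP/(2TP+FP+FN);
aggregates average the per-fold metrics, and undefined denominators
are flagged, never silently zeroed.  AUC is the rank-based
Mann–Whitney statistic; the headline value pools held-out
probabilities across folds (averaging a rank statistic over 4-subject
folds is unstable), with the per-fold average also reported.

## Leakage modes

The default execution standardizes and selects features on the **full
cohort before** cross-validation; this optimistically biases the CV
estimate because
held-out subjects informed the selection.  `leakage_mode="nested"`
re-runs standardization and selection inside each training fold and
reports the unbiased estimate alongside, clearly labelled.  The
pipeline's null calibration (no planted effect → accuracy near 0.5)
is carried out in nested mode: under whole-cohort selection the null
sits well above chance by construction, so only the nested estimate is
a meaningful calibration check.

## Desk-scale problem sizes

The shipped tests and the acceptance script run entirely on synthetic
cohorts sized so the full study completes in minutes on one CPU, as a
deliberate scaling choice: recovery and null studies use 10+10-subject
cohorts of 120 s; the GA runs with population 100 / 20 generations
(operator probabilities unchanged); the headline effect-cohort run
uses the full 20+20 × 360 s geometry.  The defaults in the public API
remain the full-scale values.

## Known limitations

* The temporal interval features (5–6) and the spectral estimator are
  interpretations of under-specified definitions; both are documented
  conventions with switches rather than claims of fidelity.
* The motion-correction scheme is a deliberately simplified
  spline-plus-wavelet procedure, not a reimplementation of any
  published artifact-correction algorithm.
* Short channels are treated as ordinary channels in the feature
  layout (matching the 22-signal count); optional short-channel
  regression is out of scope.
* Perfect (accuracy 1.0) results on strongly separated synthetic
  cohorts demonstrate pipeline correctness, not clinical performance;
  with 792 features and 40 subjects the full-cohort protocol's CV
  estimates are optimistic by design, which is why both leakage modes
  are reported.
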