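# Methods

This note documents the model, the numerical choices, the synthetic data
the tests run on, and the limits of what passing tests demonstrate.

## Segmentation

A channel of `n` samples is split into `n_segments` contiguous,
non-overlapping pieces: the first `n_segments − 1` of length
`floor(n / n_segments)`, the last absorbing the remainder (4097 → 1024,
1024, 1024, 1025). Each segment becomes an `m × k` matrix of `m`
consecutive sub-segment rows with `k = floor(len / m)`; any tail beyond
`m·k` is truncated and the dropped count logged (the alternative — padding
the long last segment — was rejected to keep every row an actual data
block). Indexing is 0-based with half-open intervals. Windows are
non-overlapping by default; an `overlap` (samples shared by consecutive
rows) is exposed for experimentation but all documented arithmetic assumes
0.

## Cov–Det reduction

The `m` sub-segment rows are treated as variables observed over the `k`
time points; their sample covariance uses the `k − 1` divisor. The
determinant is computed through the symmetric eigendecomposition
`H = VΛVᵀ`: the orthonormal factors contribute unit determinant, so
`|H| = Π γᵢ`. Eigenvalues are reported in descending order; negative
eigenvalues above `−1e−10` are clipped to zero before the product
(numerical PSD repair, logged) — genuinely negative values are left alone
so a non-PSD input is visible. On well-conditioned matrices the product
matches an LU determinant to 1e−8 relative (tested on random PSD matrices
up to 8×8 against an independent cofactor/LU oracle).

Ten descriptors are computed per covariance-matrix row (config
`feature_source="raw_rows"` switches to the raw sub-segment rows; both
give the `m × 10` grid, flattened descriptor-major). Conventions:

* variance uses the `n − 1` divisor, matching the covariance;
* skewness and kurtosis are the standardised third/fourth central
  moments; kurtosis is plain (Gaussian ≈ 3), not excess — downstream
  rank-based screening is invariant to the offset;
* both are defined as 0 for constant input so screening never sees NaN;
* the mode of continuous data is taken after Freedman–Diaconis binning:
  fullest bin (ties → leftmost), mode = the smallest most-frequent sample
  value in that bin. An exact-value mode is degenerate for real-valued
  signals; taking a sample value rather than the bin midpoint keeps the
  `min ≤ mode ≤ max` invariant exact and the discrete-data behaviour
  intuitive (`[2,2,3] → 2`). `mode_binning="fd-midpoint"` and `"exact"`
  are available.

The determinant is carried as metadata on every feature record and can be
appended as a classifier input (`append_det`, default off — whether it
enters the classifier is a genuinely open design point, and the default
keeps the 320-dimension arithmetic exact).

## Two-stage screening

Per class pair, each descriptor's values are pooled across sub-segment
columns and segments (one p-value per descriptor type): stage 1 is the
two-sample Kolmogorov–Smirnov test, stage 2 the two-sided Mann–Whitney U
test (midranks, tie-corrected normal approximation; exact null
distribution selectable for small samples — exact p-values are tested
against exhaustive enumeration for combined n ≤ 10). α = 0.05 per
descriptor with no multiple-testing correction, deliberately: the
screening is a coarse filter, not an inference.

The default combination rule is `"stage2"` — a descriptor survives iff
its Mann–Whitney p ≤ α. This is the rule that exactly reproduces the
published final feature sets for the four Bonn pairwise problems
(max/min/mode/range/variance/std for A and B vs E, the same plus kurtosis
for C and D vs E), including the cases where it disagrees with the
Kolmogorov–Smirnov verdict in either direction; the stricter `"both"`
rule is available via config. Multi-class problems compose per-pair sets
with intersection (two classes) or union (three or more), evaluated
left-to-right.

## The classifier

Weak learner: a fully-connected network `input → 9 (tanh) → 9 (ReLU) → 1
(linear)`, trained full-batch with Adam (default learning rate 0.02, up to
300 epochs) on a sample-weighted squared error. A stratified 15 %
validation slice of the training data drives early stopping (patience 30,
best parameters restored); predictions are clamped to [0, 1] and
binarised at 0.5. Inputs are z-scored per feature on the training fold
(necessary to keep tanh out of saturation); the input dimension always
equals the realized selected-feature vector length, the 9-9 geometry
applies to the hidden layers only.

Boosting: distribution `D` starts uniform over the M training examples.
Per round, the learner trains on D-weighted loss (weighting, not
resampling, since the error formula is a D-weighted sum), then
`E = Σ D_j I(|y_j − ŷ_j|)` with the strict indicator `I(x) = 1 iff
x > 0.2`, weight `w = 1/E`, and update `D_j ← D_j (1 + δ I(|y_j − ŷ_j|))`
renormalised. The indicator argument is the absolute difference so both
error directions upweight. Defaults: `L = 10` learners, `δ = 1`. Edge
policies: `E` is floored at `ε = 1e−6` so weights stay finite (the score
normalisation makes the cap scale-free); a learner with `E ≥ 0.5` is
discarded and the loop halts — if that happens on the very first round
the learner is retained with weight 1 so the ensemble remains usable on
no-signal data (the label-shuffle null exercises this). The decision is
`Q = Σ (wᵢ/Σw) pᵢ ≥ 0.5`.

Per-learner seeds derive from one root seed; identical seeds reproduce
ensembles and scores exactly on one platform.

## Metrics and protocols

All twelve metrics follow the standard confusion-matrix formulas;
FNR = 1 − Sen and FPR = 1 − Spec by construction. Ratios with a zero
denominator (DOR, PLR, NLR) return `+inf`, 0/0 returns NaN (reported as
undefined, never silently 0); a zero MCC denominator gives MCC = 0. Folds
are stratified with a fixed seed; leave-one-subject-out groups by subject
id. Screening and standardisation are re-fit inside every training fold —
the protocols only ever see a model factory, so leakage is structurally
impossible. If no descriptor survives screening in a fold (expected under
the shuffle null), all descriptors are kept and the event flagged.

## Synthetic data

The generator emulates the contrast the method assumes, at the Bonn
geometry (4097 samples, 173.61 Hz, 100 channels/class over 10 synthetic
subjects): background = 1/f-weighted Gaussian noise (sample SD normalised
to `noise_sd = 1`) plus a unit-amplitude 10 Hz alpha sinusoid with random
phase; seizure = the same background plus a 3 Hz spike-wave train (triangle
wave with one sharp 20 ms Gaussian spike riding each crest) scaled by
`seizure_amp_gain = 3`. The gain of 3 mirrors the marked amplitude
elevation of ictal EEG and makes the classes separable mainly through the
scale descriptors — which is the method's own premise, verified (not
assumed) by a Mann–Whitney check on the variance descriptor.

What this does *not* show: real ictal EEG is non-stationary within
channels, artefact-laden, and far less cleanly separable; passing tests
demonstrate the pipeline's correctness and its ability to recover a known
planted contrast, not clinical performance. Accuracies on the real Bonn /
Bern–Barcelona corpora require downloading those datasets and are outside
the test suite.

## Problem sizes

The default test and acceptance runs use the full default synthetic
dataset (200 channels → 800 segments of 320 features) for the end-to-end
protocols, and small matrices (≤ 8×8) for the determinant oracle; the
exhaustive-enumeration checks of the nonparametric tests cover every
sample-size pair with combined n ≤ 10.

## Known limitations

* The mapping from each time point to a multi-feature vector that
  motivates the covariance construction is not instantiated further; the
  sub-segment rows serve as the feature vectors.
* Boosting with inverse-error weights lets a single zero-error learner
  dominate the ensemble (weight 1/ε); on strongly separable data the
  ensemble then behaves like its best training-round learner.
* The Mann–Whitney exact mode requires tie-free data; with ties the
  tie-corrected asymptotic is used.
* Multiclass problems are handled as binary "class set vs comparator"
  compositions; there is no multiclass boosting.
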