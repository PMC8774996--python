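# covdet

Automatic epileptic-seizure detection from single-channel EEG, built around
a covariance-determinant (Cov–Det) dimensionality reduction, two-stage
nonparametric feature screening, and an AdaBoost ensemble of small
back-propagation neural networks.

Visual review of EEG recordings for seizure activity is slow and
expertise-bound; automated detection pipelines classify short EEG epochs as
ictal (seizure) or non-ictal. This package implements one such pipeline for
clinical-neurophysiology and biomedical-signal-processing researchers, with
readers for the two standard public single-channel layouts (the Bonn
five-set epilepsy corpus and the Bern–Barcelona focal/non-focal corpus), a
seeded synthetic generator so every stage is testable without downloads,
and a CLI.

## The method

1. **Segmentation.** A channel `X = {x_1, …, x_n}` is partitioned into
   `n_segments` contiguous pieces (4097 samples → 1024/1024/1024/1025),
   and each segment is rearranged into an `m × k` matrix of `m = 32`
   consecutive sub-segments.
2. **Cov–Det reduction.** The sample covariance of the sub-segment rows,
   `H = (1/(k−1)) Σ (aᵢ − m̄)(aᵢ − m̄)ᵀ`, is summarised via its
   eigendecomposition `H = VΛVᵀ`; because `|V| |Vᵀ| = 1`, the determinant
   is the eigenvalue product `|H| = Π γᵢ`. Ten statistical descriptors
   (mean, max, min, mode, median, range, variance, standard deviation,
   skewness, kurtosis) per covariance row give a 32 × 10 = 320-element
   feature vector per segment (1280 per channel).
3. **Two-stage screening.** Per class pair, each descriptor's pooled
   distributions are compared with the two-sample Kolmogorov–Smirnov test
   and the two-sided Mann–Whitney U test at α = 0.05; surviving
   per-pair sets are composed across classes with set intersection/union.
4. **AB_BP_NN classification.** AdaBoost over `L = 10` weak networks
   (two hidden layers of nine cells, tansig → ReLU → linear output) with
   distribution update `D_j ← D_j (1 + δ·I(|y_j − ŷ_j|))`, weighted error
   `E = Σ D_j I(|y_j − ŷ_j|)`, inverse-error learner weights `w = 1/E`,
   and decision score `Q = Σ (wᵢ/Σw) pᵢ ∈ [0, 1]`.
5. **Evaluation.** Twelve diagnostic metrics (accuracy, sensitivity,
   specificity, NPV, FNR, FPR, F-score, informedness, likelihood ratios,
   diagnostic odds ratio, MCC) under a stratified 50/50 split, stratified
   ten-fold cross-validation, or leave-one-subject-out, with screening and
   standardisation re-fit inside every training fold.

## Worked example

```python
import covdet as cd
from covdet.pipeline import SeizureClassifier

# two-class synthetic EEG at the Bonn geometry: 100 channels/class,
# 4097 samples at 173.61 Hz
table = cd.extract_features(cd.gen_dataset(cd.SynthConfig(seed=0)))
y = (table["label"] == cd.LABEL_SEIZURE).astype(int).to_numpy()

res = cd.ten_fold_cv(table, y, lambda: SeizureClassifier(seed=0), seed=0)
print(f"accuracy {res.accuracy:.4f}  sensitivity {res.pooled.sen:.4f} "
      f"specificity {res.pooled.spec:.4f}  mcc {res.pooled.mcc:.4f}")
```

prints

```
accuracy 1.0000  sensitivity 1.0000 specificity 1.0000  mcc 1.0000
```

— pooled over the ten test folds of 800 segments: every held-out segment
of this clearly separable synthetic dataset is classified correctly
(sensitivity = seizure segments caught, specificity = background kept
clean; both 100 %). Harder settings — smaller `seizure_amp_gain`, higher
`noise_sd` — bring the numbers below the ceiling.

The same run from a shell:

```sh
covdet simulate --out data --layout bonn --n-per-class 100 --seed 0
covdet extract  --data data --layout bonn --out features.csv
covdet evaluate --features features.csv --pos-label seizure --out metrics.json
```

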