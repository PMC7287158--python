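# mvpakit

Multivariate pattern analysis (MVPA) — statistical *decoding* of
experimental conditions from multi-dimensional recordings such as
EEG/MEG epochs (trials × channels × time) or fMRI volumes
(trials × voxels) — for researchers who want a self-contained,
scriptable Python engine with leakage-free cross-validation and
permutation statistics built in.

## What it does

Given a data array **X** ∈ ℝⁿˣᵖ (n samples, p features) and a class
label vector **y** ∈ {1, …, K}ⁿ or a real response vector, the package

- trains natively implemented models:
  - **LDA** with shrinkage-regularized covariance
    Σ_reg = (1−λ)Σ + λν**I**, ν = tr(Σ)/p, where λ defaults to the
    Ledoit–Wolf closed-form estimate; decision values
    dval = **w**ᵀ**x** + b with **w** = Σ_reg⁻¹(**m**₁ − **m**₂);
  - **multi-class LDA** (generalized eigendecomposition of
    between-/within-class scatter + MAP rule in the discriminant
    subspace), **Gaussian Naive Bayes**, **logistic regression** with
    log-F(1,1) or L2 penalty (damped Newton), a **soft-margin SVM**
    solved by dual coordinate descent (linear and kernel, optional
    Platt probability calibration), **kernel Fisher discriminant
    analysis**, subsample/subspace **ensembles**, and a
    nearest-centroid prototype illustrating the custom-model registry;
  - **ridge regression** — primal
    **w** = (**X**ᵀ**X** + λ**I**_p)⁻¹**X**ᵀ**y** or dual
    **w** = **X**ᵀ(**XX**ᵀ + λ**I**_n)⁻¹**y**, chosen automatically —
    and **kernel ridge**, α = (**K** + λ**I**)⁻¹**y**;
- cross-validates them (k-fold, leave-one-out, holdout, predefined
  folds, stratified, repeated) with **nested** preprocessing (z-score,
  PCA, under-/oversampling, trial averaging, kernel averaging) and
  nested hyperparameter grid search — everything is fitted on training
  folds only;
- sweeps the analysis over arbitrary extra dimensions (time points,
  frequencies, searchlight neighbourhoods) and supports
  **generalization** (train at time v, test at time u → a T×T matrix);
- scores with the full metric set: accuracy, AUC, confusion matrix,
  decision values, F1, Cohen's κ, precision/recall, t-value, MAE, MSE,
  R²; fold results are averaged weighted by test-set size;
- tests significance: exact binomial test, label-shuffling permutation
  tests, cluster-based permutation tests (family-wise error control via
  the maximal suprathreshold-cluster mass), and group-level
  (within/between subjects) permutation tests;
- generates seeded synthetic data (Gaussian class clouds, ERP-like
  epochs with planted spatiotemporal effects, linear-model regression
  data, multi-subject metric maps) so every analysis is testable
  without downloads.

Estimators follow the scikit-learn fit/predict convention
(`get_params`/`set_params`, fitted attributes with trailing
underscores) and compose with sklearn pipelines, while the high-level
drivers (`mv_classify`, `mv_classify_across_time`,
`mv_classify_timextime`, `mv_regress`) accept a plain configuration
dict.

## Worked example: time×time generalization

Two-class ERP-like trials (100 trials, 12 channels, 8 time points) with
one spatial activation pattern planted in two time windows, samples
2–3 and 5–6:

```python
import numpy as np
from mvpakit import mv_classify_timextime, binomial_test, synth

ds, y = synth.gen_erp_like(
    n_per_class=50, channels=12, n_times=8,
    effect_windows=[(2, 4), (5, 7)], amplitude=1.0,
    share_pattern=True, seed=3,
)
grid = mv_classify_timextime(
    {"model": "lda", "metric": "accuracy", "cv": "kfold",
     "k": 5, "repeat": 2, "seed": 0},
    ds, y,
)
print(np.round(grid["accuracy"], 2))
```

```
[[0.42 0.52 0.51 0.45 0.56 0.45 0.45 0.51]
 [0.55 0.47 0.65 0.69 0.43 0.57 0.62 0.52]
 [0.45 0.54 0.83 0.85 0.51 0.82 0.89 0.65]
 [0.46 0.55 0.8  0.85 0.47 0.81 0.86 0.61]
 [0.5  0.43 0.34 0.41 0.38 0.38 0.38 0.49]
 [0.51 0.49 0.82 0.86 0.48 0.84 0.87 0.58]
 [0.46 0.52 0.79 0.85 0.51 0.81 0.87 0.59]
 [0.54 0.48 0.68 0.68 0.48 0.66 0.72 0.63]]
```

Rows are training time points, columns test time points. Accuracy is at
chance (≈0.5) outside the planted windows, high (0.83–0.87) on the
diagonal inside them, and — because the two windows share one spatial
pattern — equally high in the *off-diagonal* blocks (train at time 2–3,
test at time 5–6 and vice versa): the classic signature of a
representation shared across time. A classifier trained at one
informative time decodes the other window too.

```python
res = binomial_test(grid["accuracy"][2, 6], n_test=100, chance=0.5)
print(f"{res.p:.2e}")   # 1.27e-16
```

The exact binomial test puts the cross-window accuracy of 0.89 far
below any conventional alpha.

A command-line interface mirrors the library
(`mvpakit classify|regress|stats|simulate`, JSON configs, NPY/CSV
data); see `mvpakit --help`.

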