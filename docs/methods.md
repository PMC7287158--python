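# Methods

This note documents the statistical models, the numerical choices, and
the synthetic-data assumptions behind mvpakit, in the spirit of a
methods appendix.

## Data model and conventions

Data is an N-dimensional real array with declared dimension roles:
exactly one *sample* dimension, one or more *feature* dimensions
(flattened internally into a single feature axis of size p), and any
number of *search* dimensions that the high-level drivers loop over.
At most one search dimension may additionally be tagged
*generalization*.  Class labels may be arbitrary distinct integers;
they are re-coded internally to contiguous 1..K (ascending), and the
mapping is recorded.  For two classes the package follows the decoding
convention that class 1 is the positive class: decision values are
positive for class 1, probabilities are P(y=1|x), and the binary-only
metrics (AUC, dval, t-value) treat class 1 as positive.

## Classifiers

**Binary LDA.**  Classes are modelled as Gaussians with class means
m₁, m₂ and a shared covariance Σ.  The pooled covariance is estimated
from within-class-centered samples with denominator n−2 and
regularized by shrinkage toward a scaled identity,
Σ_reg = (1−λ)Σ + λνI with ν = tr(Σ)/p.  The scaled-identity target
preserves total variance, so λ interpolates between the empirical
covariance (λ=0) and an isotropic covariance of equal total variance
(λ=1).  λ defaults to the Ledoit–Wolf closed-form optimum computed on
the class-centered data: with S = Xc′Xc/n, ν = tr(S)/p,
d² = ‖S − νI‖²_F/p and b² = (1/n²p) Σ_k ‖x_k x_k′ − S‖²_F (clipped at
d²), λ* = b²/d².  The degenerate case d² = 0 (no dispersion around the
target, e.g. zero scatter) is defined as λ* = 1.  The weight vector
w ∝ Σ_reg⁻¹(m₁ − m₂) is rescaled so the projected class means sit at
±1 — a pure calibration of the decision-value scale that never changes
predictions — and the bias is b = −wᵀ(m₁+m₂)/2 + log(P₁/P₂), so equal
priors put the boundary at the geometric midpoint.  Priors default to
empirical class frequencies; `prior="equal"` forces uniform priors.
Posterior probabilities evaluate the two Gaussian likelihoods with the
shared Σ_reg and normalize.

**Multi-class LDA.**  Between-class scatter S_b (class-size-weighted,
about the grand mean) against the shrinkage-regularized within-class
scatter S_w defines the generalized eigenproblem S_b v = θ S_w v; the
leading K−1 eigenvectors span the discriminant subspace.  Prediction
uses the MAP rule under equal-covariance Gaussians *fitted in the
subspace* (pooled subspace covariance, denominator n−K).  This decision
rule was an open design choice; MAP was preferred over nearest-centroid
because it degenerates to nearest-centroid exactly when the subspace
covariance is isotropic and handles anisotropy correctly otherwise.
Two-class inputs are redirected to the binary implementation.

**Gaussian Naive Bayes.**  Per class and feature, univariate Gaussian
densities (maximum-likelihood variances).  Zero variances are floored
at 1e-10 × (mean feature variance) with a warning.  Posteriors are
computed in the log domain with log-sum-exp normalization.

**Logistic regression.**  Classes coded ±1; the loss is
Σ log(1+exp(−yᵢ(wᵀxᵢ+b))) plus either the negative log-F(1,1) prior
Σⱼ [log(1+e^{wⱼ}) − wⱼ/2] (default; hyperparameter-free, finite optimum
even on separable data) or λ‖w‖².  The bias is never penalized — the
log-F prior is a prior on effect sizes, not on the base rate.  The
solver is a damped Newton method (exact Hessian, tiny ridge for
safety, Armijo backtracking) stopping when the gradient norm falls
below `tol` (default 1e-6, max 200 iterations); non-convergence
returns the model with `converged_=False` and a warning.

**SVM.**  The soft-margin problem min ½‖w‖² + c Σξᵢ is solved in the
dual by coordinate descent with closed-form clipped updates (gradient
maintained incrementally, coordinates visited in a seeded random
permutation per sweep).  The bias is handled by augmenting the kernel
with a constant feature (K̃ = K + 1), which removes the dual equality
constraint and leaves the pure box problem 0 ≤ αᵢ ≤ c; consequently
the bias is regularized like a weight, the standard trade-off for
coordinate-descent solvers.  Stopping: maximal projected-gradient
violation ≤ `tol` (default 1e-3) or `max_sweeps` (default 5000; the
generous cap costs nothing once converged and covers slow tail
convergence on correlated data).  Class probabilities, when requested,
come from Platt's sigmoid 1/(1+exp(A·dval+B)) fitted on the training
decision values by the robust Newton procedure of Lin, Lin & Weng
(2007) with Platt's smoothed targets (N₊+1)/(N₊+2) and 1/(N₋+2), so
fitted probabilities never reach 0 or 1.  Calibrating on training
dvals slightly overstates confidence relative to a cross-validated
calibration set; the (A, B) fit itself is exact.

**Kernel methods.**  Kernels: linear x·x′, polynomial
(γ x·x′ + c₀)^d, RBF exp(−γ‖x−x′‖²); γ defaults to 1/p.  Kernel FDA
(two classes) forms the class kernel-mean vectors Mᵢ and the
within-class kernel scatter N = Σ_c K_c(I − (1/n_c)11′)K_c′ and solves
α = (N + λI)⁻¹(M₁ − M₂) with ridge λ (default 0.01) on N; the bias
centers the projected class means symmetrically, equivalent to binary
LDA with equal priors when the kernel is linear.  Precomputed kernel
matrices are accepted everywhere raw data is (train: n×n; test:
n_test×n_train), except under generalization, where each grid point
needs its own feature slice.

**Ensembles.**  Each learner sees a seeded random subset of samples
and features (subsets redrawn until at least two classes are present).
`vote` takes the plurality of predicted labels with ties broken toward
the smallest class label (deterministic); `dval` averages decision
values and takes the sign (two classes only).

## Regression

Ridge regression follows the convention that the intercept is a column
of ones inside X and is penalized with the rest of w; `center=True`
switches to the common alternative (center X and y, unpenalized
intercept).  `form="auto"` solves the primal (XᵀX + λI_p) system when
n ≥ p and the dual (XXᵀ + λI_n) otherwise — algebraically identical
solutions, different costs.  λ=0 reduces to OLS; singular systems at
λ=0 raise a numerical error rather than silently pseudo-inverting.
Kernel ridge solves (K + λI)α = y and predicts f(x) = Σ αᵢ k(xᵢ, x);
by default no constant is added to the kernel, so the linear kernel
reproduces the no-intercept dual ridge exactly.  Symmetric linear
systems go through LAPACK symmetric solvers.

## Cross-validation, preprocessing, tuning

Folds are assigned by seeded permutation; stratified k-fold (the
default when labels are present) splits each class separately into
chunks differing by at most one, with a per-class fold-offset rotation
so remainders spread across folds.  Repetitions re-randomize with
seed+r.  `cv="none"` trains and tests on all data and is reported as
such (biased upward; useful for diagnostics only).  Metrics are
computed per test fold, averaged across folds weighted by test-fold
size, then averaged across repetitions.

Preprocessing is strictly nested: every step derives its state
(means, sds, principal components, group assignments) from the
training fold and only transforms the test fold.  Sampling steps
(under-/oversampling) act on the training fold only, since rebalancing
the test fold would bias class-sensitive metrics.  Trial averaging
(`average_samples`) is applied to both folds, each grouped internally
with fresh seeded groups, because averaging raises SNR symmetrically;
remainder trials form a smaller final group.  Kernel averaging does
the analogous block-averaging on a precomputed kernel matrix.

Hyperparameter candidate lists trigger a grid search by inner k-fold
cross-validation (default 5-fold) on the training fold only; the
Cartesian product of candidates is scored by the configured metric
(mae/mse minimized, everything else maximized) and ties break toward
the first candidate in grid order.  The winner is refitted on the full
training fold.

## High-level drivers

`mv_classify`/`mv_regress` run the cross-validated analysis at every
combination of search-dimension indices.  One fold plan is generated
per run and shared across all grid points, which makes the diagonal of
a time×time generalization matrix exactly equal to the per-time
analysis.  Under generalization, preprocessing and model are fitted on
the training fold at train-point v and applied to the test fold at
every test point u; the first of the two result axes is the training
point.  Searchlight neighbourhoods are binary membership matrices per
search dimension (helpers build 1-D radius bands and 3-D cubes);
member positions' features are concatenated onto the feature axis, and
boundaries truncate — spatial and temporal axes are not periodic.
Weighted (non-binary) neighbourhoods are not supported.

## Statistics

*Binomial test*: exact tail P(X ≥ k), X ~ Binomial(n_test, chance),
k = round(accuracy·n_test).  *Level-1 permutation test*: the full
cross-validated analysis is rerun on globally shuffled targets
(shuffle-then-rerun keeps every source of variation inside the null);
elementwise p-values use the add-one rule
p = (1 + #{null ≥ observed})/(1 + B), so p ≥ 1/(1+B) and zero p-values
cannot occur.  *Cluster permutation test*: map elements exceeding a
critical value are grouped under orthogonal adjacency (4-connectivity
in 2-D, 6 in 3-D; custom structures accepted), the cluster statistic
is the suprathreshold mass (sum of member values; size available as an
option — mass is generally the more sensitive choice), and cluster
p-values compare against the permutation distribution of the *maximal*
cluster statistic, which controls the family-wise error over the map.
The critical value may be absolute (e.g. 0.6 for accuracy) or derived
as a quantile of the pooled null.  *Level-2 tests*: within-subject
designs reduce to per-subject differences (paired values, or value
minus null value) tested by mean, t, or Wilcoxon signed-rank
statistics, with the null generated by per-subject sign flips applied
to the subject's entire map (the subject is the exchangeability unit);
between-subject designs use mean-difference, pooled-variance t, or
rank-sum statistics with group labels permuted.  Default two-sided
p-values by |statistic|; one-sided tails available.

## Synthetic data: what it does and does not emulate

The generators produce the statistical structure the analyses assume —
Gaussian class clouds with common covariance and controllable
separation, epoched trials with a class-antisymmetric spatial pattern
planted in time windows over (optionally temporally smoothed) white
noise, y = Xw + ε regression data, and subject-level metric maps with
between-subject offsets.  They deliberately do not emulate volume
conduction, 1/f spectra, artifacts, non-stationarity, or hemodynamics;
passing tests therefore demonstrate correctness of the *algorithms*
and calibration of the *tests* under their stated assumptions, not
performance on real recordings.  All generators are pure functions of
their arguments including the seed.

## Calibration checks and problem sizes

The test suite verifies, among others: chance-level recovery of
multi-class LDA (10-fold CV, 5 repetitions, 20 simulation seeds;
n=300/K=3 and n=400/K=8, 30 features); the null AUC over 1000 draws of
100+100 standard-normal decision values; type-I error of the level-1
permutation test on 500 null datasets (n=24, p=4, 2-fold CV, 59
permutations) and of the level-2 within/between tests on 500 null
datasets (16 subjects, 99 permutations); and the family-wise error of
the cluster permutation test across a 50-element null map versus the
inflated elementwise testing.  These sizes were chosen so each check
has enough replications for its tolerance (±2 accuracy points, type-I
in [0.03, 0.07]) while the whole suite stays quick to run.  With few
permutations, ties between observed and permuted metric values (common
for coarse metrics such as accuracy at small n) make the add-one
p-value mildly conservative; AUC is used where that matters.

## Known limitations

Logistic regression and SVM are two-class (multi-class decoding uses
multiclass LDA, Naive Bayes, or nearest-centroid); multi-class kernel
FDA is not implemented; support vector regression, CSP, and Riemannian
features are out of scope; weighted searchlight neighbourhoods and
double generalization (two generalization dimensions) are not
supported.  The SVM's bias regularization (via kernel augmentation)
means very small c values shrink the bias too.
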