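"""Linear discriminant analysis with shrinkage-regularized covariance.

Two estimators are provided:

:class:`LDA`
    Binary LDA.  Classes are modelled as Gaussians with class means
    ``m_1, m_2`` and a common covariance ``Sigma``; the discriminant is
    ``dval = w.x + b`` with ``w = Sigma_reg^{-1} (m_1 - m_2)``.
:class:`MulticlassLDA`
    K >= 3 classes via a generalized eigendecomposition of between- vs
    within-class scatter, followed by a MAP rule in the (K-1)-dimensional
    discriminant subspace.

Regularization blends the empirical pooled covariance with a scaled
identity, ``Sigma_reg = (1 - lambda) Sigma + lambda nu I`` with
``nu = trace(Sigma)/p``, so the total variance is preserved.  The
shrinkage intensity defaults to the Ledoit-Wolf closed-form estimate.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
import scipy.special

from ..base import (
    BaseEstimator,
    ClassifierMixin,
    DataError,
    HyperparameterError,
    LabelError,
    NumericalError,
)
from ._common import binary_labels_from_dval, check_X_predict, check_Xy_classification


def ledoit_wolf_shrinkage(X_centered: np.ndarray) -> float:
    """Ledoit-Wolf optimal shrinkage toward a scaled identity target.

    Parameters
    ----------
    X_centered : (n, p) array
        Rows already centered (here: within class).  The sample
        covariance is ``S = X'X / n``.

    Returns
    -------
    float in [0, 1]. The degenerate case of zero dispersion of ``S``
    around its scaled-identity target returns 1 (full shrinkage).
    """
    X = np.asarray(X_centered, dtype=float)
    n, p = X.shape
    if n < 2:
        raise DataError("Ledoit-Wolf estimate needs at least 2 samples")
    S = X.T @ X / n
    nu = np.trace(S) / p
    # squared Frobenius distance of S from nu*I, normalized by p
    d2 = np.sum(S**2) / p - nu**2
    if d2 <= np.finfo(float).eps * max(1.0, nu**2):
        return 1.0
    X2 = X**2
    b2 = np.sum(X2.T @ X2 / n - S**2) / (p * n)
    b2 = min(b2, d2)
    return float(b2 / d2)


def _regularized_covariance(S_emp, lam, p):
    nu = np.trace(S_emp) / p
    return (1.0 - lam) * S_emp + lam * nu * np.eye(p)


def _resolve_lambda(lam, X_centered):
    if lam in (None, "auto"):
        return ledoit_wolf_shrinkage(X_centered)
    lam = float(lam)
    if not 0.0 <= lam <= 1.0:
        raise HyperparameterError(f"shrinkage lambda must be in [0, 1], got {lam}")
    return lam


def _spd_solve(A, B, context):
    try:
        c, low = scipy.linalg.cho_factor(A)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(
            f"{context}: covariance matrix is singular; "
            "increase the shrinkage hyperparameter lambda"
        ) from exc
    return scipy.linalg.cho_solve((c, low), B)


class LDA(BaseEstimator, ClassifierMixin):
    """Binary linear discriminant analysis with shrinkage regularization.

    Parameters
    ----------
    shrinkage : 'auto' or float in [0, 1]
        Shrinkage intensity lambda; 'auto' uses the Ledoit-Wolf formula.
    prior : {'empirical', 'equal'}
        Class priors P(y=i): empirical class frequencies or uniform.

    Attributes
    ----------
    w_ : (p,) weight vector, ``Sigma_reg^{-1} (m_1 - m_2)`` rescaled so
        the projected class means sit at +1 and -1 (the customary
        decision-value calibration; a positive rescaling never changes
        predictions)
    b_ : bias; ``-w.(m_1 + m_2)/2 + log(P(1)/P(2))``
    class_means_ : (2, p)
    cov_ : regularized pooled covariance
    lambda_ : shrinkage actually used
    priors_ : (2,)
    classes_ : (2,) original labels, ascending
    """

    def __init__(self, shrinkage="auto", prior="empirical"):
        self.shrinkage = shrinkage
        self.prior = prior

    def fit(self, X, y):
        X, yi, classes = check_Xy_classification(X, y, n_classes=2)
        n, p = X.shape
        m1 = X[yi == 1].mean(axis=0)
        m2 = X[yi == 2].mean(axis=0)
        Xc = X.copy()
        Xc[yi == 1] -= m1
        Xc[yi == 2] -= m2
        lam = _resolve_lambda(self.shrinkage, Xc)
        S_emp = Xc.T @ Xc / (n - 2)
        S_reg = _regularized_covariance(S_emp, lam, p)
        w = _spd_solve(S_reg, m1 - m2, "LDA")
        # scale so projected class means land at +-1 (dval calibration);
        # the denominator is a Mahalanobis distance, positive unless m1 = m2
        denom = w @ (m1 - m2)
        if denom > 1e-300:
            w = w * (2.0 / denom)
        if self.prior == "equal":
            priors = np.array([0.5, 0.5])
        else:
            priors = np.array([(yi == 1).mean(), (yi == 2).mean()])
        b = -w @ (m1 + m2) / 2.0 + np.log(priors[0] / priors[1])
        self.classes_ = classes
        self.class_means_ = np.vstack([m1, m2])
        self.cov_ = S_reg
        self.lambda_ = lam
        self.priors_ = priors
        self.w_ = w
        self.b_ = float(b)
        return self

    def decision_function(self, X):
        self._check_fitted("w_")
        X = check_X_predict(X, len(self.w_))
        return X @ self.w_ + self.b_

    def predict(self, X):
        return binary_labels_from_dval(self.decision_function(X), self.classes_)

    def predict_proba(self, X):
        """Posterior P(y=i|x) from Gaussian likelihoods with shared cov."""
        self._check_fitted("w_")
        X = check_X_predict(X, len(self.w_))
        log_post = np.empty((len(X), 2))
        for i in range(2):
            d = X - self.class_means_[i]
            sol = _spd_solve(self.cov_, d.T, "LDA").T
            log_post[:, i] = -0.5 * np.sum(d * sol, axis=1) + np.log(self.priors_[i])
        log_post -= scipy.special.logsumexp(log_post, axis=1, keepdims=True)
        return np.exp(log_post)

    def to_dict(self):
        return {
            "model": "lda",
            "w": self.w_.tolist(),
            "b": self.b_,
            "class_means": self.class_means_.tolist(),
            "cov": self.cov_.tolist(),
            "lambda": self.lambda_,
            "priors": self.priors_.tolist(),
            "classes": self.classes_.tolist(),
        }


class MulticlassLDA(BaseEstimator, ClassifierMixin):
    """Multi-class LDA: discriminant subspace + MAP classification.

    Fits the generalized eigenproblem ``S_b v = theta S_w_reg v`` where
    ``S_b``/``S_w`` are between/within-class scatter matrices, keeps the
    leading ``K - 1`` eigenvectors as the discriminant subspace, and
    classifies by the maximum posterior under equal-covariance Gaussians
    fitted in that subspace.

    Parameters as :class:`LDA`; requires K >= 3 (for two classes use
    :class:`LDA`, which is the more efficient special case).
    """

    def __init__(self, shrinkage="auto", prior="empirical"):
        self.shrinkage = shrinkage
        self.prior = prior

    def fit(self, X, y):
        if len(np.unique(np.asarray(y))) == 2:
            raise LabelError(
                "only two classes present: use the binary LDA classifier instead"
            )
        X, yi, classes = check_Xy_classification(X, y, min_classes=3)
        n, p = X.shape
        K = len(classes)
        means = np.vstack([X[yi == i + 1].mean(axis=0) for i in range(K)])
        counts = np.array([(yi == i + 1).sum() for i in range(K)])
        grand = X.mean(axis=0)
        Xc = X - means[yi - 1]
        lam = _resolve_lambda(self.shrinkage, Xc)
        S_w = Xc.T @ Xc / (n - K)
        S_w_reg = _regularized_covariance(S_w, lam, p)
        dm = means - grand
        S_b = (dm.T * counts) @ dm / n
        try:
            theta, V = scipy.linalg.eigh(S_b, S_w_reg)
        except scipy.linalg.LinAlgError as exc:
            raise NumericalError(
                "MulticlassLDA: within-class scatter is singular; "
                "increase the shrinkage hyperparameter lambda"
            ) from exc
        order = np.argsort(theta)[::-1][: K - 1]
        W = V[:, order]
        Z = X @ W
        centroids = np.vstack([Z[yi == i + 1].mean(axis=0) for i in range(K)])
        Zc = Z - centroids[yi - 1]
        S_sub = Zc.T @ Zc / (n - K)
        # guard against numerically tiny subspace variance
        S_sub += 1e-12 * np.trace(S_sub) / (K - 1) * np.eye(K - 1)
        if self.prior == "equal":
            priors = np.full(K, 1.0 / K)
        else:
            priors = counts / n
        self.classes_ = classes
        self.subspace_ = W
        self.centroids_ = centroids
        self.cov_sub_ = S_sub
        self.lambda_ = lam
        self.priors_ = priors
        self.n_features_ = p
        return self

    def _log_posterior(self, X):
        self._check_fitted("subspace_")
        X = check_X_predict(X, self.n_features_)
        Z = X @ self.subspace_
        K = len(self.classes_)
        log_post = np.empty((len(Z), K))
        for i in range(K):
            d = Z - self.centroids_[i]
            sol = _spd_solve(self.cov_sub_, d.T, "MulticlassLDA").T
            log_post[:, i] = -0.5 * np.sum(d * sol, axis=1) + np.log(self.priors_[i])
        return log_post

    def predict(self, X):
        return self.classes_[np.argmax(self._log_posterior(X), axis=1)]

    def predict_proba(self, X):
        lp = self._log_posterior(X)
        lp -= scipy.special.logsumexp(lp, axis=1, keepdims=True)
        return np.exp(lp)

    def transform(self, X):
        """Project onto the discriminant subspace (p -> K-1)."""
        self._check_fitted("subspace_")
        return check_X_predict(X, self.n_features_) @ self.subspace_
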