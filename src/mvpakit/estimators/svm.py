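"""Soft-margin support vector machine solved in the dual.

The primal problem ``min 1/2 ||w||^2 + c sum_i xi_i`` subject to
``y_i (w.x_i + b) >= 1 - xi_i`` is solved through its dual

    max_alpha  sum_i alpha_i - 1/2 sum_ij alpha_i alpha_j y_i y_j K_ij
    s.t.       0 <= alpha_i <= c

by dual coordinate descent (closed-form clipped single-coordinate
updates).  The bias is handled by augmenting the kernel with a constant
feature, ``K~ = K + 1``, which removes the dual equality constraint and
leaves a pure box problem; the bias is then ``b = sum_i alpha_i y_i``.
Kernels beyond linear are supported through the same dual.

Probabilities, if requested, come from Platt's sigmoid
``P(y=1 | dval) = 1 / (1 + exp(A dval + B))`` fitted on the training
decision values by regularized maximum likelihood with smoothed targets.
"""

from __future__ import annotations

import numpy as np

from ..base import (
    BaseEstimator,
    CalibrationError,
    ClassifierMixin,
    HyperparameterError,
)
from ..kernels import KernelSpec, as_kernel_spec, compute_kernel_matrix
from ._common import binary_labels_from_dval, check_X_predict, check_Xy_classification


def fit_platt(dvals, labels, max_iter=100, tol=1e-10):
    """Fit Platt sigmoid parameters (A, B) to decision values.

    Implements the robust Newton procedure of Lin, Lin & Weng (2007)
    with Platt's smoothed targets ``t+ = (N+ + 1)/(N+ + 2)`` and
    ``t- = 1/(N- + 2)``, so fitted probabilities stay strictly inside
    (0, 1).

    Parameters
    ----------
    dvals : (n,) decision values
    labels : (n,) with the positive class coded 1 (anything else is
        treated as the negative class)

    Returns
    -------
    (A, B) : floats; ``P(y=1|d) = 1 / (1 + exp(A d + B))``
    """
    d = np.asarray(dvals, dtype=float)
    y = np.asarray(labels)
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError("Platt calibration needs both classes present")
    if np.ptp(d) == 0:
        raise CalibrationError("degenerate decision values (all equal)")
    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    A, B = 0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))
    sigma = 1e-12  # Hessian ridge

    def fval(a, b):
        z = a * d + b
        # cross-entropy with targets t, stable for both signs of z
        return float(np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-z)),
                                     (t - 1.0) * z + np.log1p(np.exp(z)))))

    f = fval(A, B)
    for _ in range(max_iter):
        z = A * d + B
        p = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)),
                     1.0 / (1.0 + np.exp(z)))  # P(y=1)
        q = 1.0 - p
        g1 = float(np.sum(d * (t - p)))
        g2 = float(np.sum(t - p))
        if abs(g1) < tol and abs(g2) < tol:
            break
        w = p * q
        h11 = float(np.sum(d * d * w)) + sigma
        h22 = float(np.sum(w)) + sigma
        h21 = float(np.sum(d * w))
        det = h11 * h22 - h21 * h21
        dA = -(h22 * g1 - h21 * g2) / det
        dB = -(-h21 * g1 + h11 * g2) / det
        gd = g1 * dA + g2 * dB
        step = 1.0
        while step >= 1e-10:
            newA, newB = A + step * dA, B + step * dB
            newf = fval(newA, newB)
            if newf < f + 1e-4 * step * gd:
                A, B, f = newA, newB, newf
                break
            step /= 2.0
        else:
            break
    return float(A), float(B)


def platt_probability(dvals, A, B):
    z = A * np.asarray(dvals, dtype=float) + B
    return np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))


class SVM(BaseEstimator, ClassifierMixin):
    """Two-class L1 soft-margin SVM via dual coordinate descent.

    Parameters
    ----------
    c : float > 0, box constraint (regularization; larger = harder margin)
    kernel : 'linear' | 'polynomial' | 'rbf' | 'precomputed' | KernelSpec
    gamma, degree, coef0 : kernel parameters (see ``KernelSpec``)
    tol : maximal projected-gradient violation at convergence
    max_sweeps : cap on passes over the coordinates
    probability : fit a Platt sigmoid on training decision values
    shuffle_seed : seed for the coordinate-order permutation

    Attributes
    ----------
    alpha_ : (n,) dual coefficients in [0, c]
    support_ : indices with alpha > 0
    w_ : explicit weights (linear kernel only)
    b_ : bias
    platt_ : (A, B) or None
    """

    def __init__(
        self,
        c=1.0,
        kernel="linear",
        gamma=None,
        degree=2,
        coef0=0.0,
        tol=1e-3,
        max_sweeps=5000,
        probability=False,
        shuffle_seed=0,
    ):
        self.c = c
        self.kernel = kernel
        self.gamma = gamma
        self.degree = degree
        self.coef0 = coef0
        self.tol = tol
        self.max_sweeps = max_sweeps
        self.probability = probability
        self.shuffle_seed = shuffle_seed

    def _spec(self) -> KernelSpec:
        if isinstance(self.kernel, KernelSpec):
            return self.kernel
        return KernelSpec(
            kind=self.kernel, gamma=self.gamma, degree=self.degree, coef0=self.coef0
        )

    def fit(self, X, y):
        if self.c <= 0:
            raise HyperparameterError("SVM box constraint c must be > 0")
        X, yi, classes = check_Xy_classification(X, y, n_classes=2)
        y_pm = np.where(yi == 1, 1.0, -1.0)
        n = len(y_pm)
        spec = self._spec()
        K = compute_kernel_matrix(spec, X)
        Q = (K + 1.0) * np.outer(y_pm, y_pm)  # +1: constant-feature bias
        Qdiag = np.diag(Q).copy()
        alpha = np.zeros(n)
        G = np.full(n, -1.0)  # gradient of 1/2 a'Qa - e'a at a=0
        rng = np.random.default_rng(self.shuffle_seed)
        for sweep in range(self.max_sweeps):
            max_violation = 0.0
            for i in rng.permutation(n):
                g = G[i]
                if alpha[i] <= 0.0:
                    pg = min(g, 0.0)
                elif alpha[i] >= self.c:
                    pg = max(g, 0.0)
                else:
                    pg = g
                if pg != 0.0:
                    max_violation = max(max_violation, abs(pg))
                    if Qdiag[i] > 0:
                        new = min(max(alpha[i] - g / Qdiag[i], 0.0), self.c)
                    else:
                        new = self.c if g < 0 else 0.0
                    delta = new - alpha[i]
                    if delta != 0.0:
                        alpha[i] = new
                        G += delta * Q[:, i]
            if max_violation <= self.tol:
                break
        self.classes_ = classes
        self.alpha_ = alpha
        self.support_ = np.flatnonzero(alpha > 0)
        self.b_ = float(alpha @ y_pm)
        self._y_pm = y_pm
        self._spec_fitted = spec
        self._X_train = None if spec.kind == "precomputed" else X
        self.n_features_ = X.shape[1]
        if spec.kind == "linear":
            self.w_ = (alpha * y_pm) @ X
        else:
            self.w_ = None
        self.platt_ = None
        if self.probability:
            dv = self._decision_from_kernel(K)
            self.platt_ = fit_platt(dv, yi)
        return self

    def _decision_from_kernel(self, K_test_train):
        return K_test_train @ (self.alpha_ * self._y_pm) + self.b_

    def decision_function(self, X):
        self._check_fitted("alpha_")
        spec = self._spec_fitted
        if spec.kind == "precomputed":
            K = np.asarray(X, dtype=float)
        else:
            X = check_X_predict(X, self.n_features_)
            K = compute_kernel_matrix(spec, X, self._X_train)
        return self._decision_from_kernel(K)

    def predict(self, X):
        return binary_labels_from_dval(self.decision_function(X), self.classes_)

    def predict_proba(self, X):
        self._check_fitted("alpha_")
        if self.platt_ is None:
            raise CalibrationError(
                "probabilities not available: fit with probability=True"
            )
        p1 = platt_probability(self.decision_function(X), *self.platt_)
        return np.column_stack([p1, 1.0 - p1])

    def dual_objective(self):
        """Dual objective value at the current solution (for diagnostics)."""
        self._check_fitted("alpha_")
        K = compute_kernel_matrix(self._spec_fitted, self._X_train)
        Q = (K + 1.0) * np.outer(self._y_pm, self._y_pm)
        return float(self.alpha_.sum() - 0.5 * self.alpha_ @ Q @ self.alpha_)
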