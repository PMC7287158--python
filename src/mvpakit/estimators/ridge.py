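"""Ridge regression (primal/dual) and kernel ridge regression.

The ridge loss ``L(w) = ||y - Xw||^2 + lambda ||w||^2`` has two
algebraically equivalent closed-form minimizers,

    w = (X'X + lambda I_p)^{-1} X'y          (primal, cost ~ p^3)
    w = X'(XX' + lambda I_n)^{-1} y          (dual,   cost ~ n^3)

and ``form='auto'`` picks whichever system is smaller.  ``lambda = 0``
reduces to ordinary least squares.  Following the usual formalism, the
intercept is realized as a column of ones appended to X and penalized
with the rest of the weights; ``center=True`` instead centers X and y
and leaves the intercept unpenalized.

Kernel ridge solves ``alpha = (K + lambda I_n)^{-1} y`` and predicts
``f(x) = sum_i alpha_i k(x_i, x)``.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from ..base import (
    BaseEstimator,
    HyperparameterError,
    NumericalError,
    RegressorMixin,
    StructuralError,
)
from ..kernels import KernelSpec, compute_kernel_matrix
from ._common import check_X_predict


def _check_Xy_regression(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise StructuralError("X must be 2-D [samples x features]")
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != X.shape[0]:
        raise StructuralError("y must be a 1-D vector matching the sample count")
    return X, y


def _solve(A, B, context):
    try:
        w = scipy.linalg.solve(A, B, assume_a="sym")
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(f"{context}: singular system; use lambda > 0") from exc
    if not np.all(np.isfinite(w)):
        raise NumericalError(f"{context}: singular system; use lambda > 0")
    return w


class Ridge(BaseEstimator, RegressorMixin):
    """Linear ridge regression with automatic primal/dual switching.

    Parameters
    ----------
    lambda_ : float >= 0
    form : {'auto', 'primal', 'dual'}
        'auto' picks primal when n >= p (after intercept augmentation),
        dual otherwise; the choice never changes the solution.
    fit_intercept : append a ones column to X (intercept penalized)
    center : center X and y instead, leaving the intercept unpenalized

    Attributes
    ----------
    w_ : weights (intercept last when fit_intercept and not center)
    intercept_ : scalar intercept
    form_used_ : 'primal' or 'dual'
    """

    def __init__(self, lambda_=0.0, form="auto", fit_intercept=True, center=False):
        self.lambda_ = lambda_
        self.form = form
        self.fit_intercept = fit_intercept
        self.center = center

    def fit(self, X, y):
        if self.lambda_ < 0:
            raise HyperparameterError("lambda must be >= 0")
        if self.form not in ("auto", "primal", "dual"):
            raise HyperparameterError(f"unknown form {self.form!r}")
        X, y = _check_Xy_regression(X, y)
        n, p = X.shape
        if self.center:
            x_mean = X.mean(axis=0)
            y_mean = y.mean()
            Xa, ya = X - x_mean, y - y_mean
        else:
            x_mean = None
            y_mean = 0.0
            Xa = np.hstack([X, np.ones((n, 1))]) if self.fit_intercept else X
            ya = y
        pa = Xa.shape[1]
        form = self.form
        if form == "auto":
            form = "primal" if n >= pa else "dual"
        lam = float(self.lambda_)
        if form == "primal":
            w = _solve(Xa.T @ Xa + lam * np.eye(pa), Xa.T @ ya, "ridge (primal)")
        else:
            w = Xa.T @ _solve(Xa @ Xa.T + lam * np.eye(n), ya, "ridge (dual)")
        if self.center:
            self.coef_ = w
            self.intercept_ = float(y_mean - x_mean @ w)
        elif self.fit_intercept:
            self.coef_ = w[:-1]
            self.intercept_ = float(w[-1])
        else:
            self.coef_ = w
            self.intercept_ = 0.0
        self.w_ = w
        self.form_used_ = form
        self.n_features_ = p
        return self

    def predict(self, X):
        self._check_fitted("coef_")
        X = check_X_predict(X, self.n_features_)
        return X @ self.coef_ + self.intercept_


class KernelRidge(BaseEstimator, RegressorMixin):
    """Kernel ridge regression in the dual.

    Parameters
    ----------
    lambda_ : float >= 0 (> 0 required when K is singular)
    kernel : 'linear' | 'polynomial' | 'rbf' | 'precomputed' | KernelSpec
    gamma, degree, coef0 : kernel parameters
    fit_intercept : optionally add the constant 1 to the kernel,
        mirroring a ones-column in the linear model; off by default so
        that ``alpha`` solves ``(K + lambda I) alpha = y`` for the plain
        kernel matrix

    Attributes
    ----------
    alpha_ : (n,) dual weights solving (K + lambda I) alpha = y
    """

    def __init__(
        self, lambda_=0.0, kernel="linear", gamma=None, degree=2, coef0=0.0,
        fit_intercept=False,
    ):
        self.lambda_ = lambda_
        self.kernel = kernel
        self.gamma = gamma
        self.degree = degree
        self.coef0 = coef0
        self.fit_intercept = fit_intercept

    def _spec(self) -> KernelSpec:
        if isinstance(self.kernel, KernelSpec):
            return self.kernel
        return KernelSpec(
            kind=self.kernel, gamma=self.gamma, degree=self.degree, coef0=self.coef0
        )

    def fit(self, X, y):
        if self.lambda_ < 0:
            raise HyperparameterError("lambda must be >= 0")
        X, y = _check_Xy_regression(np.asarray(X, dtype=float), y)
        spec = self._spec()
        K = compute_kernel_matrix(spec, X)
        if self.fit_intercept:
            K = K + 1.0
        n = K.shape[0]
        self.alpha_ = _solve(K + self.lambda_ * np.eye(n), y, "kernel ridge")
        self._spec_fitted = spec
        self._X_train = None if spec.kind == "precomputed" else X
        self.n_features_ = X.shape[1]
        return self

    def predict(self, X):
        self._check_fitted("alpha_")
        spec = self._spec_fitted
        if spec.kind == "precomputed":
            K = np.asarray(X, dtype=float)
        else:
            X = check_X_predict(X, self.n_features_)
            K = compute_kernel_matrix(spec, X, self._X_train)
        if self.fit_intercept:
            K = K + 1.0
        return K @ self.alpha_
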