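"""Kernel Fisher discriminant analysis (two classes, Mika formulation).

Working entirely with the kernel matrix ``K`` of the training data, let
``M_i`` be the kernel mean vector of class i (mean of the columns of K
belonging to class i) and

    N = sum_c K_c (I - (1/n_c) 11') K_c'

the within-class kernel scatter, where ``K_c`` holds the columns of
class c.  The dual discriminant direction is

    alpha = (N + lambda I)^{-1} (M_1 - M_2)

and decision values are ``dval(x) = sum_i alpha_i k(x_i, x) + b`` with
the bias centering the projected class means symmetrically around zero.
A small ridge ``lambda`` (default 0.01) keeps N well-conditioned.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from ..base import BaseEstimator, ClassifierMixin, HyperparameterError, NumericalError
from ..kernels import KernelSpec, compute_kernel_matrix
from ._common import binary_labels_from_dval, check_X_predict, check_Xy_classification


class KernelFDA(BaseEstimator, ClassifierMixin):
    """Binary kernel Fisher discriminant.

    Parameters
    ----------
    lambda_ : float >= 0, ridge added to the within-class kernel scatter
    kernel : 'linear' | 'polynomial' | 'rbf' | 'precomputed' | KernelSpec
    gamma, degree, coef0 : kernel parameters

    Attributes
    ----------
    alpha_ : (n,) dual weights; b_ : bias; classes_
    """

    def __init__(self, lambda_=0.01, kernel="linear", gamma=None, degree=2, coef0=0.0):
        self.lambda_ = lambda_
        self.kernel = kernel
        self.gamma = gamma
        self.degree = degree
        self.coef0 = coef0

    def _spec(self) -> KernelSpec:
        if isinstance(self.kernel, KernelSpec):
            return self.kernel
        return KernelSpec(
            kind=self.kernel, gamma=self.gamma, degree=self.degree, coef0=self.coef0
        )

    def fit(self, X, y):
        if self.lambda_ < 0:
            raise HyperparameterError("lambda must be >= 0")
        X, yi, classes = check_Xy_classification(X, y, n_classes=2)
        spec = self._spec()
        K = compute_kernel_matrix(spec, X)
        n = K.shape[0]
        M = []
        N = np.zeros((n, n))
        for cls in (1, 2):
            idx = np.flatnonzero(yi == cls)
            Kc = K[:, idx]
            M.append(Kc.mean(axis=1))
            N += Kc @ Kc.T - len(idx) * np.outer(Kc.mean(axis=1), Kc.mean(axis=1))
        A = N + self.lambda_ * np.eye(n)
        try:
            alpha = scipy.linalg.solve(A, M[0] - M[1], assume_a="sym")
        except scipy.linalg.LinAlgError as exc:
            raise NumericalError(
                "KFDA: within-class kernel scatter is singular; use lambda > 0"
            ) from exc
        if not np.all(np.isfinite(alpha)):
            raise NumericalError(
                "KFDA: within-class kernel scatter is singular; use lambda > 0"
            )
        self.classes_ = classes
        self.alpha_ = alpha
        self.b_ = float(-alpha @ (M[0] + M[1]) / 2.0)
        self._spec_fitted = spec
        self._X_train = None if spec.kind == "precomputed" else X
        self.n_features_ = X.shape[1]
        return self

    def decision_function(self, X):
        self._check_fitted("alpha_")
        spec = self._spec_fitted
        if spec.kind == "precomputed":
            K = np.asarray(X, dtype=float)
        else:
            X = check_X_predict(X, self.n_features_)
            K = compute_kernel_matrix(spec, X, self._X_train)
        return K @ self.alpha_ + self.b_

    def predict(self, X):
        return binary_labels_from_dval(self.decision_function(X), self.classes_)
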