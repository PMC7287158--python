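"""Binary logistic regression with log-F(1,1) or L2 regularization.

With classes coded +1/-1, the model is
``P(y = +-1 | x) = 1 / (1 + exp(-y (w.x + b)))`` and training minimizes
the logistic loss ``sum_i log(1 + exp(-y_i (w.x_i + b)))`` plus a
penalty:

``reg='logf'``
    the negative log-F(1,1) prior ``sum_j [log(1 + e^{w_j}) - w_j/2]``
    (Jeffrey's-prior/Firth-style penalty; hyperparameter-free, keeps the
    optimum finite even on separable data).
``reg='l2'``
    ``lambda * ||w||^2`` with ``lambda >= 0``.

The bias is never penalized.  Optimization is a damped Newton method
with Armijo backtracking line search.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg
import scipy.special

from ..base import (
    BaseEstimator,
    ClassifierMixin,
    ConfigurationError,
    HyperparameterError,
)
from ._common import binary_labels_from_dval, check_X_predict, check_Xy_classification


def _log1pexp(z):
    """Numerically stable log(1 + exp(z))."""
    out = np.empty_like(z, dtype=float)
    pos = z > 0
    out[pos] = z[pos] + np.log1p(np.exp(-z[pos]))
    out[~pos] = np.log1p(np.exp(z[~pos]))
    return out


def _sigmoid(z):
    return scipy.special.expit(z)


class LogisticRegression(BaseEstimator, ClassifierMixin):
    """Penalized binary logistic regression.

    Parameters
    ----------
    reg : {'logf', 'l2'}
    lambda_ : float >= 0, L2 penalty strength (ignored for 'logf')
    tol : gradient-norm stopping tolerance
    max_iter : Newton iteration cap

    Attributes
    ----------
    w_, b_, converged_, n_iter_, classes_
    """

    def __init__(self, reg="logf", lambda_=1.0, tol=1e-6, max_iter=200):
        self.reg = reg
        self.lambda_ = lambda_
        self.tol = tol
        self.max_iter = max_iter

    # -- objective pieces -------------------------------------------------
    def _penalty(self, w):
        if self.reg == "logf":
            return float(np.sum(_log1pexp(w) - 0.5 * w))
        return float(self.lambda_ * np.sum(w**2))

    def _penalty_grad_hess(self, w):
        if self.reg == "logf":
            s = _sigmoid(w)
            return s - 0.5, s * (1.0 - s)
        return 2.0 * self.lambda_ * w, np.full_like(w, 2.0 * self.lambda_)

    def objective(self, w, b, X, y_pm):
        """Full training objective at (w, b); y_pm coded +-1."""
        margins = y_pm * (X @ w + b)
        return float(np.sum(_log1pexp(-margins))) + self._penalty(w)

    def fit(self, X, y):
        if self.reg not in ("logf", "l2"):
            raise ConfigurationError(f"unknown regularization {self.reg!r}")
        if self.reg == "l2" and self.lambda_ < 0:
            raise HyperparameterError("lambda must be >= 0")
        X, yi, classes = check_Xy_classification(X, y, n_classes=2)
        y_pm = np.where(yi == 1, 1.0, -1.0)
        n, p = X.shape
        Xa = np.hstack([X, np.ones((n, 1))])  # bias as last coordinate
        theta = np.zeros(p + 1)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            margins = y_pm * (Xa @ theta)
            s = _sigmoid(-margins)  # d loss / d margin = -sigma(-m)
            grad = -Xa.T @ (y_pm * s)
            d = s * (1.0 - s)
            H = Xa.T @ (Xa * d[:, None])
            pg, ph = self._penalty_grad_hess(theta[:p])
            grad[:p] += pg
            H[:p, :p] += np.diag(ph)
            gnorm = np.linalg.norm(grad)
            if gnorm <= self.tol:
                converged = True
                break
            H[np.diag_indices_from(H)] += 1e-10 * (1.0 + np.trace(H) / (p + 1))
            try:
                step = scipy.linalg.solve(H, grad, assume_a="pos")
            except scipy.linalg.LinAlgError:
                step = grad
            # Armijo backtracking
            f0 = self.objective(theta[:p], theta[p], X, y_pm)
            t = 1.0
            descent = grad @ step
            for _ in range(50):
                cand = theta - t * step
                if (
                    self.objective(cand[:p], cand[p], X, y_pm)
                    <= f0 - 1e-4 * t * descent
                ):
                    break
                t *= 0.5
            theta = theta - t * step
        else:
            margins = y_pm * (Xa @ theta)
            s = _sigmoid(-margins)
            grad = -Xa.T @ (y_pm * s)
            grad[:p] += self._penalty_grad_hess(theta[:p])[0]
            converged = np.linalg.norm(grad) <= self.tol
        if not converged:
            warnings.warn(
                "logistic regression did not converge; consider raising max_iter",
                RuntimeWarning,
                stacklevel=2,
            )
        self.classes_ = classes
        self.w_ = theta[:p]
        self.b_ = float(theta[p])
        self.converged_ = bool(converged)
        self.n_iter_ = it
        return self

    def decision_function(self, X):
        self._check_fitted("w_")
        X = check_X_predict(X, len(self.w_))
        return X @ self.w_ + self.b_

    def predict_proba(self, X):
        """Columns [P(class 1), P(class 2)]."""
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([p1, 1.0 - p1])

    def predict(self, X):
        return binary_labels_from_dval(self.decision_function(X), self.classes_)
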