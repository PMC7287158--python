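"""Gaussian Naive Bayes.

Features are assumed conditionally independent given the class, each
modelled as a univariate Gaussian ``N(m_ij, s2_ij)`` for class i and
feature j; equivalently, each class has a diagonal covariance matrix.
The posterior is computed in the log domain and prediction follows the
MAP rule.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.special

from ..base import BaseEstimator, ClassifierMixin, DataError
from ._common import check_X_predict, check_Xy_classification

_LOG_2PI = float(np.log(2.0 * np.pi))


class GaussianNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-class, per-feature Gaussian densities.

    Parameters
    ----------
    prior : {'empirical', 'equal'}
    var_floor_rel : float
        Zero variances are floored to ``var_floor_rel * mean feature
        variance`` (a tiny absolute floor is used if that is zero too).

    Attributes
    ----------
    means_ : (K, p); variances_ : (K, p); priors_ : (K,); classes_ : (K,)
    """

    def __init__(self, prior="empirical", var_floor_rel=1e-10):
        self.prior = prior
        self.var_floor_rel = var_floor_rel

    def fit(self, X, y):
        X, yi, classes = check_Xy_classification(X, y)
        K = len(classes)
        counts = np.array([(yi == i + 1).sum() for i in range(K)])
        if np.any(counts < 2):
            raise DataError("Naive Bayes needs at least 2 samples per class")
        means = np.vstack([X[yi == i + 1].mean(axis=0) for i in range(K)])
        variances = np.vstack([X[yi == i + 1].var(axis=0) for i in range(K)])
        floor = self.var_floor_rel * max(X.var(axis=0).mean(), 0.0)
        floor = max(floor, np.finfo(float).tiny * 1e10)
        if np.any(variances < floor):
            warnings.warn(
                "zero-variance feature(s) encountered; variance floored",
                RuntimeWarning,
                stacklevel=2,
            )
            variances = np.maximum(variances, floor)
        self.classes_ = classes
        self.means_ = means
        self.variances_ = variances
        self.priors_ = (
            np.full(K, 1.0 / K) if self.prior == "equal" else counts / counts.sum()
        )
        return self

    def _log_posterior(self, X):
        self._check_fitted("means_")
        X = check_X_predict(X, self.means_.shape[1])
        K = len(self.classes_)
        lp = np.empty((len(X), K))
        for i in range(K):
            z2 = (X - self.means_[i]) ** 2 / self.variances_[i]
            log_lik = -0.5 * np.sum(
                z2 + np.log(self.variances_[i]) + _LOG_2PI, axis=1
            )
            lp[:, i] = log_lik + np.log(self.priors_[i])
        return lp

    def predict(self, X):
        return self.classes_[np.argmax(self._log_posterior(X), axis=1)]

    def predict_proba(self, X):
        lp = self._log_posterior(X)
        lp -= scipy.special.logsumexp(lp, axis=1, keepdims=True)
        return np.exp(lp)

    def decision_function(self, X):
        """Two classes only: log-posterior difference (class 1 - class 2)."""
        lp = self._log_posterior(X)
        if lp.shape[1] != 2:
            raise DataError("decision values are defined for two classes only")
        return lp[:, 0] - lp[:, 1]
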