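"""Nearest-centroid prototype classifier.

Doubles as the worked example of the custom-model extension point: any
object with ``fit``/``predict`` (and optionally ``decision_function``)
can be registered under a model name and then used everywhere a
built-in model is accepted (cross-validation, tuning, high-level
drivers).
"""

from __future__ import annotations

import numpy as np

from ..base import BaseEstimator, ClassifierMixin, DataError
from ._common import check_X_predict, check_Xy_classification


class NearestCentroid(BaseEstimator, ClassifierMixin):
    """Assign each sample to the class with the closest (Euclidean) centroid."""

    def fit(self, X, y):
        X, yi, classes = check_Xy_classification(X, y)
        self.classes_ = classes
        self.centroids_ = np.vstack(
            [X[yi == i + 1].mean(axis=0) for i in range(len(classes))]
        )
        self.n_features_ = X.shape[1]
        return self

    def _distances(self, X):
        self._check_fitted("centroids_")
        X = check_X_predict(X, self.n_features_)
        diff = X[:, None, :] - self.centroids_[None, :, :]
        return np.sqrt(np.sum(diff**2, axis=2))

    def predict(self, X):
        return self.classes_[np.argmin(self._distances(X), axis=1)]

    def decision_function(self, X):
        """Two classes: d(x, centroid_2) - d(x, centroid_1); positive -> class 1."""
        d = self._distances(X)
        if d.shape[1] != 2:
            raise DataError("decision values are defined for two classes only")
        return d[:, 1] - d[:, 0]
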