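"""Ensemble meta-classifier.

Trains many copies of a base learner, each on a random subset of the
training samples and features, and combines their outputs either by
plurality vote over predicted labels (``strategy='vote'``) or by the
sign of the mean decision value (``strategy='dval'``, two classes and
dval-capable learners only).  Vote ties go to the smallest class label.
"""

from __future__ import annotations

import numpy as np

from ..base import BaseEstimator, ClassifierMixin, ConfigurationError
from ._common import check_X_predict, check_Xy_classification


class Ensemble(BaseEstimator, ClassifierMixin):
    """Subspace/subsample ensemble.

    Parameters
    ----------
    learner : estimator instance used as prototype (cloned per learner)
        or a model name resolvable by the model registry.
    n_learners : number of learners
    nsamples, nfeatures : subset sizes per learner; ``None`` = all, a
        float in (0, 1) = fraction.
    strategy : {'vote', 'dval'}
    random_state : seed for the subset draws

    Attributes
    ----------
    learners_ : list of fitted learners
    sample_idx_, feature_idx_ : per-learner index subsets
    """

    def __init__(
        self,
        learner="lda",
        n_learners=10,
        nsamples=None,
        nfeatures=None,
        strategy="vote",
        random_state=0,
    ):
        self.learner = learner
        self.n_learners = n_learners
        self.nsamples = nsamples
        self.nfeatures = nfeatures
        self.strategy = strategy
        self.random_state = random_state

    def _prototype(self):
        if isinstance(self.learner, str):
            from ..models import get_model

            return get_model(self.learner)
        return self.learner

    @staticmethod
    def _resolve_size(size, total):
        if size is None:
            return total
        if isinstance(size, float) and 0 < size < 1:
            return max(1, int(round(size * total)))
        size = int(size)
        if not 1 <= size <= total:
            raise ConfigurationError(f"subset size {size} outside [1, {total}]")
        return size

    def fit(self, X, y):
        if self.strategy not in ("vote", "dval"):
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")
        X, yi, classes = check_Xy_classification(X, y)
        n, p = X.shape
        ns = self._resolve_size(self.nsamples, n)
        nf = self._resolve_size(self.nfeatures, p)
        rng = np.random.default_rng(self.random_state)
        proto = self._prototype()
        learners, sample_idx, feature_idx = [], [], []
        for _ in range(self.n_learners):
            for _attempt in range(100):
                si = rng.choice(n, size=ns, replace=False)
                if len(np.unique(yi[si])) >= 2:
                    break
            else:
                raise ConfigurationError(
                    "could not draw a sample subset containing >= 2 classes"
                )
            fi = np.sort(rng.choice(p, size=nf, replace=False))
            model = type(proto)(**proto.get_params())
            model.fit(X[np.ix_(si, fi)], yi[si])
            learners.append(model)
            sample_idx.append(si)
            feature_idx.append(fi)
        if self.strategy == "dval":
            if len(classes) != 2:
                raise ConfigurationError("strategy 'dval' needs two classes")
            if not all(hasattr(m, "decision_function") for m in learners):
                raise ConfigurationError(
                    "strategy 'dval' needs learners with decision values"
                )
        self.classes_ = classes
        self.learners_ = learners
        self.sample_idx_ = sample_idx
        self.feature_idx_ = feature_idx
        self.n_features_ = p
        return self

    def decision_function(self, X):
        self._check_fitted("learners_")
        if self.strategy != "dval":
            raise ConfigurationError("decision values only with strategy 'dval'")
        X = check_X_predict(X, self.n_features_)
        dv = np.mean(
            [m.decision_function(X[:, fi]) for m, fi in zip(self.learners_, self.feature_idx_)],
            axis=0,
        )
        return dv

    def predict(self, X):
        self._check_fitted("learners_")
        X = check_X_predict(X, self.n_features_)
        if self.strategy == "dval":
            dv = self.decision_function(X)
            return np.where(dv >= 0, self.classes_[0], self.classes_[1])
        K = len(self.classes_)
        votes = np.zeros((len(X), K), dtype=int)
        for m, fi in zip(self.learners_, self.feature_idx_):
            pred = m.predict(X[:, fi])  # internal labels 1..K
            for k in range(K):
                votes[:, k] += pred == k + 1
        # argmax returns the first (= smallest class index) on ties
        return self.classes_[np.argmax(votes, axis=1)]
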