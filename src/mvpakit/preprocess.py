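"""Nested preprocessing with fit-on-train / apply-to-test semantics.

Every step derives its fitted state (means, standard deviations,
principal components, group assignments) exclusively from the training
fold; the test fold is only ever *transformed*.  Sampling steps
(under-/oversampling) alter the training set only — rebalancing the
test fold would bias any class-sensitive metric.

Steps operate on ``(X, targets)`` pairs and return transformed pairs,
since sampling and averaging steps change the targets too.
"""

from __future__ import annotations

import warnings

import numpy as np

from .base import ConfigurationError, MVPAError, StructuralError


class PreprocessStep:
    """Base class: fit on the training fold, transform either fold."""

    #: steps that only resample the training set leave the test fold alone
    train_only = False

    def fit_transform_train(self, X, targets):
        raise NotImplementedError

    def transform_test(self, X, targets):
        raise NotImplementedError

    def _require_fitted(self, attr):
        if not hasattr(self, attr):
            raise MVPAError(f"{type(self).__name__} has not been fitted")


class ZScore(PreprocessStep):
    """Standardize each feature using training-fold mean and sd.

    Zero-variance features get sd floored to 1 (with a warning)."""

    def fit_transform_train(self, X, targets):
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        if np.any(sd == 0):
            warnings.warn(
                "zero-variance feature(s); sd floored to 1", RuntimeWarning,
                stacklevel=2,
            )
            sd = np.where(sd == 0, 1.0, sd)
        self.sd_ = sd
        return (X - self.mean_) / self.sd_, targets

    def transform_test(self, X, targets):
        self._require_fitted("mean_")
        return (X - self.mean_) / self.sd_, targets


class Demean(PreprocessStep):
    def fit_transform_train(self, X, targets):
        self.mean_ = X.mean(axis=0)
        return X - self.mean_, targets

    def transform_test(self, X, targets):
        self._require_fitted("mean_")
        return X - self.mean_, targets


class PCA(PreprocessStep):
    """Project onto the top principal components of the training data."""

    def __init__(self, n_components=None):
        self.n_components = n_components

    def fit_transform_train(self, X, targets):
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if len(s) else 0
        k = self.n_components or rank
        if k > rank:
            warnings.warn(
                f"n_components={k} exceeds rank {rank}; clipped", RuntimeWarning,
                stacklevel=2,
            )
            k = rank
        self.components_ = Vt[:k]
        return Xc @ self.components_.T, targets

    def transform_test(self, X, targets):
        self._require_fitted("components_")
        return (X - self.mean_) @ self.components_.T, targets


class Undersample(PreprocessStep):
    """Reduce every training class to the minority-class count (seeded)."""

    train_only = True

    def __init__(self, seed=0):
        self.seed = seed

    def fit_transform_train(self, X, targets):
        rng = np.random.default_rng(self.seed)
        classes, counts = np.unique(targets, return_counts=True)
        n_min = counts.min()
        keep = np.concatenate(
            [
                rng.choice(np.flatnonzero(targets == c), size=n_min, replace=False)
                for c in classes
            ]
        )
        keep.sort()
        self.fitted_ = True
        return X[keep], targets[keep]

    def transform_test(self, X, targets):
        self._require_fitted("fitted_")
        return X, targets


class Oversample(PreprocessStep):
    """Duplicate minority-class training samples up to the majority count."""

    train_only = True

    def __init__(self, seed=0):
        self.seed = seed

    def fit_transform_train(self, X, targets):
        rng = np.random.default_rng(self.seed)
        classes, counts = np.unique(targets, return_counts=True)
        n_max = counts.max()
        idx = [np.arange(len(targets))]
        for c, cnt in zip(classes, counts):
            if cnt < n_max:
                pool = np.flatnonzero(targets == c)
                idx.append(rng.choice(pool, size=n_max - cnt, replace=True))
        keep = np.concatenate(idx)
        self.fitted_ = True
        return X[keep], targets[keep]

    def transform_test(self, X, targets):
        self._require_fitted("fitted_")
        return X, targets


def _grouped_average(X, targets, group_size, rng):
    """Average seeded random within-class groups; remainder forms a
    smaller final group."""
    Xg, yg = [], []
    for c in np.unique(targets):
        idx = np.flatnonzero(targets == c)
        if group_size > len(idx):
            raise ConfigurationError(
                f"group_size {group_size} exceeds class size {len(idx)}"
            )
        idx = rng.permutation(idx)
        for start in range(0, len(idx), group_size):
            members = idx[start : start + group_size]
            Xg.append(X[members].mean(axis=0))
            yg.append(c)
    return np.vstack(Xg), np.asarray(yg)


class AverageSamples(PreprocessStep):
    """Average within-class random groups of trials to boost SNR.

    Applied to train and test folds alike (each grouped internally);
    sample counts shrink by roughly the group size."""

    def __init__(self, group_size=2, seed=0):
        self.group_size = group_size
        self.seed = seed

    def fit_transform_train(self, X, targets):
        self.fitted_ = True
        rng = np.random.default_rng(self.seed)
        return _grouped_average(X, targets, self.group_size, rng)

    def transform_test(self, X, targets):
        self._require_fitted("fitted_")
        rng = np.random.default_rng(self.seed + 1)  # fresh test-side groups
        return _grouped_average(X, targets, self.group_size, rng)


class AverageKernel(PreprocessStep):
    """Group-block averaging of a precomputed kernel matrix.

    Input X must be a kernel matrix (train: n x n; test: n_test x
    n_train).  Within-class groups are formed on each side and the
    kernel is averaged over the corresponding blocks, which equals the
    kernel between group-mean samples for linear kernels.
    """

    def __init__(self, group_size=2, seed=0):
        self.group_size = group_size
        self.seed = seed

    @staticmethod
    def _groups(targets, group_size, rng):
        groups, labels = [], []
        for c in np.unique(targets):
            idx = rng.permutation(np.flatnonzero(targets == c))
            for start in range(0, len(idx), group_size):
                groups.append(idx[start : start + group_size])
                labels.append(c)
        return groups, np.asarray(labels)

    def fit_transform_train(self, K, targets):
        if K.shape[0] != K.shape[1]:
            raise StructuralError("train-fold kernel matrix must be square")
        rng = np.random.default_rng(self.seed)
        groups, labels = self._groups(targets, self.group_size, rng)
        self.train_groups_ = groups
        G = len(groups)
        Kg = np.empty((G, G))
        for a, ga in enumerate(groups):
            for b, gb in enumerate(groups):
                Kg[a, b] = K[np.ix_(ga, gb)].mean()
        return Kg, labels

    def transform_test(self, K, targets):
        self._require_fitted("train_groups_")
        rng = np.random.default_rng(self.seed + 1)
        groups, labels = self._groups(targets, self.group_size, rng)
        Kg = np.empty((len(groups), len(self.train_groups_)))
        for a, ga in enumerate(groups):
            for b, gb in enumerate(self.train_groups_):
                Kg[a, b] = K[np.ix_(ga, gb)].mean()
        return Kg, labels


STEP_REGISTRY = {
    "zscore": ZScore,
    "demean": Demean,
    "pca": PCA,
    "undersample": Undersample,
    "oversample": Oversample,
    "average_samples": AverageSamples,
    "average_kernel": AverageKernel,
}


def make_pipeline(spec) -> list[PreprocessStep]:
    """Build a pipeline from a list of step names / (name, params) /
    dicts ``{"name": ..., **params}`` / ready-made step objects."""
    steps = []
    for item in spec or []:
        if isinstance(item, PreprocessStep):
            steps.append(item)
            continue
        if isinstance(item, str):
            name, params = item, {}
        elif isinstance(item, dict):
            params = dict(item)
            name = params.pop("name")
        else:
            name, params = item[0], dict(item[1])
        if name not in STEP_REGISTRY:
            raise ConfigurationError(
                f"unknown preprocessing step {name!r}; "
                f"available: {sorted(STEP_REGISTRY)}"
            )
        steps.append(STEP_REGISTRY[name](**params))
    return steps


def run_pipeline(steps, X_train, t_train, X_test=None, t_test=None):
    """Apply steps sequentially: fit each on the (already transformed)
    training fold, then transform the test fold with the fitted state.

    Returns ``(X_train, t_train, X_test, t_test, fitted_steps)``.
    """
    fitted = []
    for step in steps:
        X_train, t_train = step.fit_transform_train(X_train, t_train)
        if X_test is not None:
            X_test, t_test = step.transform_test(X_test, t_test)
        fitted.append(step)
    return X_train, t_train, X_test, t_test, fitted
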