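"""Seeded synthetic-data generators.

These produce inputs with the statistical structure the analyses
assume — Gaussian class clouds with controllable separation and
covariance, epoched ERP-like trials (samples x channels x time) with a
class-dependent spatiotemporal effect, linear-model regression data, and
multi-subject metric maps for group-level tests.  Every generator is a
pure function of its arguments including the seed, so the same call
always returns bit-identical data.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage

from .base import MVPAError
from .data import DataSet


class SimSpecError(MVPAError):
    pass


def _spd_covariance(p, kind, rng):
    if isinstance(kind, str):
        if kind == "isotropic":
            return np.eye(p)
        if kind == "diagonal":
            return np.diag(rng.uniform(0.5, 2.0, size=p))
        if kind == "random":
            A = rng.standard_normal((p, p))
            return A @ A.T / p + 0.1 * np.eye(p)
        raise SimSpecError(f"unknown covariance kind {kind!r}")
    C = np.asarray(kind, dtype=float)
    if C.shape != (p, p):
        raise SimSpecError(f"covariance must be {p}x{p}")
    if not np.allclose(C, C.T):
        raise SimSpecError("covariance must be symmetric")
    if np.linalg.eigvalsh(C).min() <= 0:
        raise SimSpecError("covariance must be positive definite")
    return C


def gen_gaussian_classes(
    n_per_class=50,
    p=10,
    separation=1.0,
    n_classes=2,
    covariance="isotropic",
    seed=0,
):
    """K Gaussian class clouds with a common covariance matrix.

    Class means sit ``separation`` apart along distinct coordinate axes
    (class i: ``separation * e_{i mod p}``; class 0 at the origin), so
    ``separation=0`` makes the labels independent of the features.

    Returns ``(DataSet [n x p], labels in 1..K)``.
    """
    rng = np.random.default_rng(seed)
    C = _spd_covariance(p, covariance, rng)
    L = np.linalg.cholesky(C)
    X, y = [], []
    for k in range(n_classes):
        mean = np.zeros(p)
        if k > 0:
            mean[(k - 1) % p] = separation
        X.append(rng.standard_normal((n_per_class, p)) @ L.T + mean)
        y.append(np.full(n_per_class, k + 1))
    X = np.vstack(X)
    y = np.concatenate(y)
    perm = rng.permutation(len(y))
    return DataSet(X[perm]), y[perm].astype(int)


def gen_erp_like(
    n_per_class=50,
    channels=16,
    n_times=40,
    effect_windows=((15, 25),),
    amplitude=1.0,
    noise_sd=1.0,
    share_pattern=True,
    temporal_smoothing=0.0,
    seed=0,
):
    """Epoched two-class ERP-like trials [samples x channels x time].

    Background is white Gaussian noise (optionally temporally smoothed
    to mimic autocorrelation).  Inside each effect window, class 1
    trials get ``+amplitude`` times a random spatial pattern added and
    class 2 trials ``-amplitude`` times it; with ``share_pattern=False``
    each window draws its own pattern (so representations do not
    generalize between windows).

    Returns ``(DataSet [n x channels x T], labels in {1, 2})``.
    """
    rng = np.random.default_rng(seed)
    for t0, t1 in effect_windows:
        if not (0 <= t0 < t1 <= n_times):
            raise SimSpecError(f"effect window ({t0}, {t1}) outside [0, {n_times}]")
    if noise_sd < 0:
        raise SimSpecError("noise sd must be >= 0")
    n = 2 * n_per_class
    X = rng.standard_normal((n, channels, n_times)) * noise_sd
    if temporal_smoothing > 0:
        X = scipy.ndimage.gaussian_filter1d(X, temporal_smoothing, axis=2)
    y = np.repeat([1, 2], n_per_class)
    shared = rng.standard_normal(channels)
    shared /= np.linalg.norm(shared)
    for w, (t0, t1) in enumerate(effect_windows):
        if share_pattern or w == 0:
            pattern = shared
        else:
            pattern = rng.standard_normal(channels)
            pattern /= np.linalg.norm(pattern)
        signed = np.where(y == 1, 1.0, -1.0)
        X[:, :, t0:t1] += amplitude * signed[:, None, None] * pattern[None, :, None]
    perm = rng.permutation(n)
    return DataSet(X[perm]), y[perm].astype(int)


def gen_regression(n=100, p=10, w_true=None, noise_sd=1.0, seed=0):
    """Linear-model data y = X w_true + eps, X ~ N(0, I).

    Returns ``(DataSet [n x p], y, w_true)``.
    """
    if noise_sd < 0:
        raise SimSpecError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    if w_true is None:
        w_true = rng.standard_normal(p)
    w_true = np.asarray(w_true, dtype=float)
    X = rng.standard_normal((n, p))
    y = X @ w_true + noise_sd * rng.standard_normal(n)
    return DataSet(X), y, w_true


def gen_group_level(
    n_subjects=16,
    map_shape=(50,),
    null_value=0.5,
    effect=0.0,
    effect_region=None,
    between_sd=0.05,
    noise_sd=0.05,
    seed=0,
):
    """Per-subject metric maps for level-2 testing.

    Each subject's map is ``null_value`` plus (optionally) an ``effect``
    inside ``effect_region`` (a tuple of slices), plus a subject-level
    offset (sd ``between_sd``) and elementwise noise (sd ``noise_sd``).

    Returns (subjects, \\*map_shape) array.
    """
    if between_sd < 0 or noise_sd < 0:
        raise SimSpecError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    maps = np.full((n_subjects,) + tuple(map_shape), float(null_value))
    if effect and effect_region is not None:
        region = (slice(None),) + tuple(effect_region)
        maps[region] += effect
    maps += between_sd * rng.standard_normal((n_subjects,) + (1,) * len(map_shape))
    maps += noise_sd * rng.standard_normal(maps.shape)
    return maps
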