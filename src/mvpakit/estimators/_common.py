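"""Shared helpers for classifier estimators."""

from __future__ import annotations

import numpy as np

from ..base import DataError, LabelError, StructuralError


def check_Xy_classification(X, y, n_classes=None, min_classes=2, max_classes=None):
    """Validate a 2-D training pair and return (X, y_internal, classes).

    ``y_internal`` is re-coded to ``1..K`` with ``classes[i-1]`` holding
    the original label of internal class ``i`` (ascending order).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise StructuralError(f"X must be 2-D [samples x features], got ndim={X.ndim}")
    y = np.asarray(y)
    if y.ndim != 1 or len(y) != X.shape[0]:
        raise StructuralError("y must be a 1-D vector matching the sample count")
    if not np.all(np.isfinite(X)):
        raise DataError("X contains non-finite values")
    classes = np.unique(y)
    k = len(classes)
    if k < min_classes:
        raise LabelError(f"need at least {min_classes} classes, got {k}")
    if max_classes is not None and k > max_classes:
        raise LabelError(
            f"this classifier supports at most {max_classes} classes, got {k}"
        )
    if n_classes is not None and k != n_classes:
        raise LabelError(f"expected {n_classes} classes, got {k}")
    y_internal = np.searchsorted(classes, y) + 1
    return X, y_internal.astype(int), classes


def check_X_predict(X, p_expected):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] != p_expected:
        raise StructuralError(
            f"test data has {X.shape[-1] if X.ndim else 0} features, "
            f"model was trained with {p_expected}"
        )
    return X


def binary_labels_from_dval(dval, classes):
    """dval > 0 -> first class, dval < 0 -> second; ties go to the first."""
    return np.where(np.asarray(dval) >= 0, classes[0], classes[1])
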