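"""Performance metrics for classification and regression.

Classification metrics operate on a :class:`~mvpakit.models.Prediction`
(or a plain label vector where labels suffice) against true labels coded
``1..K``; class 1 is the positive class for the binary-only metrics.
Regression metrics compare predicted and true response vectors.

Cross-validated metrics are aggregated with a proportionally weighted
average across test folds (larger test sets get larger weight), then
averaged across repetitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.stats

from .base import ConfigurationError, MVPAError, StructuralError
from .models import Prediction

CLASSIFICATION_METRICS = (
    "accuracy",
    "auc",
    "confusion",
    "dval",
    "f1",
    "kappa",
    "precision",
    "recall",
    "tval",
    "none",
)
REGRESSION_METRICS = ("mae", "mse", "r_squared", "none")

#: optimization direction used by hyperparameter tuning
METRIC_DIRECTION = {
    **{m: "maximize" for m in CLASSIFICATION_METRICS},
    "mae": "minimize",
    "mse": "minimize",
    "r_squared": "maximize",
}
BINARY_ONLY = ("auc", "dval", "tval")


@dataclass
class MetricValue:
    """A computed metric: scalar, per-class vector, or matrix."""

    name: str
    value: Any
    per_class: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def _as_prediction(predictions) -> Prediction:
    if isinstance(predictions, Prediction):
        return predictions
    return Prediction(clabel=np.asarray(predictions))


def confusion_counts(clabel, truth, n_classes):
    counts = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(truth, clabel):
        counts[t - 1, p - 1] += 1
    return counts


def _normalize_confusion(counts):
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = counts / counts.sum(axis=1, keepdims=True)
    return np.nan_to_num(norm)


def auc_score(outputs_pos, outputs_neg) -> float:
    """Rank-based AUC: P(class-1 output > class-2 output), ties count 1/2.

    Equivalent to the Mann-Whitney U statistic normalized by n1*n2.
    """
    pos = np.asarray(outputs_pos, dtype=float)
    neg = np.asarray(outputs_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise MVPAError("AUC needs outputs from both classes")
    ranks = scipy.stats.rankdata(np.concatenate([pos, neg]))
    r1 = ranks[: len(pos)].sum()
    u = r1 - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def classification_metric(name, predictions, truth, n_classes=None) -> MetricValue:
    """Compute one classification metric.

    Parameters
    ----------
    name : metric name (see ``CLASSIFICATION_METRICS``)
    predictions : Prediction or label vector
    truth : true labels coded 1..K
    n_classes : total class count (inferred from labels if omitted)
    """
    if name not in CLASSIFICATION_METRICS:
        raise ConfigurationError(f"unknown classification metric {name!r}")
    pred = _as_prediction(predictions)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise StructuralError("prediction/truth length mismatch")
    K = int(n_classes or max(truth.max(), pred.clabel.max()))
    if name in BINARY_ONLY and K != 2:
        raise ConfigurationError(f"metric {name!r}: for two classes only (K={K})")

    if name == "none":
        return MetricValue("none", pred)
    if name == "accuracy":
        return MetricValue("accuracy", float(np.mean(pred.clabel == truth)))
    if name == "auc":
        out = pred.dval if pred.dval is not None else pred.prob
        if out is None:
            raise ConfigurationError(
                "metric 'auc' needs decision values or probabilities"
            )
        return MetricValue("auc", auc_score(out[truth == 1], out[truth == 2]))
    if name == "dval":
        if pred.dval is None:
            raise ConfigurationError("metric 'dval' needs decision values")
        return MetricValue(
            "dval",
            np.array([pred.dval[truth == 1].mean(), pred.dval[truth == 2].mean()]),
        )
    if name == "tval":
        if pred.dval is None:
            raise ConfigurationError("metric 'tval' needs decision values")
        d1, d2 = pred.dval[truth == 1], pred.dval[truth == 2]
        n1, n2 = len(d1), len(d2)
        sp2 = ((n1 - 1) * d1.var(ddof=1) + (n2 - 1) * d2.var(ddof=1)) / (n1 + n2 - 2)
        return MetricValue(
            "tval", float((d1.mean() - d2.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2)))
        )

    counts = confusion_counts(pred.clabel, truth, K)
    if name == "confusion":
        return MetricValue(
            "confusion", _normalize_confusion(counts), extra={"counts": counts}
        )
    if name == "kappa":
        n = counts.sum()
        po = np.trace(counts) / n
        pe = float(counts.sum(axis=1) @ counts.sum(axis=0)) / n**2
        return MetricValue("kappa", float((po - pe) / (1.0 - pe)))
    # precision / recall / f1 from the confusion matrix
    tp = np.diag(counts).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = tp / counts.sum(axis=0)
        recall = tp / counts.sum(axis=1)
        f1 = 2 * precision * recall / (precision + recall)
    per_class = {"precision": precision, "recall": recall, "f1": f1}[name]
    per_class = np.nan_to_num(per_class)
    # scalar: class-1 value for two classes, macro average for K > 2
    scalar = float(per_class[0]) if K == 2 else float(np.mean(per_class))
    return MetricValue(name, scalar, per_class=per_class)


def regression_metric(name, predicted, truth) -> MetricValue:
    if name not in REGRESSION_METRICS:
        raise ConfigurationError(f"unknown regression metric {name!r}")
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape:
        raise StructuralError("prediction/truth length mismatch")
    if name == "none":
        return MetricValue("none", predicted)
    err = truth - predicted
    if name == "mae":
        return MetricValue("mae", float(np.mean(np.abs(err))))
    if name == "mse":
        return MetricValue("mse", float(np.mean(err**2)))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn(
            "r_squared undefined for zero-variance truth", RuntimeWarning, stacklevel=2
        )
        return MetricValue("r_squared", float("nan"))
    return MetricValue("r_squared", 1.0 - float(np.sum(err**2)) / ss_tot)


def weighted_fold_average(values, test_sizes):
    """Proportionally weighted average of per-fold metric values.

    Works elementwise for vector/matrix metrics.  ``MetricValue`` inputs
    are unwrapped; plain numbers/arrays pass through.
    """
    if len(values) == 0:
        raise StructuralError("no fold values to average")
    vals = [v.value if isinstance(v, MetricValue) else v for v in values]
    sizes = np.asarray(test_sizes, dtype=float)
    if len(sizes) != len(vals):
        raise StructuralError("fold values and sizes differ in length")
    stacked = np.stack([np.asarray(v, dtype=float) for v in vals])
    w = sizes / sizes.sum()
    out = np.tensordot(w, stacked, axes=(0, 0))
    return out if out.ndim else float(out)
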