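"""Model registry and prediction plumbing.

Models are addressed by short names (as in run configurations); custom
estimators can be added with :func:`register_model`.  A
:class:`Prediction` bundles the three classifier output types: discrete
class labels, decision values, and class-1 probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import ConfigurationError
from .estimators import (
    LDA,
    SVM,
    Ensemble,
    GaussianNaiveBayes,
    KernelFDA,
    KernelRidge,
    LogisticRegression,
    MulticlassLDA,
    NearestCentroid,
    Ridge,
)

_HYPER_ALIASES = {"lambda": "lambda_", "lam": "lambda_"}

MODEL_REGISTRY: dict[str, type] = {
    "lda": LDA,
    "multiclass_lda": MulticlassLDA,
    "naive_bayes": GaussianNaiveBayes,
    "logreg": LogisticRegression,
    "svm": SVM,
    "kernel_fda": KernelFDA,
    "ridge": Ridge,
    "kernel_ridge": KernelRidge,
    "ensemble": Ensemble,
    "prototype": NearestCentroid,
}

REGRESSION_MODELS = {"ridge", "kernel_ridge"}


def register_model(name: str, estimator_class: type) -> None:
    """Register a custom estimator class under a model name."""
    MODEL_REGISTRY[name] = estimator_class


def get_model(name: str, hyperparameters: dict | None = None):
    """Instantiate a registered model with the given hyperparameters.

    Hyperparameter names follow the estimator's ``__init__`` keywords;
    ``lambda`` is accepted as an alias for ``lambda_``.  For LDA-family
    models ``lambda`` maps to the shrinkage intensity.
    """
    if name not in MODEL_REGISTRY:
        raise ConfigurationError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        )
    cls = MODEL_REGISTRY[name]
    params = dict(hyperparameters or {})
    valid = set(cls._param_names()) if hasattr(cls, "_param_names") else None
    resolved = {}
    for key, value in params.items():
        key = _HYPER_ALIASES.get(key, key)
        if valid is not None:
            if key == "lambda_" and "lambda_" not in valid and "shrinkage" in valid:
                key = "shrinkage"
            if key not in valid:
                raise ConfigurationError(
                    f"model {name!r} has no hyperparameter {key!r}; "
                    f"valid: {sorted(valid)}"
                )
        resolved[key] = value
    return cls(**resolved)


def is_regression_model(model) -> bool:
    if isinstance(model, str):
        return model in REGRESSION_MODELS
    return getattr(model, "_estimator_type", "") == "regressor"


@dataclass
class Prediction:
    """Classifier outputs for one test set.

    clabel : predicted class labels (in the label coding the model saw)
    dval : decision values or None (two classes: positive -> class 1)
    prob : P(class 1 | x) or None
    """

    clabel: np.ndarray
    dval: np.ndarray | None = None
    prob: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.clabel)


def predict_all(model, X) -> Prediction:
    """Collect every output type the fitted model supports."""
    clabel = np.asarray(model.predict(X))
    dval = prob = None
    if hasattr(model, "decision_function"):
        try:
            dval = np.asarray(model.decision_function(X))
        except Exception:
            dval = None
    if hasattr(model, "predict_proba"):
        try:
            proba = np.asarray(model.predict_proba(X))
            prob = proba[:, 0]
        except Exception:
            prob = None
    return Prediction(clabel=clabel, dval=dval, prob=prob)
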