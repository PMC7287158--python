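"""Minimal estimator base classes (sklearn-compatible duck-typed API).

Estimators follow the scikit-learn contract: hyperparameters are
``__init__`` keyword arguments, fitted state lives in trailing-underscore
attributes, and ``get_params`` / ``set_params`` enable composition with
pipelines and grid search.
"""

from __future__ import annotations

import inspect
from typing import Any

import numpy as np


class MVPAError(Exception):
    """Base error for this package."""


class StructuralError(MVPAError):
    """Shape/length mismatch between data structures."""


class DataError(MVPAError):
    """Non-finite or otherwise invalid data values."""


class LabelError(MVPAError):
    """Degenerate or inconsistent class labels."""


class HyperparameterError(MVPAError):
    """Hyperparameter outside its admissible range."""


class ConfigurationError(MVPAError):
    """Invalid analysis configuration (unknown model, metric, option...)."""


class NumericalError(MVPAError):
    """Singular or ill-conditioned linear system."""


class CalibrationError(MVPAError):
    """Probability calibration requested but unavailable or degenerate."""


class BaseEstimator:
    """get_params/set_params via ``__init__`` signature introspection."""

    @classmethod
    def _param_names(cls) -> list[str]:
        sig = inspect.signature(cls.__init__)
        return [
            name
            for name, p in sig.parameters.items()
            if name != "self" and p.kind not in (p.VAR_POSITIONAL, p.VAR_KEYWORD)
        ]

    def get_params(self, deep: bool = True) -> dict[str, Any]:
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params: Any) -> "BaseEstimator":
        valid = set(self._param_names())
        for key, value in params.items():
            if key not in valid:
                raise ValueError(
                    f"Invalid parameter {key!r} for estimator "
                    f"{type(self).__name__}. Valid parameters: {sorted(valid)}"
                )
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:
        params = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({params})"

    def _check_fitted(self, attr: str) -> None:
        if not hasattr(self, attr):
            raise MVPAError(
                f"{type(self).__name__} is not fitted yet; call fit() first."
            )


class ClassifierMixin:
    """Shared prediction plumbing for classifiers.

    Classes are re-coded internally to ``1..K``; ``classes_`` stores the
    original label of each internal class in ascending order.  For two
    classes the decision value convention is ``dval > 0`` -> class 1
    (``classes_[0]``).
    """

    _estimator_type = "classifier"

    def score(self, X, y) -> float:
        from .metrics import classification_metric

        return float(
            classification_metric("accuracy", self.predict(X), np.asarray(y)).value
        )


class RegressorMixin:
    _estimator_type = "regressor"

    def score(self, X, y) -> float:
        from .metrics import regression_metric

        return float(regression_metric("r_squared", self.predict(X), np.asarray(y)).value)


class TransformerMixin:
    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
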