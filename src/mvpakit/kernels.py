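"""Kernel functions and kernel-matrix computation.

Kernels evaluate inner products in an implicit feature space,
``k(x, x') = <phi(x), phi(x')>``, letting linear algorithms act
non-linearly on the original inputs (the kernel trick).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .base import ConfigurationError, StructuralError

KERNEL_KINDS = ("linear", "polynomial", "rbf", "precomputed")


@dataclass
class KernelSpec:
    """Kernel choice and parameters.

    kind : 'linear' | 'polynomial' | 'rbf' | 'precomputed'
    gamma : rbf width / polynomial scale; ``None`` means 1/p (set at
        matrix-computation time from the data).
    degree : polynomial degree (>= 1).
    coef0 : polynomial offset (0 gives the homogeneous kernel).
    """

    kind: str = "linear"
    gamma: float | None = None
    degree: int = 2
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ConfigurationError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "polynomial" and self.degree < 1:
            raise ConfigurationError("polynomial kernel requires degree >= 1")
        if self.gamma is not None and self.gamma <= 0:
            raise ConfigurationError("gamma must be positive")

    def resolved_gamma(self, p: int) -> float:
        return 1.0 / p if self.gamma is None else float(self.gamma)


def as_kernel_spec(kernel, **kwargs) -> KernelSpec:
    if isinstance(kernel, KernelSpec):
        return kernel
    return KernelSpec(kind=kernel, **kwargs)


def kernel_eval(spec: KernelSpec, x, x2) -> float:
    """Evaluate the kernel on a single pair of feature vectors."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    x2 = np.atleast_1d(np.asarray(x2, dtype=float))
    if x.shape != x2.shape:
        raise StructuralError("kernel arguments must have equal feature length")
    return float(
        compute_kernel_matrix(spec, x[None, :], x2[None, :])[0, 0]
    )


def compute_kernel_matrix(spec: KernelSpec, X, X2=None) -> np.ndarray:
    """Pairwise kernel matrix K[i, j] = k(X[i], X2[j]).

    With ``X2=None`` the self-kernel is returned (symmetrized to kill
    rounding asymmetry).
    """
    spec = as_kernel_spec(spec)
    if spec.kind == "precomputed":
        # X *is* already a kernel matrix
        return np.asarray(X, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    self_kernel = X2 is None
    X2 = X if self_kernel else np.atleast_2d(np.asarray(X2, dtype=float))
    if X.shape[1] != X2.shape[1]:
        raise StructuralError(
            f"feature counts differ: {X.shape[1]} vs {X2.shape[1]}"
        )
    gamma = spec.resolved_gamma(X.shape[1])
    if spec.kind == "linear":
        K = X @ X2.T
    elif spec.kind == "polynomial":
        K = (gamma * (X @ X2.T) + spec.coef0) ** spec.degree
    elif spec.kind == "rbf":
        K = np.exp(-gamma * cdist(X, X2, "sqeuclidean"))
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown kernel kind {spec.kind!r}")
    if self_kernel:
        K = 0.5 * (K + K.T)
    return K
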