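"""Core data containers and input validation.

A :class:`DataSet` wraps an N-dimensional real array (N >= 2) together
with a *role* for each dimension:

``sample``
    the observations (trials); exactly one dimension.
``feature``
    the variables a model sees (channels, voxels); at least one.
``search``
    extra dimensions (time points, frequencies) the high-level drivers
    loop over, fitting one model per position.
``generalization``
    a search dimension additionally used for train-at-v / test-at-u
    generalization (e.g. time x time decoding); at most one.

Class labels are arbitrary distinct integers on input and are re-coded to
contiguous ``1..K`` internally; the mapping is recorded so predictions can
be reported in the caller's coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base import DataError, LabelError, StructuralError

VALID_ROLES = ("sample", "feature", "search", "generalization")


@dataclass
class DataSet:
    """N-dimensional data array with declared dimension roles.

    Parameters
    ----------
    values : ndarray, N >= 2 dimensions
        Real-valued data.
    dim_roles : sequence of str, optional
        One role per dimension.  Default: axis 0 = ``sample``,
        axis 1 = ``feature``, remaining axes = ``search``.
    dim_coords : dict, optional
        Maps axis index to a coordinate array/list (e.g. time points in
        seconds, channel names).
    """

    values: np.ndarray
    dim_roles: tuple[str, ...] = ()
    dim_coords: dict[int, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim < 2:
            raise StructuralError(
                f"DataSet requires >= 2 dimensions, got {self.values.ndim}"
            )
        if not self.dim_roles:
            roles = ["sample", "feature"] + ["search"] * (self.values.ndim - 2)
            self.dim_roles = tuple(roles)
        else:
            self.dim_roles = tuple(self.dim_roles)
        if len(self.dim_roles) != self.values.ndim:
            raise StructuralError(
                f"{len(self.dim_roles)} roles declared for "
                f"{self.values.ndim}-dimensional data"
            )
        for role in self.dim_roles:
            if role not in VALID_ROLES:
                raise StructuralError(f"unknown dimension role {role!r}")
        if self.dim_roles.count("sample") != 1:
            raise StructuralError("exactly one dimension must be tagged 'sample'")
        if "feature" not in self.dim_roles:
            raise StructuralError("at least one dimension must be tagged 'feature'")
        if self.dim_roles.count("generalization") > 1:
            raise StructuralError("at most one generalization dimension is supported")

    @property
    def sample_axis(self) -> int:
        return self.dim_roles.index("sample")

    @property
    def feature_axes(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.dim_roles) if r == "feature")

    @property
    def search_axes(self) -> tuple[int, ...]:
        return tuple(
            i for i, r in enumerate(self.dim_roles) if r in ("search", "generalization")
        )

    @property
    def generalization_axis(self) -> int | None:
        return (
            self.dim_roles.index("generalization")
            if "generalization" in self.dim_roles
            else None
        )

    @property
    def n(self) -> int:
        return self.values.shape[self.sample_axis]

    @property
    def p(self) -> int:
        return int(np.prod([self.values.shape[a] for a in self.feature_axes]))


def as_dataset(X, dim_roles=None, dim_coords=None) -> DataSet:
    """Coerce an array (or DataSet) into a validated DataSet."""
    if isinstance(X, DataSet):
        return X
    return DataSet(np.asarray(X, dtype=float), tuple(dim_roles or ()), dim_coords or {})


def recode_labels(y) -> tuple[np.ndarray, dict[int, int]]:
    """Re-code arbitrary integer labels to contiguous 1..K.

    Returns the re-coded vector and the mapping ``{original: internal}``.
    Original values map in ascending order, so the smallest label becomes
    class 1.
    """
    y = np.asarray(y)
    if y.ndim != 1:
        raise StructuralError("labels must be a 1-D vector")
    if not np.issubdtype(y.dtype, np.integer):
        yf = np.asarray(y, dtype=float)
        if not np.all(yf == np.round(yf)):
            raise LabelError("class labels must be integers")
        y = yf.astype(int)
    uniq = np.unique(y)
    mapping = {int(orig): i + 1 for i, orig in enumerate(uniq)}
    recoded = np.searchsorted(uniq, y) + 1
    return recoded.astype(int), mapping


def validate_inputs(data, targets, kind: str = "classification"):
    """Validate and canonicalize a (data, targets) pair.

    Parameters
    ----------
    data : array or DataSet
    targets : 1-D array
        Integer class labels (classification) or real responses
        (regression).
    kind : {'classification', 'regression'}

    Returns
    -------
    data : DataSet
    targets : ndarray
        Labels re-coded to 1..K, or responses as float vector.
    mapping : dict or None
        ``{original_label: internal_label}`` for classification.

    Raises
    ------
    StructuralError, DataError, LabelError
    """
    ds = as_dataset(data)
    if not np.all(np.isfinite(ds.values)):
        raise DataError("data contains non-finite values")
    if ds.n < 2:
        raise DataError(f"need at least 2 samples, got {ds.n}")
    t = np.asarray(targets)
    if t.ndim != 1:
        raise StructuralError("targets must be a 1-D vector")
    if len(t) != ds.n:
        raise StructuralError(
            f"targets length {len(t)} does not match sample count {ds.n}"
        )
    if kind == "classification":
        recoded, mapping = recode_labels(t)
        k = len(mapping)
        if k < 2:
            raise LabelError("only a single class present in the labels")
        return ds, recoded, mapping
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise DataError("responses contain non-finite values")
    return ds, t, None
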