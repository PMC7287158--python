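"""High-level drivers: decoding over arbitrary data dimensions.

``mv_classify`` / ``mv_regress`` accept N-dimensional data with declared
dimension roles and run a cross-validated analysis at every combination
of search-dimension indices, optionally with

* *generalization*: one search dimension is additionally used as a
  train-at-v / test-at-u axis, yielding e.g. a time x time metric matrix
  (train time = first of the two result axes);
* *searchlight*: per search dimension, a binary neighbourhood matrix
  expands the feature set at each centre position to all its
  neighbours (boundaries truncate; axes are not treated as periodic).

The fold plan is generated once per run and shared across all grid
points, so e.g. the diagonal of a time x time matrix matches the
across-time result exactly.
"""

from __future__ import annotations

import numpy as np

from .base import ConfigurationError, StructuralError
from .data import DataSet, as_dataset, validate_inputs
from .resampling import (
    ResultGrid,
    _normalize_cfg,
    evaluate_fold,
    fit_fold,
    make_folds,
    weighted_fold_average,
)


# ---------------------------------------------------------------------------
# neighbourhood helpers
def radius_neighbours(n_positions: int, radius: int) -> np.ndarray:
    """1-D chain neighbourhood: positions within ``radius`` steps
    (truncated at the edges, no wraparound)."""
    idx = np.arange(n_positions)
    return (np.abs(idx[:, None] - idx[None, :]) <= radius).astype(int)


def cube_neighbours(shape, extent: int = 1) -> np.ndarray:
    """Cube neighbourhood on a regular grid (e.g. 3x3x3 voxel cubes for
    ``extent=1`` on a 3-D grid).  Positions are the flattened grid
    points in C order; the matrix is [positions x positions]."""
    coords = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, len(shape))
    cheb = np.max(np.abs(coords[:, None, :] - coords[None, :, :]), axis=2)
    return (cheb <= extent).astype(int)


def _check_neighbours(mat, size):
    mat = np.asarray(mat)
    if mat.shape != (size, size):
        raise StructuralError(
            f"neighbourhood matrix shape {mat.shape} does not match "
            f"dimension length {size}"
        )
    if not np.all(np.diag(mat) == 1):
        raise StructuralError("every centre must belong to its own neighbourhood")
    return mat.astype(bool)


def build_searchlight_features(X, centre: int, neighbours) -> np.ndarray:
    """Extract the feature slice for one searchlight centre.

    X : (n, p, positions) array; returns (n, p * n_members) with the
    features of all neighbourhood members concatenated.
    """
    X = np.asarray(X)
    if X.ndim != 3:
        raise StructuralError("expected a 3-D [samples x features x positions] array")
    mat = _check_neighbours(neighbours, X.shape[2])
    members = np.flatnonzero(mat[centre])
    return X[:, :, members].reshape(X.shape[0], -1)


# ---------------------------------------------------------------------------
# the general driver
def _canonical(ds: DataSet):
    """Reorder to (sample, feature..., search...) and flatten features."""
    order = (
        [ds.sample_axis]
        + list(ds.feature_axes)
        + list(ds.search_axes)
    )
    vals = np.moveaxis(ds.values, order, range(len(order)))
    n = vals.shape[0]
    n_feat_axes = len(ds.feature_axes)
    p = int(np.prod(vals.shape[1 : 1 + n_feat_axes]))
    vals = vals.reshape((n, p) + vals.shape[1 + n_feat_axes :])
    gen_pos = None
    for i, ax in enumerate(ds.search_axes):
        if ds.dim_roles[ax] == "generalization":
            gen_pos = i
    return vals, gen_pos, list(ds.search_axes)


def _slice_grid_point(Xc, grid_idx, masks):
    """Select one grid point: per search dim either a single position or
    the centre's neighbourhood, flattened into the feature axis."""
    sel = Xc
    for d in reversed(range(len(grid_idx))):
        axis = 2 + d
        if masks[d] is None:
            sel = np.take(sel, grid_idx[d], axis=axis)
        else:
            sel = np.take(sel, np.flatnonzero(masks[d][grid_idx[d]]), axis=axis)
    return sel.reshape(sel.shape[0], -1)


def _mv_general(cfg, X, targets, kind) -> ResultGrid:
    cfg_in = dict(cfg or {})
    gen_request = cfg_in.pop("generalization", None)
    cfg = _normalize_cfg(cfg_in, kind)
    cfg["generalization"] = gen_request
    ds, y, _ = validate_inputs(X, targets, kind=kind)
    if gen_request is not None and "generalization" not in ds.dim_roles:
        roles = list(ds.dim_roles)
        if roles[int(gen_request)] not in ("search",):
            raise ConfigurationError(
                f"axis {gen_request} is not a search dimension"
            )
        roles[int(gen_request)] = "generalization"
        ds = DataSet(ds.values, tuple(roles), ds.dim_coords)
    if (
        "generalization" in ds.dim_roles
        and cfg["hyperparameter"].get("kernel") == "precomputed"
    ):
        raise ConfigurationError(
            "precomputed kernels cannot be combined with generalization"
        )
    Xc, gen_pos, search_axes = _canonical(ds)
    grid_shape = Xc.shape[2:]
    n_search = len(grid_shape)

    # neighbourhood matrices, one (or None) per search dimension
    nb = cfg["neighbours"]
    if nb is None:
        masks = [None] * n_search
    else:
        if n_search == 1 and not isinstance(nb, (list, tuple)):
            nb = [nb]
        if len(nb) != n_search:
            raise StructuralError(
                f"{len(nb)} neighbourhood matrices for {n_search} search dims"
            )
        masks = [
            None if m is None else _check_neighbours(m, grid_shape[d])
            for d, m in enumerate(nb)
        ]

    plan = make_folds(
        cfg["cv"],
        n=len(y),
        k=cfg["k"],
        p=cfg["p"],
        repeats=cfg["repeat"],
        labels=y if kind == "classification" else None,
        stratify=cfg["stratify"],
        seed=cfg["seed"],
        fold=cfg["fold"],
    )

    metric_names = cfg["metric"]
    if n_search == 0:
        from .resampling import _run_plan

        return _run_plan(Xc.reshape(len(y), -1), y, plan, cfg, kind)
    if "none" in metric_names:
        raise ConfigurationError(
            "metric 'none' is only available for 2-D data (use crossvalidate)"
        )

    outer_dims = [d for d in range(n_search) if d != gen_pos]
    outer_shape = tuple(grid_shape[d] for d in outer_dims)
    results: dict[str, np.ndarray] = {}

    def store(metric, idx, value):
        value = np.asarray(value, dtype=float)
        if metric not in results:
            results[metric] = np.empty(
                (
                    outer_shape
                    + ((grid_shape[gen_pos],) * 2 if gen_pos is not None else ())
                    + value.shape
                ),
                dtype=float,
            )
        results[metric][idx] = value

    for outer_idx in np.ndindex(*outer_shape) if outer_shape else [()]:
        if gen_pos is None:
            grid_idx = list(outer_idx)
            Xslice = _slice_grid_point(Xc, grid_idx, masks)
            agg = _cv_point(Xslice, y, plan, cfg, kind)
            for m in metric_names:
                store(m, outer_idx, agg[m])
        else:
            T = grid_shape[gen_pos]
            agg = _cv_generalization(
                Xc, y, plan, cfg, kind, outer_idx, outer_dims, gen_pos, masks, T
            )
            for m in metric_names:
                for v in range(T):
                    for u in range(T):
                        store(m, outer_idx + (v, u), agg[m][v][u])

    dim_names = tuple(f"dim{ax}" for ax in search_axes)
    if gen_pos is not None:
        names = list(dim_names)
        gname = names.pop(gen_pos)
        names += [f"{gname}_train", f"{gname}_test"]
        dim_names = tuple(names)
    coords = {i: ds.dim_coords.get(ax) for i, ax in enumerate(search_axes)}
    grid = ResultGrid(
        metrics={
            m: (results[m] if results[m].shape else float(results[m]))
            for m in metric_names
        },
        cfg=dict(cfg),
        dim_names=dim_names,
        dim_coords=coords,
    )
    return grid


def _cv_point(Xslice, y, plan, cfg, kind):
    """Standard CV at a single grid point, using the shared fold plan."""
    from .resampling import _run_plan

    return _run_plan(Xslice, y, plan, cfg, kind).metrics


def _cv_generalization(Xc, y, plan, cfg, kind, outer_idx, outer_dims, gen_pos, masks, T):
    """Train at gen position v, test at every u, within the CV scheme."""
    metric_names = cfg["metric"]

    def grid_idx_at(v):
        idx = [0] * (len(outer_dims) + 1)
        for pos, d in enumerate(outer_dims):
            idx[d] = outer_idx[pos]
        idx[gen_pos] = v
        return idx

    results_repeats = {m: [] for m in metric_names}
    for r in range(plan.repeats):
        rep_vals = {m: [[[] for _ in range(T)] for _ in range(T)] for m in metric_names}
        sizes = []
        for train, test in plan.folds(r):
            if kind == "classification" and len(np.unique(y[train])) < 2:
                continue
            sizes.append(len(test))
            for v in range(T):
                Xtr = _slice_grid_point(Xc, grid_idx_at(v), masks)[train]
                steps, model, _ = fit_fold(Xtr, y[train], cfg, kind)
                for u in range(T):
                    Xte = _slice_grid_point(Xc, grid_idx_at(u), masks)[test]
                    vals, _ = evaluate_fold(steps, model, Xte, y[test], cfg, kind)
                    for m in metric_names:
                        rep_vals[m][v][u].append(vals[m])
        for m in metric_names:
            results_repeats[m].append(
                [
                    [weighted_fold_average(rep_vals[m][v][u], sizes) for u in range(T)]
                    for v in range(T)
                ]
            )
    agg = {}
    for m in metric_names:
        stacked = np.asarray(results_repeats[m], dtype=float)
        agg[m] = stacked.mean(axis=0)
    return agg


def mv_classify(cfg, X, labels) -> ResultGrid:
    """General-purpose decoding driver for data of arbitrary dimension."""
    return _mv_general(cfg, X, labels, "classification")


def mv_regress(cfg, X, responses) -> ResultGrid:
    """Regression counterpart of :func:`mv_classify`."""
    return _mv_general(cfg, X, responses, "regression")


def _require_3d(X):
    ds = as_dataset(X)
    if ds.values.ndim != 3:
        raise StructuralError(
            "expected 3-D [samples x features x time points] data"
        )
    return ds


def mv_classify_across_time(cfg, X, labels) -> ResultGrid:
    """Classification at every time point of [samples x features x time]
    data; returns a metric vector over time."""
    ds = _require_3d(X)
    return mv_classify(cfg, ds, labels)


def mv_classify_timextime(cfg, X, labels) -> ResultGrid:
    """Time generalization: train at each time point, test at all time
    points; returns a [train time x test time] metric matrix."""
    ds = _require_3d(X)
    cfg = dict(cfg or {})
    cfg["generalization"] = 2
    return mv_classify(cfg, ds, labels)
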