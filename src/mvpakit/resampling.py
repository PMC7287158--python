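"""Fold construction, the cross-validation engine, and nested
hyperparameter grid search.

The engine is strictly leakage-free: for each fold, preprocessing is
fitted on the training fold only, hyperparameter tuning runs an inner
cross-validation on the training fold only, and the model never sees
test-fold samples before prediction.  Metrics are computed per test
fold, averaged across folds proportionally to test-fold size, then
averaged across repetitions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .base import ConfigurationError, StructuralError
from .data import validate_inputs
from .metrics import (
    METRIC_DIRECTION,
    MetricValue,
    classification_metric,
    regression_metric,
    weighted_fold_average,
)
from .models import Prediction, get_model, is_regression_model, predict_all


@dataclass
class FoldPlan:
    """Assignment of samples to test folds for each repetition.

    ``assignments[r][i]`` is the index of the test fold sample ``i``
    belongs to in repetition ``r``; ``-1`` marks samples that are never
    tested (holdout training portion).  ``cv='none'`` produces a single
    pseudo-fold where train = test = all samples.
    """

    cv: str
    n: int
    k: int
    repeats: int
    assignments: list[np.ndarray]
    stratified: bool = False
    seed: int = 0

    def folds(self, repeat: int):
        """Yield (train_idx, test_idx) pairs for one repetition."""
        a = self.assignments[repeat]
        if self.cv == "none":
            idx = np.arange(self.n)
            yield idx, idx
            return
        for f in range(self.k):
            test = np.flatnonzero(a == f)
            train = np.flatnonzero((a != f) & (a >= 0) | (a == -1))
            yield train, test

    @property
    def n_folds(self) -> int:
        return 1 if self.cv == "none" else self.k


def _kfold_assignment(n, k, rng, labels=None):
    a = np.empty(n, dtype=int)
    if labels is None:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, k)):
            a[chunk] = f
    else:
        # per class: contiguous chunks of a shuffled index list, rotated
        # by a per-class offset so remainder samples spread across folds
        for offset, c in enumerate(np.unique(labels)):
            idx = rng.permutation(np.flatnonzero(labels == c))
            for f, chunk in enumerate(np.array_split(idx, k)):
                a[chunk] = (f + offset) % k
    return a


def make_folds(
    cv="kfold",
    n=None,
    k=5,
    p=0.2,
    repeats=1,
    labels=None,
    stratify=None,
    seed=0,
    fold=None,
) -> FoldPlan:
    """Build a reproducible fold plan.

    Parameters
    ----------
    cv : 'kfold' | 'leaveout' | 'holdout' | 'predefined' | 'none'
    n : sample count
    k : folds for 'kfold'
    p : test fraction for 'holdout' (0 < p < 1)
    repeats : repetitions, each with freshly randomized assignment
    labels : class labels; enables stratification
    stratify : force stratification on/off (default: on when labels given)
    seed : base seed; repetition r uses seed + r
    fold : predefined assignment vector for cv='predefined'
    """
    if n is None:
        raise StructuralError("sample count n is required")
    if cv == "predefined":
        if fold is None:
            raise ConfigurationError("cv='predefined' requires a fold vector")
        fold = np.asarray(fold)
        if len(fold) != n:
            raise StructuralError(f"fold vector length {len(fold)} != n {n}")
        uniq = np.unique(fold)
        a = np.searchsorted(uniq, fold)
        return FoldPlan("predefined", n, len(uniq), 1, [a], False, seed)
    if cv == "none":
        return FoldPlan("none", n, 1, 1, [np.zeros(n, dtype=int)], False, seed)
    if cv == "leaveout":
        return FoldPlan(
            "leaveout", n, n, 1, [np.arange(n)], False, seed
        )
    if cv == "holdout":
        if not 0 < p < 1:
            raise ConfigurationError("holdout fraction p must be in (0, 1)")
        n_test = max(1, int(round(p * n)))
        assignments = []
        for r in range(repeats):
            rng = np.random.default_rng(seed + r)
            a = np.full(n, -1, dtype=int)
            a[rng.choice(n, size=n_test, replace=False)] = 0
            assignments.append(a)
        return FoldPlan("holdout", n, 1, repeats, assignments, False, seed)
    if cv != "kfold":
        raise ConfigurationError(f"unknown cross-validation type {cv!r}")
    if k > n:
        raise ConfigurationError(f"k={k} exceeds sample count n={n}")
    do_strat = (labels is not None) if stratify is None else bool(stratify)
    if do_strat and labels is None:
        raise ConfigurationError("stratification requires labels")
    assignments = []
    for r in range(repeats):
        rng = np.random.default_rng(seed + r)
        assignments.append(
            _kfold_assignment(n, k, rng, labels if do_strat else None)
        )
    return FoldPlan("kfold", n, k, repeats, assignments, do_strat, seed)


@dataclass
class ResultGrid:
    """Cross-validated metric values, with per-fold provenance.

    metrics : {metric name: aggregated value (scalar or ndarray)}
    per_fold : {metric name: list over repeats of list over folds}
    test_sizes : list over repeats of per-fold test sizes
    cfg : configuration echo
    dim_names, dim_coords : populated by the high-level drivers when
        metrics are laid out over search/generalization dimensions
    """

    metrics: dict
    per_fold: dict = field(default_factory=dict)
    test_sizes: list = field(default_factory=list)
    cfg: dict = field(default_factory=dict)
    dim_names: tuple = ()
    dim_coords: dict = field(default_factory=dict)
    #: per repeat, per fold: fitted models / preprocessing / tuned params
    models: list = field(default_factory=list)
    fitted_steps: list = field(default_factory=list)
    fold_params: list = field(default_factory=list)

    def __getitem__(self, name):
        return self.metrics[name]


def _normalize_cfg(cfg: dict, kind: str) -> dict:
    defaults = {
        "model": "ridge" if kind == "regression" else "lda",
        "hyperparameter": {},
        "metric": "mse" if kind == "regression" else "accuracy",
        "preprocess": [],
        "cv": "kfold",
        "k": 5,
        "repeat": 1,
        "p": 0.2,
        "fold": None,
        "stratify": None,
        "seed": 0,
        "tune_k": 5,
        "tune_metric": None,
        "neighbours": None,
        "generalization": None,
    }
    unknown = set(cfg) - set(defaults)
    if unknown:
        raise ConfigurationError(
            f"unknown configuration field(s): {sorted(unknown)}"
        )
    out = {**defaults, **cfg}
    if isinstance(out["metric"], str):
        out["metric"] = [out["metric"]]
    return out


def _metric_fns(kind):
    return regression_metric if kind == "regression" else classification_metric


def _split_grid(hyper: dict):
    """Separate fixed hyperparameters from candidate lists."""
    fixed, grid = {}, {}
    for key, val in (hyper or {}).items():
        if isinstance(val, (list, tuple, np.ndarray)) and not isinstance(val, str):
            grid[key] = list(val)
        else:
            fixed[key] = val
    return fixed, grid


def tune_hyperparameters(
    grid: dict,
    X_train,
    y_train,
    model="lda",
    fixed=None,
    metric=None,
    kind="classification",
    inner_k=5,
    seed=0,
):
    """Grid search by inner cross-validation on the training fold only.

    Returns the best hyperparameter combination (dict).  Ties are broken
    by grid order (first wins).  A grid with a single combination is
    returned without running the inner CV.
    """
    for key, vals in grid.items():
        if len(vals) == 0:
            raise ConfigurationError(f"empty candidate list for {key!r}")
    keys = list(grid)
    combos = [dict(zip(keys, vals)) for vals in itertools.product(*grid.values())]
    if len(combos) <= 1:
        return {**(fixed or {}), **(combos[0] if combos else {})}
    metric = metric or ("mse" if kind == "regression" else "accuracy")
    direction = METRIC_DIRECTION[metric]
    n = len(y_train)
    inner_k = min(inner_k, n)
    labels = y_train if kind == "classification" else None
    plan = make_folds(
        "kfold", n=n, k=inner_k, labels=labels, seed=seed, repeats=1
    )
    best_score, best = None, None
    for combo in combos:
        params = {**(fixed or {}), **combo}
        vals, sizes = [], []
        for train, test in plan.folds(0):
            model_inst = _resolve_model(model, params, kind)
            model_inst.fit(X_train[train], y_train[train])
            if kind == "regression":
                m = regression_metric(metric, model_inst.predict(X_train[test]),
                                      y_train[test])
            else:
                m = classification_metric(
                    metric, predict_all(model_inst, X_train[test]), y_train[test]
                )
            vals.append(m)
            sizes.append(len(test))
        score = weighted_fold_average(vals, sizes)
        better = (
            best_score is None
            or (direction == "maximize" and score > best_score)
            or (direction == "minimize" and score < best_score)
        )
        if better:
            best_score, best = score, params
    return best


def _resolve_model(model, hyper, kind):
    if isinstance(model, str):
        return get_model(model, hyper)
    # estimator prototype: clone with overridden params
    params = model.get_params()
    params.update(hyper or {})
    return type(model)(**params)


def fit_fold(X_train, y_train, cfg, kind):
    """Fit the preprocessing pipeline and model on one training fold.

    Returns ``(fitted_steps, fitted_model, tuned_hyperparameters)``.
    """
    from .preprocess import make_pipeline, run_pipeline

    fixed, grid = _split_grid(cfg["hyperparameter"])
    steps = make_pipeline(cfg["preprocess"])
    Xt, yt, _, _, fitted_steps = run_pipeline(steps, X_train, y_train)
    if grid:
        params = tune_hyperparameters(
            grid,
            Xt,
            yt,
            model=cfg["model"],
            fixed=fixed,
            metric=cfg["tune_metric"] or cfg["metric"][0],
            kind=kind,
            inner_k=cfg["tune_k"],
            seed=cfg["seed"],
        )
    else:
        params = fixed
    model = _resolve_model(cfg["model"], params, kind)
    model.fit(Xt, yt)
    return fitted_steps, model, params


def evaluate_fold(fitted_steps, model, X_test, y_test, cfg, kind):
    """Transform a test fold with fitted steps and compute metrics."""
    for step in fitted_steps:
        X_test, y_test = step.transform_test(X_test, y_test)
    if kind == "regression":
        predicted = model.predict(X_test)
        vals = {m: regression_metric(m, predicted, y_test) for m in cfg["metric"]}
    else:
        pred = predict_all(model, X_test)
        vals = {m: classification_metric(m, pred, y_test) for m in cfg["metric"]}
    return vals, len(y_test)


def _aggregate(per_fold, test_sizes, metric_names):
    """Weighted average across folds, then plain average across repeats."""
    out = {}
    for m in metric_names:
        if m == "none":
            out[m] = [vals for rep in per_fold[m] for vals in rep]
            continue
        per_repeat = [
            weighted_fold_average(rep_vals, sizes)
            for rep_vals, sizes in zip(per_fold[m], test_sizes)
        ]
        out[m] = (
            float(np.mean(per_repeat))
            if np.ndim(per_repeat[0]) == 0
            else np.mean(per_repeat, axis=0)
        )
    return out


def crossvalidate(cfg, X, targets) -> ResultGrid:
    """Cross-validated model evaluation on 2-D [samples x features] data.

    ``cfg`` is a dict with fields model, hyperparameter, metric,
    preprocess, cv, k, repeat, p, fold, stratify, seed (all optional).
    Candidate lists inside ``hyperparameter`` trigger nested tuning.
    """
    kind = "regression" if is_regression_model(cfg.get("model", "lda")) else (
        cfg.get("_kind", "classification")
    )
    cfg = _normalize_cfg({k: v for k, v in cfg.items() if k != "_kind"}, kind)
    ds, y, _ = validate_inputs(X, targets, kind=kind)
    if ds.values.ndim != 2:
        raise StructuralError(
            "crossvalidate expects 2-D data; use the high-level drivers "
            "for multi-dimensional data"
        )
    Xm = ds.values
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
    return _run_plan(Xm, y, plan, cfg, kind)


def _run_plan(Xm, y, plan, cfg, kind) -> ResultGrid:
    metric_names = cfg["metric"]
    per_fold = {m: [] for m in metric_names}
    test_sizes = []
    all_models, all_steps, all_params = [], [], []
    for r in range(plan.repeats):
        rep_vals = {m: [] for m in metric_names}
        sizes = []
        rep_models, rep_steps, rep_params = [], [], []
        for train, test in plan.folds(r):
            if kind == "classification" and len(np.unique(y[train])) < 2:
                warnings.warn(
                    "a fold lost all samples of a class; skipping fold",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            steps, model, params = fit_fold(Xm[train], y[train], cfg, kind)
            vals, n_test = evaluate_fold(
                steps, model, Xm[test], y[test], cfg, kind
            )
            for m in metric_names:
                rep_vals[m].append(vals[m])
            sizes.append(n_test)
            rep_models.append(model)
            rep_steps.append(steps)
            rep_params.append(params)
        for m in metric_names:
            per_fold[m].append(rep_vals[m])
        test_sizes.append(sizes)
        all_models.append(rep_models)
        all_steps.append(rep_steps)
        all_params.append(rep_params)
    metrics = _aggregate(per_fold, test_sizes, metric_names)
    return ResultGrid(
        metrics=metrics,
        per_fold=per_fold,
        test_sizes=test_sizes,
        cfg=dict(cfg),
        models=all_models,
        fitted_steps=all_steps,
        fold_params=all_params,
    )
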