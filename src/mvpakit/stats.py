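"""Level-1 (within-dataset) and level-2 (group) significance testing.

Level 1 operates on a single dataset: an exact binomial test of
classification accuracy against chance, a label-shuffling permutation
test of any metric map, and a cluster-based permutation test that
controls the family-wise error across a metric map by comparing
suprathreshold-cluster mass against the permutation distribution of the
maximal cluster.

Level 2 operates on per-subject metric maps: within-subject designs
(paired values, or a single value against a null value) use per-subject
swaps/sign flips as the exchangeability scheme; between-subject designs
permute group membership.  Statistics: mean, t, Wilcoxon signed-rank
(within) or rank-sum (between).  All permutation p-values use the
add-one rule, p = (1 + #{null >= observed}) / (1 + n_permutations), so
p >= 1/(1 + n_permutations) always.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.stats

from .base import ConfigurationError, StructuralError
from .metrics import METRIC_DIRECTION


@dataclass
class Cluster:
    members: np.ndarray  # index tuple arrays into the map
    mass: float
    size: int
    p: float = np.nan


@dataclass
class StatTestResult:
    """Observed statistic, null distribution, p-values, significance mask."""

    statistic: np.ndarray | float
    p: np.ndarray | float
    mask: np.ndarray | None = None
    null: np.ndarray | None = None
    clusters: list[Cluster] = field(default_factory=list)
    alpha: float = 0.05
    n_permutations: int | None = None
    seed: int | None = None
    info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
def binomial_test(accuracy, n_test, chance=0.5, alpha=0.05) -> StatTestResult:
    """Exact binomial tail test of accuracy against chance level.

    p = P(X >= k) with X ~ Binomial(n_test, chance) and
    k = round(accuracy * n_test).
    """
    if not 0 < chance < 1:
        raise ConfigurationError("chance level must lie strictly in (0, 1)")
    k = int(round(float(accuracy) * n_test))
    p = float(scipy.stats.binom.sf(k - 1, n_test, chance))
    return StatTestResult(
        statistic=float(accuracy),
        p=p,
        mask=np.array(p <= alpha),
        alpha=alpha,
        info={"k": k, "n": int(n_test), "chance": chance},
    )


# ---------------------------------------------------------------------------
def _add_one_p(null, observed, direction="maximize"):
    null = np.asarray(null, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if direction == "maximize":
        exceed = (null >= obs).sum(axis=0)
    else:
        exceed = (null <= obs).sum(axis=0)
    return (1.0 + exceed) / (1.0 + null.shape[0])


def permutation_test_level1(
    cfg,
    X,
    targets,
    n_permutations=500,
    seed=0,
    alpha=0.05,
    kind="classification",
    cluster=None,
) -> StatTestResult:
    """Label-shuffling permutation test of a (possibly multi-dim) metric map.

    Runs the configured cross-validated analysis once on the observed
    targets, then ``n_permutations`` times on globally shuffled targets,
    rerunning the full analysis each time.  Elementwise p-values follow
    the add-one rule in the metric's favourable direction.  Passing a
    ``cluster`` dict (keys: ``critical_value``, optionally ``statistic``,
    ``adjacency``) switches to cluster-based family-wise correction.
    """
    if n_permutations < 1:
        raise ConfigurationError("n_permutations must be >= 1")
    from .highlevel import mv_classify, mv_regress

    cfg = dict(cfg or {})
    metric = cfg.get("metric", "mse" if kind == "regression" else "accuracy")
    if not isinstance(metric, str):
        raise ConfigurationError("permutation test expects a single metric")
    direction = METRIC_DIRECTION.get(metric)
    if direction is None or metric in ("none", "confusion", "dval"):
        raise ConfigurationError(f"metric {metric!r} has no defined test direction")
    driver = mv_regress if kind == "regression" else mv_classify
    observed = np.asarray(driver(cfg, X, targets)[metric], dtype=float)
    rng = np.random.default_rng(seed)
    targets = np.asarray(targets)
    null = np.empty((n_permutations,) + observed.shape)
    for b in range(n_permutations):
        null[b] = np.asarray(driver(cfg, X, rng.permutation(targets))[metric])
    if cluster is not None:
        return _cluster_from_null(
            observed, null, alpha=alpha, seed=seed, direction=direction, **cluster
        )
    direction_word = "maximize" if direction == "maximize" else "minimize"
    p = _add_one_p(null, observed, direction_word)
    return StatTestResult(
        statistic=observed if observed.ndim else float(observed),
        p=p if np.ndim(p) else float(p),
        mask=np.asarray(p <= alpha),
        null=null,
        alpha=alpha,
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
def _label_clusters(exceed_mask, adjacency=None):
    """Connected components of a boolean map.

    Default adjacency: orthogonal neighbours (4-connectivity in 2-D,
    6 in 3-D).  ``adjacency`` may be a custom binary structure for
    ``scipy.ndimage.label``.
    """
    mask = np.asarray(exceed_mask, dtype=bool)
    if mask.ndim == 0:
        mask = mask[None]
    structure = (
        scipy.ndimage.generate_binary_structure(mask.ndim, 1)
        if adjacency is None
        else np.asarray(adjacency, dtype=bool)
    )
    labels, n = scipy.ndimage.label(mask, structure=structure)
    return labels, n


def _cluster_stats(values, labels, n, statistic="mass"):
    out = []
    for c in range(1, n + 1):
        members = np.nonzero(labels == c)
        mass = float(np.sum(values[members]))
        size = int(len(members[0]))
        stat = mass if statistic == "mass" else float(size)
        out.append((members, stat, mass, size))
    return out


def cluster_permutation_test(
    observed_map,
    null_maps,
    critical_value,
    alpha=0.05,
    adjacency=None,
    statistic="mass",
    direction="maximize",
    seed=None,
) -> StatTestResult:
    """Cluster-based permutation test over a metric map.

    Elements of the observed map exceeding ``critical_value`` are grouped
    into connected clusters; each cluster's statistic (sum of member
    values = "mass", or "size") is compared to the null distribution of
    the *maximal* cluster statistic across the permutation maps, which
    controls the family-wise error over the whole map.

    ``critical_value`` may be an absolute threshold (e.g. 0.6 for
    accuracy) or the pair ``("quantile", q)``, resolved as the q-quantile
    of the pooled null values.
    """
    return _cluster_from_null(
        np.asarray(observed_map, dtype=float),
        np.asarray(null_maps, dtype=float),
        critical_value=critical_value,
        alpha=alpha,
        adjacency=adjacency,
        statistic=statistic,
        direction=direction,
        seed=seed,
    )


def _cluster_from_null(
    observed,
    null,
    critical_value,
    alpha=0.05,
    adjacency=None,
    statistic="mass",
    direction="maximize",
    seed=None,
):
    if statistic not in ("mass", "size"):
        raise ConfigurationError("cluster statistic must be 'mass' or 'size'")
    if isinstance(critical_value, (tuple, list)) and critical_value[0] == "quantile":
        critical_value = float(np.quantile(null, critical_value[1]))
    thr = float(critical_value)
    sign = 1.0 if direction == "maximize" else -1.0
    obs = sign * observed
    nul = sign * null
    thr = sign * thr
    labels, n = _label_clusters(obs > thr, adjacency)
    clusters_raw = _cluster_stats(obs, labels, n, statistic)
    null_max = np.zeros(len(nul))
    for b, nm in enumerate(nul):
        lb, nb = _label_clusters(nm > thr, adjacency)
        stats = _cluster_stats(nm, lb, nb, statistic)
        if stats:
            null_max[b] = max(s[1] for s in stats)
    clusters = []
    mask = np.zeros(np.shape(observed) if np.ndim(observed) else (1,), dtype=bool)
    for members, stat, mass, size in clusters_raw:
        p = float((1.0 + np.sum(null_max >= stat)) / (1.0 + len(null_max)))
        clusters.append(Cluster(members=members, mass=sign * mass, size=size, p=p))
        if p <= alpha:
            mask[members] = True
    p_map = np.ones(mask.shape)
    for cl in clusters:
        p_map[cl.members] = cl.p
    return StatTestResult(
        statistic=observed,
        p=p_map if np.ndim(observed) else float(p_map[0]),
        mask=mask if np.ndim(observed) else mask[0],
        null=null_max,
        clusters=clusters,
        alpha=alpha,
        n_permutations=len(null_max),
        seed=seed,
        info={"critical_value": sign * thr, "statistic": statistic},
    )


# ---------------------------------------------------------------------------
def _within_statistic(d, statistic):
    """Statistic of per-subject differences d (subjects x map...)."""
    S = d.shape[0]
    if statistic == "mean":
        return d.mean(axis=0)
    if statistic == "t":
        sd = d.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.finfo(float).tiny ** 0.5, sd)
        return d.mean(axis=0) / (sd / np.sqrt(S))
    if statistic == "wilcoxon":
        # signed-rank sum: ranks of |d| across subjects, signed
        absd = np.abs(d)
        ranks = scipy.stats.rankdata(absd, axis=0)
        return np.sum(np.sign(d) * ranks, axis=0)
    raise ConfigurationError(
        f"statistic {statistic!r} not valid for within-subject designs"
    )


def _between_statistic(values, groups, statistic):
    g1 = values[groups == 1]
    g2 = values[groups == 2]
    if statistic == "mean":
        return g1.mean(axis=0) - g2.mean(axis=0)
    if statistic == "t":
        n1, n2 = len(g1), len(g2)
        sp2 = (
            (n1 - 1) * g1.var(axis=0, ddof=1) + (n2 - 1) * g2.var(axis=0, ddof=1)
        ) / (n1 + n2 - 2)
        sp2 = np.where(sp2 == 0, np.finfo(float).tiny ** 0.5, sp2)
        return (g1.mean(axis=0) - g2.mean(axis=0)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    if statistic == "ranksum":
        ranks = scipy.stats.rankdata(values, axis=0)
        return ranks[groups == 1].sum(axis=0)
    raise ConfigurationError(
        f"statistic {statistic!r} not valid for between-subject designs"
    )


def level2_permutation_test(
    values,
    design="within",
    statistic="t",
    null_value=None,
    values2=None,
    groups=None,
    n_permutations=1000,
    seed=0,
    alpha=0.05,
    tail="two",
    cluster=None,
) -> StatTestResult:
    """Group-level permutation test on per-subject metric maps.

    Parameters
    ----------
    values : (subjects, ...) metric values/maps, one row per subject
    design : 'within' or 'between'
    statistic : 'mean' | 't' | 'wilcoxon' (within) | 'ranksum' (between)
    null_value : within-design single-value case: the chance value the
        metric is tested against (e.g. 0.5 for AUC)
    values2 : within-design paired case: second condition's values
    groups : between-design: vector of group labels (two groups)
    tail : 'two', 'right' or 'left'
    cluster : optional dict with ``critical_value`` (and optionally
        ``statistic``, ``adjacency``) to apply cluster correction
    """
    values = np.asarray(values, dtype=float)
    if values.ndim < 1 or values.shape[0] < 2:
        raise StructuralError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    S = values.shape[0]

    if design == "within":
        if statistic == "ranksum":
            raise ConfigurationError(
                "'ranksum' is a between-subjects statistic; use 'wilcoxon'"
            )
        if values2 is not None:
            v2 = np.asarray(values2, dtype=float)
            if v2.shape != values.shape:
                raise StructuralError("paired values must have equal shapes")
            d = values - v2
        elif null_value is not None:
            d = values - float(null_value)
        else:
            raise ConfigurationError(
                "within design needs either paired values2 or a null_value"
            )
        observed = _within_statistic(d, statistic)
        null = np.empty((n_permutations,) + observed.shape)
        for b in range(n_permutations):
            signs = rng.choice([-1.0, 1.0], size=S)
            null[b] = _within_statistic(d * signs.reshape((S,) + (1,) * (d.ndim - 1)),
                                        statistic)
    elif design == "between":
        if statistic == "wilcoxon":
            raise ConfigurationError(
                "'wilcoxon' is a within-subjects statistic; use 'ranksum'"
            )
        if groups is None:
            raise ConfigurationError("between design needs a groups vector")
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        if len(uniq) != 2:
            raise ConfigurationError("between design needs exactly two groups")
        g = np.where(groups == uniq[0], 1, 2)
        observed = _between_statistic(values, g, statistic)
        null = np.empty((n_permutations,) + observed.shape)
        for b in range(n_permutations):
            null[b] = _between_statistic(values, rng.permutation(g), statistic)
    else:
        raise ConfigurationError(f"unknown design {design!r}")

    if cluster is not None:
        return _cluster_from_null(
            np.asarray(observed), null, alpha=alpha, seed=seed, **cluster
        )
    if tail == "two":
        p = _add_one_p(np.abs(null), np.abs(observed), "maximize")
    elif tail == "right":
        p = _add_one_p(null, observed, "maximize")
    elif tail == "left":
        p = _add_one_p(null, observed, "minimize")
    else:
        raise ConfigurationError(f"unknown tail {tail!r}")
    return StatTestResult(
        statistic=observed if np.ndim(observed) else float(observed),
        p=p if np.ndim(p) else float(p),
        mask=np.asarray(p <= alpha),
        null=null,
        alpha=alpha,
        n_permutations=n_permutations,
        seed=seed,
        info={"design": design, "statistic": statistic, "tail": tail},
    )
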