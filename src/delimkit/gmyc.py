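"""Single-threshold generalized mixed Yule coalescent (GMYC) model.

Given an ultrametric gene tree, the model posits a single threshold time T:
branching events older than T are speciation events of a Yule-like
diversification process; events younger than T are coalescences within the
species-level entities defined by the branches crossing T.

Let the internal-node heights be t_1 > ... > t_{n-1} (root first).  For each
inter-event interval i = 1..n-2 of duration x_i = t_i - t_{i+1}, every
lineage present is assigned to one process: a branch that extends above T
belongs to the diversification process (k_i such lineages), a branch lying
entirely below T belongs to the coalescent process of its entity
(n_{i,j} lineages in entity j).  The combined event rate on interval i is

    b_i = lambda_S * k_i^p_S + lambda_C * sum_j [n_{i,j} (n_{i,j}-1)]^p_C

and the log-likelihood is  sum_i ( ln b_i  -  b_i x_i ),  conditioning on the
root event and omitting the eventless span below the youngest node.  With
p_S = p_C = 1 the two terms reduce to a Yule process and a set of independent
neutral coalescents.  The null model (one process on the whole tree) is the
special case T above the root, so the alternative is nested and the
likelihood-ratio statistic is non-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .errors import InputError, OptimizationError
from .trees import TreeNode, UltrametricTree

LOG_ZERO = -1e300  # flagged stand-in for log(0) on an interval with an event


@dataclass(frozen=True)
class GmycConfig:
    """Options for the single-threshold fit.

    estimate_p
        If True, the scaling exponents p_S, p_C are estimated in [0, 2];
        otherwise they are fixed (default 1, the pure Yule/coalescent case,
        which is more stable on small trees).
    df
        Degrees of freedom of the chi-square reference distribution for the
        likelihood-ratio test (threshold + one extra rate [+ exponents]).
    """

    estimate_p: bool = False
    df: int = 3
    p_s: float = 1.0
    p_c: float = 1.0


@dataclass
class GmycFit:
    """Result of a single-threshold GMYC fit."""

    T_hat: float
    lambda_S: float
    lambda_C: float
    p_S: float
    p_C: float
    logL_alt: float
    logL_null: float
    LR: float
    p_value: float
    n_entities: int
    cluster_map: dict[str, str]
    threshold_scan: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "T_hat": self.T_hat,
            "lambda_S": self.lambda_S,
            "lambda_C": self.lambda_C,
            "p_S": self.p_S,
            "p_C": self.p_C,
            "logL_alt": self.logL_alt,
            "logL_null": self.logL_null,
            "LR": self.LR,
            "p_value": self.p_value,
            "n_entities": self.n_entities,
            "cluster_map": dict(sorted(self.cluster_map.items())),
        }


# ---------------------------------------------------------------------------
# entities


def entities_at_threshold(
    tree: UltrametricTree, T: float
) -> tuple[dict[str, str], int]:
    """Entities defined by the branches crossing height ``T``.

    Each branch whose parent is above T and whose child node is at or below T
    defines one entity comprising the tips beneath it.  Entities are labelled
    by their alphabetically first tip.  Returns ``(cluster_map, n_entities)``.
    """
    if T < 0:
        raise InputError(f"threshold must be >= 0, got {T}")
    cluster_map: dict[str, str] = {}
    n_entities = 0

    def assign(node: TreeNode) -> None:
        nonlocal n_entities
        tips = sorted(tree.leaf_names_below(node))
        label = tips[0]
        n_entities += 1
        for t in tips:
            cluster_map[t] = label

    if tree.root.height <= T:
        assign(tree.root)
        return cluster_map, n_entities
    stack = list(tree.root.children)
    while stack:
        node = stack.pop()
        if node.height <= T:
            assign(node)
        else:
            stack.extend(node.children)
    return cluster_map, n_entities


# ---------------------------------------------------------------------------
# interval bookkeeping


def _sorted_events(tree: UltrametricTree) -> list[TreeNode]:
    order = {n: i for i, n in enumerate(tree.preorder())}
    events = tree.internal_nodes()
    # descending height; preorder index breaks ties so parents precede
    # children among simultaneous (zero-length) events
    return sorted(events, key=lambda n: (-n.height, order[n]))


def interval_stats(
    tree: UltrametricTree, T: float
) -> list[tuple[float, int, list[int]]]:
    """Per-interval (duration, diversification-lineage count, cluster sizes).

    Cluster sizes list only entities with >= 2 lineages present (singleton
    coalescent lineages contribute no waiting rate).
    """
    events = _sorted_events(tree)
    if len(events) < 2:
        return []
    # entity membership under T, for branches entirely below T
    cluster_map, _ = entities_at_threshold(tree, T) if T >= 0 else ({}, 0)

    def entity_of(node: TreeNode) -> str:
        tips = sorted(tree.leaf_names_below(node))
        return cluster_map[tips[0]]

    active: list[TreeNode] = list(tree.root.children)
    stats_list: list[tuple[float, int, list[int]]] = []
    prev_h = tree.root.height
    for node in events[1:]:
        x = prev_h - node.height
        k = 0
        clusters: dict[str, int] = {}
        for branch in active:
            if branch.parent.height > T:
                k += 1
            else:
                lab = entity_of(branch)
                clusters[lab] = clusters.get(lab, 0) + 1
        stats_list.append(
            (x, k, sorted(v for v in clusters.values() if v >= 2))
        )
        active.remove(node)
        active.extend(node.children)
        prev_h = node.height
    return stats_list


# ---------------------------------------------------------------------------
# likelihoods


def _loglik_from_stats(
    stats_list: list[tuple[float, int, list[int]]],
    lambda_s: float,
    lambda_c: float,
    p_s: float,
    p_c: float,
) -> float:
    ll = 0.0
    for x, k, ns in stats_list:
        b_s = lambda_s * k**p_s if k > 0 else 0.0
        b_c = lambda_c * sum((n * (n - 1)) ** p_c for n in ns)
        b = b_s + b_c
        if b <= 0.0:
            return LOG_ZERO
        ll += math.log(b) - b * x
    return ll


def gmyc_loglik(
    tree: UltrametricTree,
    T: float,
    lambda_s: float,
    lambda_c: float,
    p_s: float = 1.0,
    p_c: float = 1.0,
) -> float:
    """Mixed-model log-likelihood at threshold ``T``.

    Intervals of zero duration (simultaneous nodes) contribute only the event
    term.  Returns ``LOG_ZERO`` if the rate vanishes on an interval that ends
    with an event.
    """
    if lambda_s <= 0 or lambda_c <= 0:
        raise InputError("rate parameters must be > 0")
    if not (0 <= p_s <= 2 and 0 <= p_c <= 2):
        raise InputError("scaling exponents must lie in [0, 2]")
    if tree.n_tips < 3:
        raise InputError("model fitting requires >= 3 tips")
    return _loglik_from_stats(interval_stats(tree, T), lambda_s, lambda_c, p_s, p_c)


def null_loglik(tree: UltrametricTree, lambda0: float, p0: float = 1.0) -> float:
    """Single-process null: b_i = lambda0 * [N_i (N_i - 1)]^p0 on all intervals."""
    if lambda0 <= 0:
        raise InputError("lambda0 must be > 0")
    if tree.n_tips < 3:
        raise InputError("model fitting requires >= 3 tips")
    events = _sorted_events(tree)
    ll = 0.0
    prev_h = tree.root.height
    n_lineages = 2
    for node in events[1:]:
        x = prev_h - node.height
        b = lambda0 * (n_lineages * (n_lineages - 1)) ** p0
        if b <= 0:
            return LOG_ZERO
        ll += math.log(b) - b * x
        n_lineages += 1
        prev_h = node.height
    return ll


# ---------------------------------------------------------------------------
# fitting


def _maximize_at_threshold(
    stats_list: list[tuple[float, int, list[int]]], cfg: GmycConfig
) -> tuple[float, float, float, float, float]:
    """Maximize logL over rates (and exponents) at a fixed threshold.

    Returns (logL, lambda_S, lambda_C, p_S, p_C).
    """
    m = len(stats_list)
    if m == 0:
        raise InputError("tree too small: no inter-event interval")

    def negll_rates(v: np.ndarray, p_s: float, p_c: float) -> float:
        return -_loglik_from_stats(
            stats_list, math.exp(v[0]), math.exp(v[1]), p_s, p_c
        )

    # moment-style starting rates: events per unit of summed weighted time
    tot_x = sum(x for x, _, _ in stats_list) or 1.0
    start = math.log(max(m / tot_x, 1e-6))
    bounds2 = [(-25.0, 25.0)] * 2

    best: tuple[float, float, float, float, float] | None = None
    if cfg.estimate_p:
        def negll4(v: np.ndarray) -> float:
            return -_loglik_from_stats(
                stats_list, math.exp(v[0]), math.exp(v[1]), v[2], v[3]
            )

        for p0 in (1.0, 0.5):
            res = optimize.minimize(
                negll4,
                x0=np.array([start, start, p0, p0]),
                method="L-BFGS-B",
                bounds=bounds2 + [(0.0, 2.0)] * 2,
            )
            cand = (
                -res.fun,
                math.exp(res.x[0]),
                math.exp(res.x[1]),
                float(res.x[2]),
                float(res.x[3]),
            )
            if best is None or cand[0] > best[0]:
                best = cand
    else:
        for s0, s1 in ((start, start), (start + 2.0, start - 2.0), (start - 2.0, start + 2.0)):
            res = optimize.minimize(
                negll_rates,
                x0=np.array([s0, s1]),
                args=(cfg.p_s, cfg.p_c),
                method="L-BFGS-B",
                bounds=bounds2,
            )
            cand = (
                -res.fun,
                math.exp(res.x[0]),
                math.exp(res.x[1]),
                cfg.p_s,
                cfg.p_c,
            )
            if best is None or cand[0] > best[0]:
                best = cand
    if best is None or not math.isfinite(best[0]):
        raise OptimizationError("likelihood maximization failed at threshold")
    return best


def candidate_thresholds(tree: UltrametricTree) -> list[float]:
    """Threshold grid: midpoints between distinct node heights, plus one
    candidate below the youngest node and one above the root (the null)."""
    hs = sorted(set(n.height for n in tree.internal_nodes()))
    cands = [0.5 * hs[0]]
    cands += [0.5 * (a + b) for a, b in zip(hs, hs[1:])]
    cands.append(hs[-1] * 1.1 + 1.0)  # older than the root: null boundary
    return cands


def fit_gmyc_single(
    tree: UltrametricTree, config: Optional[GmycConfig] = None
) -> GmycFit:
    """Fit the single-threshold model by scanning candidate thresholds.

    The likelihood is piecewise in T between node heights, so the scan over
    inter-node midpoints is exhaustive.  The null (one process on the whole
    tree) is the above-root candidate, so logL_alt >= logL_null always.
    """
    cfg = config or GmycConfig()
    if tree.n_tips < 3:
        raise InputError("model fitting requires >= 3 tips")
    if tree.n_tips < 4:
        import warnings

        warnings.warn("GMYC fit on < 4 tips is weakly informative", stacklevel=2)
    cands = candidate_thresholds(tree)
    scan: list[tuple[float, float]] = []
    best = None
    for T in cands:
        stats_list = interval_stats(tree, T)
        ll, lam_s, lam_c, p_s, p_c = _maximize_at_threshold(stats_list, cfg)
        scan.append((T, ll))
        if best is None or ll > best[1]:
            best = (T, ll, lam_s, lam_c, p_s, p_c)
    assert best is not None
    logL_null = scan[-1][1]  # above-root candidate
    T_hat, logL_alt, lam_s, lam_c, p_s, p_c = best
    lr = max(2.0 * (logL_alt - logL_null), 0.0)
    p_value = float(stats.chi2.sf(lr, df=cfg.df)) if lr > 0 else 1.0
    cluster_map, n_entities = entities_at_threshold(tree, T_hat)
    return GmycFit(
        T_hat=T_hat,
        lambda_S=lam_s,
        lambda_C=lam_c,
        p_S=p_s,
        p_C=p_c,
        logL_alt=logL_alt,
        logL_null=logL_null,
        LR=lr,
        p_value=p_value,
        n_entities=n_entities,
        cluster_map=cluster_map,
        threshold_scan=scan,
    )
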