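"""General mixed Yule-coalescent (GMYC) species delimitation.

The model: an ultrametric single-locus tree is generated by interspecific
diversification (Yule) branching near the root and intraspecific coalescent
branching near the tips.  A threshold age T separates the two regimes:
internal nodes older than T belong to the diversification process, strictly
younger nodes to the coalescent process of their cluster.  Tips subtended by
a coalescent subtree form a *cluster*; tips whose lineage never enters a
coalescent subtree are *singletons*; clusters + singletons = delimited
*entities*.

Between successive branching ages the waiting time ``x_i`` competes against
a combined branching rate

    b_i = lambda1 * n_Y,i ** p1  +  lambda2 * sum_k [n_k,i (n_k,i - 1)] ** p2

where ``n_Y,i`` counts lineages whose parent node is in the diversification
process and ``n_k,i`` counts lineages inside coalescent cluster k.  The
log-likelihood is ``sum_i [log b_i - b_i x_i]`` over the n-1 waiting
intervals from the root to the present (the exponents p1, p2 make each
process's rate an exponential-family distortion of the pure Yule /
Kingman expectations; p1 = p2 = 1 recovers those).

Fitting is by bounded quasi-Newton (L-BFGS-B) with a fixed multistart grid.
The null model is a single coalescent-type process ``lambda [n(n-1)]**p``
over the whole tree (k = 2 parameters); the single-threshold model scans
every branching age as a candidate T (k = 5); the multiple-threshold model
hill-climbs over per-lineage threshold assignments starting from the
single-threshold optimum.  Model choice and averaging use AICc with tip
count as the sample size.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import NumericalError, TreeError
from .io_formats import TreeNode, UltrametricTree

_EPS_REL = 1e-9  # relative perturbation for simultaneous node ages


# ---------------------------------------------------------------------------
# Interval bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class IntervalTable:
    """Ordered branching ages (root first) and waiting-interval data."""

    ages: np.ndarray          # distinct branching ages, descending
    x: np.ndarray             # interval durations; x.sum() == root age
    lineages: np.ndarray      # total lineage count within each interval
    perturbed: bool           # True if simultaneous ages were nudged


def _perturb_ties(tree: UltrametricTree) -> tuple[UltrametricTree, bool]:
    """Return a copy in which equal internal node ages are separated by a
    deterministic epsilon (< 1e-9 x root age), preserving parent>child."""
    tree = tree.copy()
    internals = tree.internal_nodes()  # preorder: parents precede children
    ages = [n.age for n in internals]
    if len(set(ages)) == len(ages):
        return tree, False
    eps = _EPS_REL * tree.root_age / max(len(internals), 1)
    seen: dict[float, int] = {}
    for node in internals:  # preorder => ties broken downward, child younger
        count = seen.get(node.age, 0)
        seen[node.age] = count + 1
        if count:
            node.age = node.age - count * eps
    return tree, True


def branching_intervals(tree: UltrametricTree) -> IntervalTable:
    """Waiting intervals between successive branching ages.

    Requires a binary ultrametric tree with at least 3 tips (outgroups
    should be pruned first).  Simultaneous node ages are perturbed
    deterministically and the fact recorded.
    """
    if tree.n_tips < 3:
        raise TreeError("GMYC needs at least 3 tips")
    return _intervals_impl(tree)


def _intervals_impl(tree: UltrametricTree) -> IntervalTable:
    if tree.n_tips < 2:
        raise TreeError("need at least 2 tips")
    if not tree.is_binary():
        raise TreeError("GMYC requires a fully bifurcating tree")
    tree2, perturbed = _perturb_ties(tree)
    ages = np.sort([n.age for n in tree2.internal_nodes()])[::-1]
    bounds = np.concatenate([ages, [0.0]])
    x = -np.diff(bounds)
    lineages = np.arange(2, len(ages) + 2)
    return IntervalTable(ages=ages, x=x, lineages=lineages, perturbed=perturbed)


class _TreeData:
    """Precomputed structures shared by all fits on one tree."""

    def __init__(self, tree: UltrametricTree):
        self.table = _intervals_impl(tree)  # validates shape
        self.tree, self.perturbed = _perturb_ties(tree)
        self.internals = self.tree.internal_nodes()   # preorder
        self.index = {id(n): k for k, n in enumerate(self.internals)}
        self.ages = np.array([n.age for n in self.internals])
        order = np.argsort(self.ages)[::-1]
        self.sorted_ages = self.ages[order]
        bounds = np.concatenate([self.sorted_ages, [0.0]])
        self.x = -np.diff(bounds)
        mids = (bounds[:-1] + bounds[1:]) / 2.0
        # one edge per non-root node; edge crossing matrix E x I
        self.edges: list[TreeNode] = [
            n for n in self.tree.root.preorder() if n.parent is not None
        ]
        pa = np.array([e.parent.age for e in self.edges])
        ca = np.array([e.age for e in self.edges])
        self.cross = (pa[:, None] > mids[None, :]) & (mids[None, :] > ca[:, None])
        self.n_tips = self.tree.n_tips
        self.root_age = self.tree.root_age

    # -- assignments -----------------------------------------------------
    def all_coalescent(self) -> frozenset:
        return frozenset(range(len(self.internals)))

    def threshold_assignment(self, T: float) -> frozenset:
        """Coalescent node set for a single threshold: ages strictly < T."""
        return frozenset(
            k for k, n in enumerate(self.internals) if n.age < T
        )

    def candidate_assignments(self) -> list[tuple[float, frozenset]]:
        """All single-threshold candidates: every branching age plus the
        all-coalescent (T above the root) and all-diversification (T = 0)
        extremes, de-duplicated."""
        cands: list[tuple[float, frozenset]] = []
        seen = set()
        for T in [math.inf, *sorted(self.ages, reverse=True), 0.0]:
            a = self.threshold_assignment(T)
            if a not in seen:
                seen.add(a)
                cands.append((T, a))
        return cands

    def decompose(self, coal: frozenset):
        """Clusters (tip-label lists) and singletons for an assignment."""
        cluster_of: dict[int, int] = {}
        clusters: list[list[str]] = []
        root_of: list[TreeNode] = []
        for node in self.tree.root.preorder():
            if node.is_leaf:
                continue
            k = self.index[id(node)]
            if k not in coal:
                continue
            pk = (
                self.index[id(node.parent)] if node.parent is not None else None
            )
            if pk is not None and pk in coal:
                cluster_of[k] = cluster_of[pk]
            else:
                cluster_of[k] = len(clusters)
                clusters.append([])
                root_of.append(node)
        for r, members in zip(root_of, clusters):
            members.extend(t.label for t in r.leaves())
        clustered = {m for c in clusters for m in c}
        singletons = [t.label for t in self.tree.tips() if t.label not in clustered]
        return clusters, singletons

    def counts(self, coal: frozenset):
        """Per-interval Yule lineage counts and cluster n(n-1) matrix."""
        cluster_of: dict[int, int] = {}
        n_clusters = 0
        for node in self.tree.root.preorder():
            if node.is_leaf:
                continue
            k = self.index[id(node)]
            if k not in coal:
                continue
            pk = self.index[id(node.parent)] if node.parent is not None else None
            if pk is not None and pk in coal:
                cluster_of[k] = cluster_of[pk]
            else:
                cluster_of[k] = n_clusters
                n_clusters += 1
        I = len(self.x)
        nY = np.zeros(I)
        P = np.zeros((I, n_clusters))
        for e_idx, node in enumerate(self.edges):
            pk = self.index[id(node.parent)]
            row = self.cross[e_idx]
            if pk in coal:
                P[:, cluster_of[pk]] += row
            else:
                nY += row
        return nY, P  # P holds raw per-cluster lineage counts

    def is_valid(self, coal: frozenset) -> bool:
        """Coalescent subtrees must be down-closed (no Yule node below a
        coalescent node)."""
        for node in self.internals:
            k = self.index[id(node)]
            if k in coal:
                for c in node.children:
                    if not c.is_leaf and self.index[id(c)] not in coal:
                        return False
        return True


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GMYCParams:
    lambda1: float
    lambda2: float
    p1: float
    p2: float
    thresholds: tuple[float, ...] = ()


#: When True (default) the coalescent exponent applies to the whole product
#: n(n-1), symmetric with the null model; when False it applies to (n-1)
#: only, i.e. n * (n-1)^p2.  Module-level switch because it selects a model
#: convention, not a per-fit tuning knob.
EXPONENT_ON_PRODUCT = True


def _rate(nY, P, x, lam1, lam2, p1, p2):
    a = np.where(nY > 0, lam1 * np.power(np.maximum(nY, 1e-300), p1), 0.0)
    if P.shape[1]:
        if EXPONENT_ON_PRODUCT:
            prod = P * (P - 1.0)
            terms = np.where(prod > 0, np.power(np.maximum(prod, 1e-300), p2), 0.0)
        else:
            terms = np.where(
                P > 1, P * np.power(np.maximum(P - 1.0, 1e-300), p2), 0.0
            )
        c = lam2 * terms.sum(axis=1)
    else:
        c = 0.0
    return a + c


def _loglik_arrays(nY, P, x, lam1, lam2, p1, p2) -> float:
    b = _rate(nY, P, x, lam1, lam2, p1, p2)
    if np.any(b <= 0.0) or not np.all(np.isfinite(b)):
        return -math.inf
    return float((np.log(b) - b * x).sum())


def loglik(
    tree: UltrametricTree,
    params: GMYCParams,
    coalescent_ages_below: float | None = None,
) -> float:
    """Mixed-model log-likelihood for explicit parameter values.

    The process assignment is derived from a single threshold age: nodes
    strictly younger than the threshold are coalescent.  When
    ``coalescent_ages_below`` is None, ``max(params.thresholds)`` is used,
    or the whole tree is treated as one coalescent process if no threshold
    is recorded.  Returns ``-inf`` (never raises) when a waiting interval
    has zero total rate.
    """
    data = _TreeData(tree)
    if coalescent_ages_below is None:
        coalescent_ages_below = (
            max(params.thresholds) if params.thresholds else math.inf
        )
    coal = data.threshold_assignment(coalescent_ages_below)
    nY, P = data.counts(coal)
    return _loglik_arrays(
        nY, P, data.x, params.lambda1, params.lambda2, params.p1, params.p2
    )


# ---------------------------------------------------------------------------
# Fit containers
# ---------------------------------------------------------------------------

def aicc(logL: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion; n = number of tips."""
    if n - k - 1 <= 0:
        raise NumericalError(
            f"AICc undefined: n - k - 1 = {n - k - 1} (tree too small "
            f"for k = {k} parameters)"
        )
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class GMYCFit:
    params: GMYCParams
    logL: float
    k: int
    clusters: list[list[str]]
    singletons: list[str]
    n_tips: int
    method: str
    converged: bool = True
    coalescent_nodes: frozenset = field(default_factory=frozenset, repr=False)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def entities(self) -> int:
        return len(self.clusters) + len(self.singletons)

    @property
    def aicc(self) -> float:
        return aicc(self.logL, self.k, self.n_tips)

    def summary(self) -> dict:
        return {
            "method": self.method,
            "logL": self.logL,
            "k": self.k,
            "lambda1": self.params.lambda1,
            "lambda2": self.params.lambda2,
            "p1": self.params.p1,
            "p2": self.params.p2,
            "thresholds": list(self.params.thresholds),
            "clusters": self.n_clusters,
            "entities": self.entities,
        }


# ---------------------------------------------------------------------------
# Optimisation
# ---------------------------------------------------------------------------

_P_BOUNDS = (0.0, 3.0)


def _multistart_grid(lam0: float, n_starts: int):
    """Fixed grid of (lambda factor, p) starting points around a moment
    estimate of the rate."""
    factors = [1.0, 0.1, 10.0, 0.02, 50.0]
    ps = [1.0, 0.5, 1.8, 0.2]
    grid = []
    for p in ps:
        for f in factors:
            grid.append((lam0 * f, p))
    return grid[: max(n_starts, 1)]


def _optimize_rates(
    nY, P, x, n_events, n_starts=10, fix_p=None, extra_starts=(),
):
    """Maximise the mixed likelihood over (lambda1, lambda2, p1, p2).

    Parameters are optimised as (log lambda1, log lambda2, p1, p2) with
    L-BFGS-B.  ``extra_starts`` are full 4-tuples prepended to the grid
    (used to seed nested models with their parent optimum).
    """
    # moment start: lambda such that expected events ~ observed intervals
    denom_y = float((np.where(nY > 0, nY, 0.0) * x).sum())
    denom_c = float(
        ((P * (P - 1.0)).clip(min=0.0).sum(axis=1) * x).sum()
    ) if P.shape[1] else 0.0
    lam_y0 = n_events / denom_y if denom_y > 0 else 1.0
    lam_c0 = n_events / denom_c if denom_c > 0 else 1.0

    def unpack(theta):
        l1, l2 = math.exp(theta[0]), math.exp(theta[1])
        if fix_p is not None:
            return l1, l2, fix_p, fix_p
        return l1, l2, theta[2], theta[3]

    def nll(theta):
        val = _loglik_arrays(nY, P, x, *unpack(theta))
        return -val if math.isfinite(val) else 1e12

    lo1 = math.log(max(lam_y0, 1e-12)) - 14
    hi1 = math.log(max(lam_y0, 1e-12)) + 14
    lo2 = math.log(max(lam_c0, 1e-12)) - 14
    hi2 = math.log(max(lam_c0, 1e-12)) + 14
    if fix_p is None:
        bounds = [(lo1, hi1), (lo2, hi2), _P_BOUNDS, _P_BOUNDS]
    else:
        bounds = [(lo1, hi1), (lo2, hi2)]

    starts = []
    for s in extra_starts:
        l1, l2, p1, p2 = s
        t = [
            min(max(math.log(max(l1, 1e-12)), lo1), hi1),
            min(max(math.log(max(l2, 1e-12)), lo2), hi2),
        ]
        if fix_p is None:
            t += [p1, p2]
        starts.append(np.array(t))
    for lam_f, p in _multistart_grid(1.0, n_starts):
        t = [
            min(max(math.log(lam_y0 * lam_f), lo1), hi1),
            min(max(math.log(lam_c0 * lam_f), lo2), hi2),
        ]
        if fix_p is None:
            t += [p, p]
        starts.append(np.array(t))

    best_val, best_theta, any_ok = math.inf, None, False
    for t0 in starts:
        res = optimize.minimize(
            nll, t0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        any_ok = any_ok or res.success
        if res.fun < best_val:
            best_val, best_theta = res.fun, res.x
    if best_theta is None or not math.isfinite(best_val):
        raise NumericalError(
            f"rate optimisation failed after {len(starts)} starts "
            f"(best objective {best_val})"
        )
    l1, l2, p1, p2 = unpack(best_theta)
    return (l1, l2, p1, p2), -best_val, any_ok


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

def fit_null(
    tree: UltrametricTree, n_starts: int = 10, fix_p: float | None = None
) -> GMYCFit:
    """Null model: one coalescent-type process lambda [n(n-1)]**p over the
    whole tree (k = 2 free parameters)."""
    data = _TreeData(tree)
    coal = data.all_coalescent()
    nY, P = data.counts(coal)
    n_events = len(data.x)
    (l1, l2, p1, p2), logL, ok = _optimize_rates(
        nY, P, data.x, n_events, n_starts=n_starts, fix_p=fix_p
    )
    clusters, singletons = data.decompose(coal)
    return GMYCFit(
        params=GMYCParams(0.0, l2, 0.0, p2, thresholds=()),
        logL=logL,
        k=2,
        clusters=clusters,
        singletons=singletons,
        n_tips=data.n_tips,
        method="null",
        converged=ok,
        coalescent_nodes=coal,
    )


def _fit_assignment(
    data: _TreeData,
    coal: frozenset,
    threshold: tuple[float, ...],
    k: int,
    method: str,
    n_starts: int,
    extra_starts=(),
) -> GMYCFit:
    nY, P = data.counts(coal)
    (l1, l2, p1, p2), logL, ok = _optimize_rates(
        nY, P, data.x, len(data.x), n_starts=n_starts, extra_starts=extra_starts
    )
    clusters, singletons = data.decompose(coal)
    return GMYCFit(
        params=GMYCParams(l1, l2, p1, p2, thresholds=threshold),
        logL=logL,
        k=k,
        clusters=clusters,
        singletons=singletons,
        n_tips=data.n_tips,
        method=method,
        converged=ok,
        coalescent_nodes=coal,
    )


def candidate_single_threshold_fits(
    tree: UltrametricTree, n_starts: int = 10
) -> tuple[GMYCFit, list[GMYCFit]]:
    """Fit the null model and every single-threshold candidate model.

    Candidate thresholds are the branching ages plus the all-coalescent and
    all-diversification extremes.  The null optimum seeds the all-coalescent
    candidate, which guarantees max logL(single) >= max logL(null).
    """
    data = _TreeData(tree)
    null = fit_null(tree, n_starts=n_starts)
    seed_params = (
        max(null.params.lambda2, 1e-12),
        null.params.lambda2,
        null.params.p2,
        null.params.p2,
    )
    fits = []
    for T, coal in data.candidate_assignments():
        fits.append(
            _fit_assignment(
                data, coal, (T,), 5, "single", n_starts,
                extra_starts=[seed_params],
            )
        )
    return null, fits


def fit_single_threshold(tree: UltrametricTree, n_starts: int = 10) -> GMYCFit:
    """Best single-threshold GMYC fit (k = 5: four rate/exponent parameters
    plus the threshold age)."""
    _, fits = candidate_single_threshold_fits(tree, n_starts=n_starts)
    return max(fits, key=lambda f: f.logL)


def minimal_threshold_set(data: _TreeData, coal: frozenset) -> tuple[float, ...]:
    """Smallest set of threshold ages generating an assignment.

    Every Yule->coalescent boundary edge constrains its lineage's threshold
    to the open age interval (child, parent); singleton tip edges under a
    Yule parent constrain it to (0, parent).  The minimum number of
    distinct threshold values is the minimum piercing set of these
    intervals (greedy on upper endpoints); a single-threshold assignment
    yields exactly one.
    """
    intervals: list[tuple[float, float]] = []
    for node in data.tree.root.preorder():
        if node.parent is None:
            continue
        pk = data.index.get(id(node.parent))
        parent_is_coal = pk in coal
        if parent_is_coal:
            continue
        if node.is_leaf:
            intervals.append((0.0, node.parent.age))
        elif data.index[id(node)] in coal:
            intervals.append((node.age, node.parent.age))
    if not intervals:
        return ()
    intervals.sort(key=lambda iv: iv[1])
    points: list[float] = []
    for lo, hi in intervals:
        if points and points[-1] > lo:
            continue
        points.append(lo + (hi - lo) * (1 - 1e-9))
    return tuple(sorted(points, reverse=True))


def fit_multiple_threshold(
    tree: UltrametricTree,
    max_iter: int = 10_000,
    seed: int = 0,
    n_starts: int = 4,
    start: GMYCFit | None = None,
) -> GMYCFit:
    """Multiple-threshold GMYC by hill climbing over assignments.

    Starting from the single-threshold optimum, repeatedly propose moving
    one cluster boundary to an adjacent node — either promoting a cluster
    root to the diversification process (splitting it) or demoting a
    lowest diversification node to coalescent (merging its descendants) —
    re-optimising the rates at each proposal and accepting improvements,
    until a local optimum or ``max_iter`` proposals.  Proposal order is
    shuffled by ``seed``.  k = 4 + number of distinct thresholds (minimum
    piercing count, see :func:`minimal_threshold_set`).
    """
    data = _TreeData(tree)
    if start is None:
        start = fit_single_threshold(tree, n_starts=max(n_starts, 4))
    coal = start.coalescent_nodes
    best = start
    rng = random.Random(seed)
    proposals = 0
    improved = True
    while improved and proposals < max_iter:
        improved = False
        moves = []
        coal_set = best.coalescent_nodes
        for node in data.internals:
            k = data.index[id(node)]
            if k in coal_set:
                pk = data.index.get(id(node.parent)) if node.parent else None
                if pk is None or pk not in coal_set:
                    moves.append(("promote", k))
            else:
                if all(
                    c.is_leaf or data.index[id(c)] in coal_set
                    for c in node.children
                ):
                    moves.append(("demote", k))
        rng.shuffle(moves)
        for kind, k in moves:
            if proposals >= max_iter:
                break
            proposals += 1
            new_coal = (
                frozenset(best.coalescent_nodes - {k})
                if kind == "promote"
                else frozenset(best.coalescent_nodes | {k})
            )
            thr = minimal_threshold_set(data, new_coal)
            cand = _fit_assignment(
                data, new_coal, thr, 4 + max(len(thr), 1), "multiple",
                n_starts,
                extra_starts=[
                    (
                        max(best.params.lambda1, 1e-12),
                        max(best.params.lambda2, 1e-12),
                        best.params.p1,
                        best.params.p2,
                    )
                ],
            )
            if cand.logL > best.logL + 1e-10:
                best = cand
                improved = True
                break
    converged = not improved or proposals < max_iter
    if proposals >= max_iter and improved:
        warnings.warn(
            "multiple-threshold search hit max_iter before a local optimum; "
            "returning best fit so far"
        )
        converged = False
    thr = minimal_threshold_set(data, best.coalescent_nodes)
    return GMYCFit(
        params=GMYCParams(
            best.params.lambda1, best.params.lambda2,
            best.params.p1, best.params.p2, thresholds=thr,
        ),
        logL=best.logL,
        k=4 + max(len(thr), 1),
        clusters=best.clusters,
        singletons=best.singletons,
        n_tips=best.n_tips,
        method="multiple",
        converged=converged,
        coalescent_nodes=best.coalescent_nodes,
    )


# ---------------------------------------------------------------------------
# Tests and model averaging
# ---------------------------------------------------------------------------

def lr_test(logL0: float, logL1: float, df: int = 2) -> tuple[float, float]:
    """Likelihood-ratio test: 2(logL1 - logL0) against chi-square(df).

    Negative ratios (alternative worse than null, possible with distinct
    candidate sets) are clamped to 0 with a warning.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    ratio = 2.0 * (logL1 - logL0)
    if ratio < 0:
        warnings.warn(f"negative LR ratio {ratio:.6g} clamped to 0")
        ratio = 0.0
    p = float(stats.chi2.sf(ratio, df))
    return ratio, p


@dataclass
class MultimodelResult:
    fits: list[GMYCFit]            # retained models, ordered by AICc
    weights: np.ndarray            # Akaike weights (sum to 1)
    delta_aicc: np.ndarray
    mean_clusters: float
    var_clusters: float
    mean_entities: float
    var_entities: float
    tip_labels: list[str]
    pair_prob: np.ndarray          # n x n cluster co-membership probability
    n_candidates: int

    def pair_probability(self, a: str, b: str) -> float:
        i, j = self.tip_labels.index(a), self.tip_labels.index(b)
        return float(self.pair_prob[i, j])


def multimodel_average(
    fits: list[GMYCFit],
    tip_labels: list[str],
    cutoff: float = 7.0,
) -> MultimodelResult:
    """AICc model averaging over a candidate set (null + all
    single-threshold fits by default; composition is up to the caller and
    recorded via ``n_candidates``).

    Models within ``cutoff`` AICc units of the best are retained; Akaike
    weights are exp(-dAICc/2) normalised.  Averaged cluster and entity
    counts carry between-model variances, and ``pair_prob[i, j]`` is the
    summed weight of retained models placing tips i and j in one cluster.
    """
    if not fits:
        raise ValueError("no candidate fits")
    aiccs = np.array([f.aicc for f in fits])
    delta = aiccs - aiccs.min()
    keep = delta <= cutoff
    kept = [f for f, k in zip(fits, keep) if k]
    dk = delta[keep]
    order = np.argsort(dk)
    kept = [kept[i] for i in order]
    dk = dk[order]
    w = np.exp(-dk / 2.0)
    w = w / w.sum()

    cl = np.array([f.n_clusters for f in kept], dtype=float)
    en = np.array([f.entities for f in kept], dtype=float)
    mean_cl = float((w * cl).sum())
    mean_en = float((w * en).sum())
    var_cl = float((w * (cl - mean_cl) ** 2).sum())
    var_en = float((w * (en - mean_en) ** 2).sum())

    idx = {t: i for i, t in enumerate(tip_labels)}
    n = len(tip_labels)
    pair = np.zeros((n, n))
    for f, wm in zip(kept, w):
        for cluster in f.clusters:
            ii = [idx[t] for t in cluster]
            for a_i, a in enumerate(ii):
                for b in ii[a_i + 1 :]:
                    pair[a, b] += wm
                    pair[b, a] += wm
    np.fill_diagonal(pair, 1.0)
    return MultimodelResult(
        fits=kept,
        weights=w,
        delta_aicc=dk,
        mean_clusters=mean_cl,
        var_clusters=var_cl,
        mean_entities=mean_en,
        var_entities=var_en,
        tip_labels=list(tip_labels),
        pair_prob=pair,
        n_candidates=len(fits),
    )


def entities_at_probability(
    mm: MultimodelResult, tree: UltrametricTree, threshold: float
) -> tuple[list[list[str]], list[str]]:
    """Greedy decomposition at a cluster-probability threshold.

    Walking from the root, the maximal clades in which every internal tip
    pair has co-membership probability >= ``threshold`` become clusters;
    all remaining tips are singletons.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    idx = {t: i for i, t in enumerate(mm.tip_labels)}
    clusters: list[list[str]] = []
    singletons: list[str] = []

    def min_pair(tips: list[str]) -> float:
        ii = [idx[t] for t in tips]
        best = 1.0
        for a_i, a in enumerate(ii):
            for b in ii[a_i + 1 :]:
                if mm.pair_prob[a, b] < best:
                    best = mm.pair_prob[a, b]
        return best

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            singletons.append(node.label)
            return
        tips = [t.label for t in node.leaves()]
        if min_pair(tips) >= threshold:
            clusters.append(tips)
            return
        for c in node.children:
            walk(c)

    walk(tree.root)
    return clusters, singletons


def entity_confidence_interval(
    fits: list[GMYCFit], delta: float = 2.0
) -> tuple[int, int]:
    """Range of entity counts among models within ``delta`` log-likelihood
    units of the maximum (the conventional 2-unit support set)."""
    best = max(f.logL for f in fits)
    ents = [f.entities for f in fits if f.logL >= best - delta]
    return min(ents), max(ents)


# ---------------------------------------------------------------------------
# Lineage-through-time
# ---------------------------------------------------------------------------

def ltt(tree: UltrametricTree) -> list[tuple[float, int]]:
    """Lineage-through-time step function: (age, lineage count just below
    that age), from the root (2 lineages) to the youngest node (n)."""
    table = branching_intervals(tree)
    return [(float(a), int(n)) for a, n in zip(table.ages, table.lineages)]


def ltt_plot(tree: UltrametricTree, path: str, log_scale: bool = True) -> None:
    """Write an LTT plot (age axis reversed, optional log lineage axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    steps = ltt(tree)
    ages = [a for a, _ in steps] + [0.0]
    counts = [n for _, n in steps] + [tree.n_tips]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(ages, counts, where="post")
    ax.set_xlim(max(ages), 0)
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel("age")
    ax.set_ylabel("lineages")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
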