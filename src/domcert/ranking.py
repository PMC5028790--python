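"""Linear rank orders, rank transforms, certainty categories, sensitivity.

The dominance-probability matrix is reduced to a single linear hierarchy
by finding the ordering that minimizes the summed cost of its pairwise
placements: placing i above j costs (1 - DP_ij), so placements that the
dyadic probabilities contradict are expensive and a perfectly consistent
matrix is minimized exactly at the true order.  The combinatorial search
uses simulated annealing over adjacent transpositions with a greedy
polish, which for small groups provably reaches the exhaustive optimum
(checked against full permutation search in the tests).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

from .dominance import infer_dominance
from .observations import WinLossMatrix


@dataclasses.dataclass
class RankOrder:
    ids: list[str]  # best to worst
    cost: float

    @property
    def n(self) -> int:
        return len(self.ids)

    def ordinal(self, animal_id: str) -> int:
        """1-based rank, 1 = top."""
        return self.ids.index(animal_id) + 1


def order_cost(dp: np.ndarray, perm: np.ndarray) -> float:
    """Cost of an ordering: sum of (1 - DP_ij) over pairs placed i-above-j."""
    sub = dp[np.ix_(perm, perm)]
    upper = np.triu_indices(len(perm), k=1)
    vals = sub[upper]
    vals = np.where(np.isnan(vals), 0.5, vals)
    return float(np.sum(1.0 - vals))


def find_lowest_cost_order(
    dp: np.ndarray,
    ids: list[str] | None = None,
    seed: int = 0,
    sweeps_per_node_sq: int = 200,
    n_restarts: int = 1,
    t_start: float = 0.5,
    t_end: float = 1e-4,
) -> RankOrder:
    """Lowest-cost linear order of a dominance-probability matrix.

    Deterministic given ``seed``: geometric-cooling simulated annealing
    with adjacent-transposition proposals (the cost change of swapping
    neighbours a, b is simply DP_ab - DP_ba), followed by a greedy
    adjacent-swap polish.  Exact ties between adjacent animals are
    resolved toward the initial id order.
    """
    dp = np.asarray(dp, dtype=float)
    n = dp.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    if n == 1:
        return RankOrder(list(ids), 0.0)
    dpf = np.where(np.isnan(dp), 0.5, dp)
    rng = np.random.default_rng(seed)

    # win-probability row mean gives a David's-score-like warm start
    start_score = dpf.sum(axis=1)
    base_order = np.argsort(-start_score, kind="stable")

    def anneal(order: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        order = order.copy()
        n_steps = sweeps_per_node_sq * n * n
        temps = t_start * (t_end / t_start) ** (
            np.arange(n_steps) / max(n_steps - 1, 1)
        )
        positions = rng.integers(0, n - 1, size=n_steps).tolist()
        # accept a swap iff its cost change is below -T*log(u); this folds
        # the Metropolis test (including delta < 0) into one comparison
        thresholds = (-temps * np.log(rng.random(n_steps))).tolist()
        d = dpf.tolist()
        ordl = order.tolist()
        for step in range(n_steps):
            p = positions[step]
            a = ordl[p]
            b = ordl[p + 1]
            if d[a][b] - d[b][a] < thresholds[step]:
                ordl[p] = b
                ordl[p + 1] = a
        return np.array(ordl)

    def polish(order: np.ndarray) -> np.ndarray:
        ordl = order.tolist()
        improved = True
        while improved:
            improved = False
            for p in range(n - 1):
                a, b = ordl[p], ordl[p + 1]
                delta = dpf[a, b] - dpf[b, a]
                if delta < -1e-15 or (abs(delta) <= 1e-15 and b < a):
                    ordl[p], ordl[p + 1] = b, a
                    improved = True
        return np.array(ordl)

    best_order = None
    best_cost = np.inf
    for r in range(max(n_restarts, 1)):
        init = base_order if r == 0 else rng.permutation(n)
        cand = polish(anneal(init, rng))
        cost = order_cost(dp, cand)
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_order = cand
    return RankOrder([ids[i] for i in best_order], best_cost)


def proportion_outranked(order: RankOrder) -> dict[str, float]:
    """Rank as the fraction of groupmates outranked: top 1, bottom 0."""
    n = order.n
    if n < 2:
        raise ValueError("proportion outranked needs at least 2 animals")
    return {a: (n - (i + 1)) / (n - 1) for i, a in enumerate(order.ids)}


@dataclasses.dataclass
class CertaintyCategories:
    """Group-specific low/moderate/high certainty bands.

    ``breakpoints`` are on the DC scale; ``quantile_breakpoints`` are the
    corresponding positions on the empirical-quantile axis of the
    segmented fit.
    """

    breakpoints: tuple[float, float] | None
    quantile_breakpoints: tuple[float, float] | None
    categories: dict[str, str]


def _segmented_sse(x: np.ndarray, y: np.ndarray, b1: float, b2: float):
    X = np.column_stack(
        [np.ones_like(x), x, np.clip(x - b1, 0, None), np.clip(x - b2, 0, None)]
    )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def categorize_certainty(
    dc: dict[str, float] | "np.ndarray",
    min_gap: float = 0.05,
    grid: int = 40,
) -> CertaintyCategories:
    """Fit a two-breakpoint segmented regression to the DC distribution.

    Sorted DC values are regressed on their empirical quantile with a
    continuous piecewise-linear model holding two breakpoints; the
    breakpoints are found by a coarse-to-fine grid search on the
    quantile axis (deterministic, immune to the local minima that
    iterative linearization can fall into) and mapped back to the DC
    scale through the fitted curve.  Animals below the lower fitted
    breakpoint are "low" certainty, above the upper "high", otherwise
    "moderate".
    """
    if isinstance(dc, dict):
        ids = list(dc)
        vals = np.array([dc[a] for a in ids], dtype=float)
    else:
        vals = np.asarray(dc, dtype=float)
        ids = [str(i) for i in range(len(vals))]
    n = len(vals)
    if n < 10:
        raise ValueError("need at least 10 animals to categorize certainty")
    order = np.argsort(vals, kind="stable")
    y = vals[order]
    x = np.arange(n) / (n - 1)
    if np.ptp(y) < 1e-12:
        warnings.warn("constant dominance certainty; single category")
        return CertaintyCategories(None, None, {a: "moderate" for a in ids})

    def search(b1s: np.ndarray, b2s: np.ndarray):
        best = (np.inf, None, None, None)
        for b1 in b1s:
            for b2 in b2s:
                if b2 - b1 < min_gap:
                    continue
                sse, coef = _segmented_sse(x, y, b1, b2)
                if sse < best[0]:
                    best = (sse, b1, b2, coef)
        return best

    lo, hi = 0.02, 0.98
    cand = np.linspace(lo, hi, grid)
    sse, b1, b2, coef = search(cand, cand)
    # refine around the coarse optimum
    step = (hi - lo) / (grid - 1)
    fine1 = np.linspace(max(lo, b1 - step), min(hi, b1 + step), 21)
    fine2 = np.linspace(max(lo, b2 - step), min(hi, b2 + step), 21)
    sse, b1, b2, coef = search(fine1, fine2)

    def fitted(q: float) -> float:
        return float(
            coef[0] + coef[1] * q + coef[2] * max(q - b1, 0) + coef[3] * max(q - b2, 0)
        )

    dc_b1, dc_b2 = fitted(b1), fitted(b2)
    cats = {}
    for a, v in zip(ids, vals):
        if v < dc_b1:
            cats[a] = "low"
        elif v <= dc_b2:
            cats[a] = "moderate"
        else:
            cats[a] = "high"
    return CertaintyCategories((dc_b1, dc_b2), (float(b1), float(b2)), cats)


@dataclasses.dataclass
class SensitivityReport:
    """Stability of DC values under single-node deletion."""

    correlations: dict[str, dict[str, float]]  # node -> {pearson, spearman}


def node_removal_sensitivity(
    W: WinLossMatrix,
    nodes_to_remove: list[str],
    **dominance_kwargs,
) -> SensitivityReport:
    """Recompute DC after deleting single animals and correlate with original.

    Network metrics are not independent across nodes (paths are shared),
    so this checks how much one animal's presence moves everyone else's
    dominance certainty.  High correlations mean node-level DC values
    can be treated as approximately independent observations.
    """
    base = infer_dominance(W, **dominance_kwargs)
    base_dc = dict(zip(base.ids, base.dc))
    out: dict[str, dict[str, float]] = {}
    for node in nodes_to_remove:
        if node not in W.ids:
            raise ValueError(f"unknown animal id {node!r}")
        if W.n - 1 < 3:
            raise ValueError("removal would leave fewer than 3 animals")
        reduced = W.drop(node)
        res = infer_dominance(reduced, **dominance_kwargs)
        new_dc = dict(zip(res.ids, res.dc))
        keep = [a for a in W.ids if a != node]
        orig = np.array([base_dc[a] for a in keep])
        new = np.array([new_dc[a] for a in keep])
        pear = float(stats.pearsonr(orig, new)[0])
        spear = float(stats.spearmanr(orig, new)[0])
        out[node] = {"pearson": pear, "spearman": spear}
    return SensitivityReport(out)
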