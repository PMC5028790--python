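"""Dominance-probability inference from directed agonistic networks.

The core idea: direct wins are sparse (most dyads in a large group are
never seen to interact), but the win network carries indirect evidence —
if A beats B and B beats C, the directed path A->B->C is (weak) evidence
that A outranks C, and the strength of that evidence scales with how
transitive the network is overall.  This module

1. counts all directed *simple* paths up to a maximum length between
   every ordered pair of animals,
2. measures triad transitivity t (proportion of decided triads that are
   transitive rather than cyclic),
3. converts indirect paths into fractional imputed wins, weighted by a
   transitivity-dependent factor that is always < 1 so a single direct
   win outweighs any single imputed win, and
4. turns the combined win evidence for each dyad into a dominance
   probability DP_ij = P(i outranks j) via a Beta posterior with a
   uniform (add-one) prior, so a dyad with no evidence at all sits at
   the perfectly ambiguous DP = 0.5.

Dyadic certainty is c_ij = max(DP_ij, 1 - DP_ij) in [0.5, 1], and an
animal's dominance certainty (DC) is the mean of c over its dyads.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy import special

from .observations import WinLossMatrix

DEFAULT_MAX_PATH_LEN = 3
DEFAULT_INDIRECT_BETA = 0.5
DEFAULT_PRIOR = 1.0


@dataclasses.dataclass
class PathwayCounts:
    """Directed simple-path counts per ordered pair and path length.

    ``counts[l - 1]`` is the N x N matrix for length ``l``.  Length-1
    counts are the raw direct win counts (direct evidence scales with
    the number of observed wins); lengths >= 2 count distinct simple
    paths in the binarized win graph (an edge i->j exists iff i beat j
    at least once).
    """

    ids: list[str]
    counts: np.ndarray  # shape (max_len, N, N)

    @property
    def max_len(self) -> int:
        return self.counts.shape[0]

    def level(self, length: int) -> np.ndarray:
        return self.counts[length - 1]


@dataclasses.dataclass
class TransitivityReport:
    n_transitive: int
    n_cyclic: int

    @property
    def t(self) -> float | None:
        closed = self.n_transitive + self.n_cyclic
        if closed == 0:
            return None
        return self.n_transitive / closed


def _simple_path_counts_dfs(adj: np.ndarray, max_len: int) -> np.ndarray:
    """Exhaustive DFS over simple paths; exact for any max_len (slow)."""
    n = adj.shape[0]
    out = np.zeros((max_len, n, n))
    succ = [np.flatnonzero(adj[i]) for i in range(n)]

    def extend(start: int, node: int, visited: set[int], edges: int) -> None:
        for nxt in succ[node]:
            if nxt in visited:
                continue
            out[edges, start, nxt] += 1  # path now has edges+1 edges
            if edges + 1 < max_len:
                visited.add(int(nxt))
                extend(start, int(nxt), visited, edges + 1)
                visited.remove(int(nxt))

    for s in range(n):
        extend(s, s, {s}, 0)
    # slot 0 filled by caller (raw counts); here store binary adjacency
    out[0] = adj
    return out


def enumerate_directed_paths(
    W: WinLossMatrix, max_len: int = DEFAULT_MAX_PATH_LEN
) -> PathwayCounts:
    """Count directed simple paths of every length up to ``max_len``.

    For lengths 2 and 3 the counts are computed exactly by
    inclusion–exclusion on powers of the binarized adjacency matrix;
    longer lengths fall back to exhaustive depth-first search.  Both
    routes count the same objects: node-distinct directed paths.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    A = (W.counts > 0).astype(float)
    np.fill_diagonal(A, 0.0)
    n = W.n
    counts = np.zeros((max_len, n, n))
    counts[0] = W.counts  # raw direct wins, not binarized
    if max_len >= 2:
        A2 = A @ A
        L2 = A2.copy()
        np.fill_diagonal(L2, 0.0)  # i -> k -> i is not a pair path
        counts[1] = L2
    if max_len >= 3:
        A3 = A @ A @ A
        d2 = np.diag(A2)
        # remove walks revisiting the endpoint (k = j) or the start (m = i),
        # add back the doubly-degenerate i->j->i->j walks
        L3 = A3 - A * d2[None, :] - d2[:, None] * A + A * A.T * A
        np.fill_diagonal(L3, 0.0)
        counts[2] = L3
    if max_len >= 4:
        counts_dfs = _simple_path_counts_dfs(A, max_len)
        counts[3:] = counts_dfs[3:]
    return PathwayCounts(list(W.ids), counts)


def compute_transitivity(W: WinLossMatrix) -> TransitivityReport:
    """Census decided triads as transitive or cyclic.

    A dyad is *decided* when one animal has strictly more wins over the
    other; triads containing an undecided dyad are excluded.  For a
    triad with three decided dyads, cyclic means A>B>C>A; anything else
    is transitive.
    """
    if W.n < 3:
        raise ValueError("transitivity needs at least 3 animals")
    D = (W.counts > W.counts.T).astype(float)  # strict majority direction
    M = D + D.T  # 0/1 symmetric: decided dyads
    n_closed = int(round(np.trace(M @ M @ M) / 6))
    n_cyclic = int(round(np.trace(D @ D @ D) / 3))
    return TransitivityReport(
        n_transitive=n_closed - n_cyclic, n_cyclic=n_cyclic
    )


def transitivity_weight(
    t: float | None, length: int, beta: float = DEFAULT_INDIRECT_BETA
) -> float:
    """Weight of one imputed win from a path of the given length.

    g(t, l) = beta * max(2t - 1, 0)^(l-1): grows with transitivity,
    decays with path length, vanishes for t <= 0.5 (an untransitive
    network carries no usable indirect information), and is always < 1
    so direct wins dominate imputed ones.
    """
    if length < 2:
        raise ValueError("imputed wins come from paths of length >= 2")
    if t is None:
        t = 0.5
    if not 0.0 <= t <= 1.0:
        raise ValueError("transitivity must lie in [0, 1]")
    return beta * max(2.0 * t - 1.0, 0.0) ** (length - 1)


def impute_wins(
    paths: PathwayCounts,
    t: float | None,
    beta: float = DEFAULT_INDIRECT_BETA,
) -> np.ndarray:
    """Combine direct wins with transitivity-weighted imputed wins."""
    weighted = paths.level(1).astype(float).copy()
    for length in range(2, paths.max_len + 1):
        weighted += transitivity_weight(t, length, beta) * paths.level(length)
    return weighted


def dominance_probability(
    weighted_wins: np.ndarray,
    ids: list[str] | None = None,
    prior: float = DEFAULT_PRIOR,
) -> np.ndarray:
    """Dyadic dominance probabilities from (possibly fractional) win counts.

    DP_ij = P(X > 1/2) for X ~ Beta(w_ij + prior, w_ji + prior).  With
    the default uniform prior, a dyad with no direct or indirect
    evidence sits at DP = 0.5 (perfect ambiguity) and DP_ij + DP_ji = 1
    always.  The diagonal is NaN (self-dominance is undefined).
    """
    w = np.asarray(weighted_wins, dtype=float)
    if (w < 0).any():
        raise ValueError("weighted wins must be nonnegative")
    if prior <= 0:
        raise ValueError("Beta prior must be positive")
    a = w + prior
    # P(X > 1/2) for X ~ Beta(a_ij, a_ji) equals I_{1/2}(a_ji, a_ij)
    dp = special.betainc(a.T, a, 0.5)
    np.fill_diagonal(dp, np.nan)
    return dp


def dyadic_certainty(dp: np.ndarray) -> np.ndarray:
    """c_ij = max(DP_ij, 1 - DP_ij): certainty regardless of direction."""
    c = np.maximum(dp, 1.0 - dp)
    return c


def average_dominance_certainty(c: np.ndarray) -> np.ndarray:
    """Per-animal dominance certainty: mean dyadic certainty over partners."""
    n = c.shape[0]
    if n < 2:
        raise ValueError("dominance certainty needs at least 2 animals")
    return np.nanmean(c, axis=1)


@dataclasses.dataclass
class DominanceResult:
    """Bundle of per-group dominance inference outputs."""

    ids: list[str]
    transitivity: TransitivityReport
    weighted_wins: np.ndarray
    dp: np.ndarray
    certainty: np.ndarray
    dc: np.ndarray


def infer_dominance(
    W: WinLossMatrix,
    max_len: int = DEFAULT_MAX_PATH_LEN,
    beta: float = DEFAULT_INDIRECT_BETA,
    prior: float = DEFAULT_PRIOR,
) -> DominanceResult:
    """Run the full chain: paths -> transitivity -> imputed wins -> DP -> DC."""
    paths = enumerate_directed_paths(W, max_len=max_len)
    trans = compute_transitivity(W)
    weighted = impute_wins(paths, trans.t, beta=beta)
    dp = dominance_probability(weighted, prior=prior)
    c = dyadic_certainty(dp)
    dc = average_dominance_certainty(c)
    return DominanceResult(list(W.ids), trans, weighted, dp, c, dc)
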