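import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import integrate, stats

from domcert.dominance import (
    average_dominance_certainty,
    compute_transitivity,
    dominance_probability,
    dyadic_certainty,
    enumerate_directed_paths,
    impute_wins,
    infer_dominance,
    transitivity_weight,
)
from domcert.observations import WinLossMatrix


def wl(ids, edges):
    n = len(ids)
    counts = np.zeros((n, n))
    for a, b, *w in edges:
        counts[ids.index(a), ids.index(b)] = w[0] if w else 1
    return WinLossMatrix(list(ids), counts)


def nx_path_oracle(counts, max_len):
    """Count simple paths per ordered pair and length via networkx."""
    n = counts.shape[0]
    G = nx.from_numpy_array((counts > 0).astype(int), create_using=nx.DiGraph)
    out = np.zeros((max_len, n, n))
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            for path in nx.all_simple_paths(G, s, t, cutoff=max_len):
                out[len(path) - 2 + 1 - 1, s, t] += 1  # length = edges
    out[0] = counts  # level 1 holds raw counts by convention
    return out


class TestPathEnumeration:
    def test_chain(self):
        W = wl("ABC", [("A", "B"), ("B", "C")])
        paths = enumerate_directed_paths(W)
        assert paths.level(1)[0, 2] == 0
        assert paths.level(2)[0, 2] == 1
        assert paths.level(2)[2, 0] == 0

    def test_multiple_parallel_pathways(self):
        # two node-disjoint 2-step routes A->D and no direct interaction
        W = wl("ABCD", [("A", "B"), ("B", "D"), ("A", "C"), ("C", "D")])
        paths = enumerate_directed_paths(W)
        assert paths.level(1)[0, 3] == 0
        assert paths.level(2)[0, 3] == 2

    def test_invalid_max_len(self):
        W = wl("AB", [("A", "B")])
        with pytest.raises(ValueError):
            enumerate_directed_paths(W, max_len=0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 8)
        counts = rng.integers(0, 3, size=(n, n)).astype(float)
        np.fill_diagonal(counts, 0)
        W = WinLossMatrix([str(i) for i in range(n)], counts)
        for max_len in (3, 5):
            paths = enumerate_directed_paths(W, max_len=max_len)
            oracle = nx_path_oracle(counts, max_len)
            assert np.allclose(paths.counts, oracle)


def bruteforce_transitivity(counts):
    n = counts.shape[0]
    trans = cyc = 0
    for i, j, k in itertools.combinations(range(n), 3):
        dirs = {}
        for a, b in ((i, j), (j, k), (i, k)):
            if counts[a, b] > counts[b, a]:
                dirs[(a, b)] = 1
            elif counts[b, a] > counts[a, b]:
                dirs[(a, b)] = -1
        if len(dirs) < 3:
            continue
        # cyclic iff every node has exactly one win within the triad
        wins = {i: 0, j: 0, k: 0}
        for (a, b), d in dirs.items():
            wins[a if d == 1 else b] += 1
        if sorted(wins.values()) == [1, 1, 1]:
            cyc += 1
        else:
            trans += 1
    return trans, cyc


class TestTransitivity:
    def test_single_transitive_triad(self):
        W = wl("ABC", [("A", "B"), ("B", "C"), ("A", "C")])
        rep = compute_transitivity(W)
        assert rep.t == 1.0

    def test_single_cyclic_triad(self):
        W = wl("ABC", [("A", "B"), ("B", "C"), ("C", "A")])
        rep = compute_transitivity(W)
        assert rep.t == 0.0

    def test_no_closed_triads(self):
        W = wl("ABC", [("A", "B")])
        assert compute_transitivity(W).t is None

    def test_tied_dyads_excluded(self):
        W = wl("ABC", [("A", "B"), ("B", "A"), ("B", "C"), ("A", "C")])
        assert compute_transitivity(W).t is None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_triad_census_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        counts = rng.integers(0, 4, size=(6, 6)).astype(float)
        np.fill_diagonal(counts, 0)
        W = WinLossMatrix(list("ABCDEF"), counts)
        rep = compute_transitivity(W)
        trans, cyc = bruteforce_transitivity(counts)
        assert (rep.n_transitive, rep.n_cyclic) == (trans, cyc)


class TestImputedWins:
    def test_no_indirect_paths_identity(self):
        W = wl("AB", [("A", "B", 3)])
        paths = enumerate_directed_paths(W)
        weighted = impute_wins(paths, t=1.0)
        assert np.allclose(weighted, W.counts)

    def test_uninformative_transitivity_contributes_nothing(self):
        W = wl("ABC", [("A", "B"), ("B", "C")])
        paths = enumerate_directed_paths(W)
        weighted = impute_wins(paths, t=0.5)
        assert np.allclose(weighted, W.counts)

    def test_hand_computed_weighting(self):
        # two 2-step pathways at perfect transitivity: g(1, 2) = 0.5 each
        W = wl("ABCD", [("A", "B"), ("B", "D"), ("A", "C"), ("C", "D")])
        paths = enumerate_directed_paths(W)
        weighted = impute_wins(paths, t=1.0)
        assert weighted[0, 3] == pytest.approx(0.5 * 2)

    def test_direct_wins_always_outweigh_imputed(self):
        for t in (0.6, 0.9, 1.0):
            for length in (2, 3, 4):
                assert transitivity_weight(t, length) < 1.0

    def test_absent_transitivity_treated_as_prior(self):
        W = wl("ABC", [("A", "B"), ("B", "C")])
        paths = enumerate_directed_paths(W)
        assert np.allclose(impute_wins(paths, t=None), W.counts)


def beta_sf_quadrature(a, b):
    pdf = lambda x: stats.beta.pdf(x, a, b)
    val, _ = integrate.quad(pdf, 0.5, 1.0)
    return val


class TestDominanceProbability:
    def test_symmetric_wins_give_half(self):
        for k in (0, 1, 5):
            dp = dominance_probability(np.array([[0.0, k], [k, 0.0]]))
            assert dp[0, 1] == pytest.approx(0.5)

    def test_zero_evidence_is_ambiguous(self):
        dp = dominance_probability(np.zeros((3, 3)))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(dp[off], 0.5)

    @pytest.mark.parametrize("wins", [(5, 0), (3, 1), (10, 2), (0.5, 0.1)])
    def test_matches_quadrature_oracle(self, wins):
        wij, wji = wins
        dp = dominance_probability(np.array([[0.0, wij], [wji, 0.0]]))
        expected = beta_sf_quadrature(wij + 1, wji + 1)
        assert dp[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_complementarity(self):
        rng = np.random.default_rng(2)
        w = rng.gamma(1.0, 2.0, size=(10, 10))
        np.fill_diagonal(w, 0)
        dp = dominance_probability(w)
        off = ~np.eye(10, dtype=bool)
        assert np.allclose((dp + dp.T)[off], 1.0, atol=1e-12)

    def test_monotone_in_same_direction_evidence(self):
        # adding another node-disjoint same-direction path never lowers DP
        W1 = wl("ABCD", [("A", "B"), ("B", "D")])
        W2 = wl("ABCD", [("A", "B"), ("B", "D"), ("A", "C"), ("C", "D")])
        t = 0.9
        dp1 = dominance_probability(impute_wins(enumerate_directed_paths(W1), t))
        dp2 = dominance_probability(impute_wins(enumerate_directed_paths(W2), t))
        assert dp2[0, 3] >= dp1[0, 3]

    def test_contradictory_path_reduces_certainty(self):
        W1 = wl("ABCD", [("A", "B"), ("B", "D")])
        W2 = wl("ABCD", [("A", "B"), ("B", "D"), ("D", "C"), ("C", "A")])
        t = 0.9
        c1 = dyadic_certainty(
            dominance_probability(impute_wins(enumerate_directed_paths(W1), t)))
        c2 = dyadic_certainty(
            dominance_probability(impute_wins(enumerate_directed_paths(W2), t)))
        assert c2[0, 3] <= c1[0, 3]

    def test_negative_wins_rejected(self):
        with pytest.raises(ValueError):
            dominance_probability(np.array([[0.0, -1.0], [1.0, 0.0]]))


class TestCertainty:
    @pytest.mark.parametrize("dp,c", [(1.0, 1.0), (0.5, 0.5), (0.2, 0.8)])
    def test_reflection(self, dp, c):
        assert dyadic_certainty(np.array([[np.nan, dp]]))[0, 1] == pytest.approx(c)

    def test_average_certainty_bounds(self):
        c = np.array([[np.nan, 1.0, 0.5], [1.0, np.nan, 0.7],
                      [0.5, 0.7, np.nan]])
        dc = average_dominance_certainty(c)
        assert dc[0] == pytest.approx(0.75)
        assert np.all(dc >= 0.5) and np.all(dc <= 1.0)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            average_dominance_certainty(np.array([[np.nan]]))


class TestPermutationEquivariance:
    def test_full_chain_equivariant(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 3, size=(6, 6)).astype(float)
        np.fill_diagonal(counts, 0)
        ids = list("ABCDEF")
        W = WinLossMatrix(ids, counts)
        res = infer_dominance(W)
        perm = [2, 0, 5, 1, 4, 3]
        W2 = WinLossMatrix([ids[i] for i in perm],
                           counts[np.ix_(perm, perm)])
        res2 = infer_dominance(W2)
        assert np.allclose(res2.dp, res.dp[np.ix_(perm, perm)], equal_nan=True)
        assert np.allclose(res2.dc, res.dc[perm])
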