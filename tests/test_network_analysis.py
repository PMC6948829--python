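"""Correlation networks, graph metrics, Delta-r and permutation schemes."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from oracles import clustering_by_triangles, modularity_of_partition, optimal_modularity
from painnet import (
    binarize_top,
    correlation_matrix,
    fisher_z_compare,
    louvain_modularity,
    mean_clustering,
    mean_delta_r,
    permute_between_group,
    permute_within_subject,
    stat_mean_delta_r,
)
from painnet.network_analysis import BinaryNetwork, CorrelationMatrix


def _corr_from(R, names):
    return CorrelationMatrix(r=pd.DataFrame(R, index=names, columns=names), n=50)


class TestCorrelationMatrix:
    def test_identical_columns_r_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(50), "d": rng.standard_normal(50)})
        corr = correlation_matrix(df)
        assert corr.r.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((5000, 4)), columns=list("abcd"))
        corr = correlation_matrix(df)
        off = corr.r.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_anticorrelated_pair(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(40)
        df = pd.DataFrame({"a": x, "b": -x, "c": rng.standard_normal(40)})
        corr = correlation_matrix(df)
        assert corr.r.loc["a", "b"] == pytest.approx(-1.0)

    def test_zero_variance_named(self):
        df = pd.DataFrame({"a": np.arange(10.0), "flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(df)


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = fisher_z_compare(0.4, 50, 0.4, 60)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_published_pair_comparison(self):
        # BPI<->joint-pain correlation rising from .266 to .837 at n=84
        z, p = fisher_z_compare(0.266, 84, 0.837, 84)
        assert z == pytest.approx(5.97, abs=0.01)
        assert p < 1e-8

    def test_p_monotone_in_gap(self):
        ps = [fisher_z_compare(0.2, 80, 0.2 + d, 80)[1] for d in (0.1, 0.3, 0.5)]
        assert ps[0] > ps[1] > ps[2]

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_compare(1.0, 50, 0.5, 50)


class TestBinarizeTop:
    def test_four_node_enumeration(self):
        names = list("ABCD")
        R = np.eye(4)
        vals = {("A", "B"): .9, ("B", "D"): .8, ("B", "C"): .3,
                ("A", "D"): .2, ("A", "C"): .1, ("C", "D"): .05}
        for (a, b), v in vals.items():
            i, j = names.index(a), names.index(b)
            R[i, j] = R[j, i] = v
        net = binarize_top(_corr_from(R, names), 0.25)
        assert {tuple(sorted(e)) for e in net.graph.edges()} == {("A", "B"), ("B", "D")}

    def test_21_nodes_yield_53_edges(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 21))
        corr = correlation_matrix(pd.DataFrame(X, columns=[f"m{i}" for i in range(21)]))
        net = binarize_top(corr, 0.25)
        assert net.edge_count == 53  # round(0.25 * 210)

    def test_fraction_one_gives_complete_graph(self):
        rng = np.random.default_rng(4)
        corr = correlation_matrix(pd.DataFrame(rng.standard_normal((30, 6))))
        net = binarize_top(corr, 0.999999)
        assert net.edge_count == 15

    def test_monotone_transform_invariance(self):
        """The network depends only on the |r| ranking, not the values."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 8))
        corr = correlation_matrix(pd.DataFrame(X, columns=list("abcdefgh")))
        R2 = np.sign(corr.r.to_numpy()) * np.abs(corr.r.to_numpy()) ** 3
        np.fill_diagonal(R2, 1.0)
        net1 = binarize_top(corr, 0.3)
        net2 = binarize_top(_corr_from(R2, list("abcdefgh")), 0.3)
        assert set(net1.graph.edges()) == set(net2.graph.edges())

    @pytest.mark.parametrize("p,frac", [(5, 0.2), (8, 0.25), (12, 0.4)])
    def test_edge_count_rule(self, p, frac):
        rng = np.random.default_rng(p)
        corr = correlation_matrix(pd.DataFrame(rng.standard_normal((30, p))))
        net = binarize_top(corr, frac)
        assert net.edge_count == int(np.floor(frac * p * (p - 1) / 2 + 0.5))

    def test_community_attribute_attached(self):
        rng = np.random.default_rng(6)
        corr = correlation_matrix(pd.DataFrame(rng.standard_normal((30, 4)),
                                               columns=list("abcd")))
        net = binarize_top(corr, 0.5, communities={"a": "X", "b": "X"})
        assert net.graph.nodes["a"]["community"] == "X"
        assert net.graph.nodes["c"]["community"] == "unassigned"


def _net(edges, nodes=None):
    G = nx.Graph()
    if nodes:
        G.add_nodes_from(nodes)
    G.add_edges_from(edges)
    return BinaryNetwork(graph=G, fraction=0.25)


class TestClustering:
    def test_triangle_is_maximal(self):
        assert mean_clustering(_net([(1, 2), (1, 3), (2, 3)])) == 1.0

    def test_path_has_no_clustering(self):
        assert mean_clustering(_net([("A", "B"), ("B", "D")])) == 0.0

    def test_mixed_graph_hand_count(self):
        # triangle 1-2-3 plus pendant 4: (1 + 1 + 1/3 + 0)/4 = 7/12
        val = mean_clustering(_net([(1, 2), (1, 3), (2, 3), (3, 4)]))
        assert val == pytest.approx(7 / 12)

    def test_agrees_with_triangle_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(3, 8))
            G = nx.gnp_random_graph(n, rng.uniform(0.2, 0.9),
                                    seed=int(rng.integers(2 ** 31)))
            adj = {v: set(G.neighbors(v)) for v in G.nodes()}
            assert mean_clustering(_net(G.edges(), nodes=G.nodes())) == \
                pytest.approx(clustering_by_triangles(adj), abs=1e-12)


class TestLouvain:
    def test_two_disjoint_triangles(self):
        net = _net([(1, 2), (1, 3), (2, 3), (4, 5), (4, 6), (5, 6)])
        metrics = louvain_modularity(net, reps=20, seed=0)
        assert metrics.modularity_mean == pytest.approx(0.5)
        assert metrics.modularity_sd == 0.0

    def test_single_clique_zero_modularity(self):
        net = _net([(i, j) for i in range(5) for j in range(i + 1, 5)])
        metrics = louvain_modularity(net, reps=10, seed=1)
        assert metrics.modularity_mean == pytest.approx(0.0, abs=1e-12)

    def test_determinism(self):
        net = _net([(1, 2), (2, 3), (3, 4), (4, 1), (1, 3)])
        a = louvain_modularity(net, reps=15, seed=9)
        b = louvain_modularity(net, reps=15, seed=9)
        assert a.modularity_draws == b.modularity_draws

    def test_never_beats_brute_force_optimum(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            G = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2 ** 31)))
            if G.number_of_edges() == 0:
                continue
            metrics = louvain_modularity(_net(G.edges(), nodes=G.nodes()), reps=10, seed=2)
            opt = optimal_modularity(list(G.edges()), list(G.nodes()))
            assert metrics.modularity_mean <= opt + 1e-9
            assert metrics.modularity_mean >= opt - 0.02

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            louvain_modularity(_net([], nodes=[1, 2]), reps=5, seed=0)


class TestMeanDeltaR:
    def test_identical_matrices_zero(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.4
        comp = mean_delta_r(_corr_from(R, list("abc")), _corr_from(R, list("abc")))
        assert comp.mean_delta_r == 0.0

    def test_three_measure_hand_computation(self):
        names = list("abc")
        A, B = np.eye(3), np.eye(3)
        for (i, j), v in {(0, 1): 0.2, (0, 2): 0.4, (1, 2): -0.1}.items():
            A[i, j] = A[j, i] = v
        for (i, j), v in {(0, 1): 0.5, (0, 2): 0.4, (1, 2): 0.3}.items():
            B[i, j] = B[j, i] = v
        comp = mean_delta_r(_corr_from(A, names), _corr_from(B, names))
        assert comp.mean_delta_r == pytest.approx((0.3 + 0.0 + 0.4) / 3)

    def test_bounded_by_two(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.standard_normal((30, 5)))
        Y = pd.DataFrame(rng.standard_normal((30, 5)))
        comp = mean_delta_r(correlation_matrix(X), correlation_matrix(Y))
        assert 0 <= comp.mean_delta_r <= 2

    def test_mismatched_measures_rejected(self):
        A = _corr_from(np.eye(3), list("abc"))
        B = _corr_from(np.eye(3), list("abd"))
        with pytest.raises(ValueError):
            mean_delta_r(A, B)


class TestPermutation:
    def _paired(self, seed, n=40, p=6, shift=False):
        rng = np.random.default_rng(seed)
        f = rng.standard_normal((n, 1))
        a = f @ np.ones((1, p)) * 0.6 + rng.standard_normal((n, p))
        if shift:
            b = rng.standard_normal((n, p))  # structure destroyed
        else:
            b = f @ np.ones((1, p)) * 0.6 + rng.standard_normal((n, p))
        cols = [f"m{i}" for i in range(p)]
        idx = [f"s{i}" for i in range(n)]
        return (pd.DataFrame(a, columns=cols, index=idx),
                pd.DataFrame(b, columns=cols, index=idx))

    def test_same_seed_identical_probability(self):
        a, b = self._paired(0)
        r1 = permute_within_subject(a, b, stat_mean_delta_r, reps=200, seed=5)
        r2 = permute_within_subject(a, b, stat_mean_delta_r, reps=200, seed=5)
        assert r1.probability == r2.probability
        np.testing.assert_array_equal(r1.draws, r2.draws)

    def test_invariant_to_subject_and_measure_order(self):
        a, b = self._paired(1)
        r1 = permute_within_subject(a, b, stat_mean_delta_r, reps=150, seed=3)
        perm = np.random.default_rng(0).permutation(len(a))
        a2, b2 = a.iloc[perm], b.iloc[perm]
        # same subject set, shuffled presentation; statistic itself must match
        assert stat_mean_delta_r(a2.loc[a.index].to_numpy(), b2.loc[b.index].to_numpy()) == \
            pytest.approx(r1.observed)
        cols2 = list(reversed(a.columns))
        assert stat_mean_delta_r(a[cols2].to_numpy(), b[cols2].to_numpy()) == \
            pytest.approx(r1.observed)

    def test_structure_change_detected(self):
        a, b = self._paired(2, n=80, shift=True)
        res = permute_within_subject(a, b, stat_mean_delta_r, reps=300, seed=1)
        assert res.probability < 0.05

    def test_probability_never_zero(self):
        a, b = self._paired(3)
        res = permute_within_subject(a, b, stat_mean_delta_r, reps=100, seed=2)
        assert res.probability >= 1 / 101

    def test_low_reps_warns(self):
        a, b = self._paired(4)
        with pytest.warns(UserWarning):
            permute_within_subject(a, b, stat_mean_delta_r, reps=50, seed=0)

    def test_between_group_scheme(self):
        a1, b1 = self._paired(5, n=120, shift=True)   # arm with change
        a2, b2 = self._paired(6, n=120, shift=False)  # stable arm
        a1.index = [f"g1_{i}" for i in range(120)]
        b1.index = a1.index
        a2.index = [f"g2_{i}" for i in range(120)]
        b2.index = a2.index
        pre = pd.concat([a1, a2])
        post = pd.concat([b1, b2])
        labels = pd.Series(["A"] * 120 + ["B"] * 120, index=pre.index)
        res = permute_between_group(pre, post, labels, stat_mean_delta_r,
                                    reps=300, seed=4)
        assert res.probability < 0.05
        assert res.scheme == "between_group"
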