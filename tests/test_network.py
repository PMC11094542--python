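"""Correlations, RMT thresholding, topology and module detection."""
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from crust_assembly import network as nm
from crust_assembly.community_structure import TaxonPartition
from crust_assembly.io_core import AsvTable
from crust_assembly.network import CoNetwork


def brute_force_best_q(G):
    """Exhaustive search over all set partitions (feasible for <= 8 nodes)."""
    nodes = list(G.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {head}] + part[i + 1:]
            yield part + [{head}]

    return max(nm.newman_q(G, p) for p in partitions(nodes))


def _corr_df(mat, prefix="a"):
    n = mat.shape[0]
    ids = [f"{prefix}{i}" for i in range(n)]
    return pd.DataFrame(mat, index=ids, columns=ids)


def block_correlation(seed, n=40, block=20, r_in=0.9, noise=0.2):
    rng = np.random.default_rng(seed)
    R = rng.uniform(-noise, noise, (n, n))
    R = (R + R.T) / 2
    for lo in range(0, n, block):
        sub = r_in + rng.normal(0, 0.02, (block, block))
        R[lo:lo + block, lo:lo + block] = (sub + sub.T) / 2
    np.fill_diagonal(R, 1.0)
    return _corr_df(np.clip(R, -1, 1))


class TestPrevalenceFilter:
    def test_threshold_behaviour(self):
        rows = np.zeros((36, 3))
        rows[:5, 0] = 1    # 5/36 < 1/3 -> dropped
        rows[:13, 1] = 1   # 13/36 > 1/3 -> kept
        rows[:, 2] = 1
        t = AsvTable(pd.DataFrame(rows, index=[f"s{i}" for i in range(36)],
                                  columns=["x", "y", "z"]))
        out = nm.prevalence_filter(t, 1 / 3)
        assert out.asv_ids == ["y", "z"]

    def test_removing_everything_is_error(self):
        t = AsvTable(pd.DataFrame([[1, 0], [0, 1]], index=["s1", "s2"],
                                  columns=["x", "y"]))
        with pytest.raises(ValueError):
            nm.prevalence_filter(t, 1.0)


class TestCorrelation:
    def _lognormal_table(self, seed, n_s=30, n_t=10):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(3, 1, size=(n_s, n_t))
        return base

    def test_proportional_counts_high_r(self):
        base = self._lognormal_table(0)
        counts = np.column_stack([base[:, 0], 2 * base[:, 0], base[:, 1]])
        t = AsvTable(pd.DataFrame(np.round(counts), index=[f"s{i}" for i in range(30)],
                                  columns=["i", "j", "k"]))
        corr = nm.correlation_matrix(t)
        assert corr.r.loc["i", "j"] > 0.99  # ln(2x+1) vs ln(x+1): monotone

    def test_symmetric_unit_diagonal_and_order_invariance(self):
        base = np.round(self._lognormal_table(1))
        t = AsvTable(pd.DataFrame(base, index=[f"s{i}" for i in range(30)],
                                  columns=[f"t{i}" for i in range(10)]))
        corr = nm.correlation_matrix(t)
        assert np.allclose(corr.r.values, corr.r.values.T)
        assert np.allclose(np.diag(corr.r.values), 1.0)
        perm = np.random.default_rng(2).permutation(30)
        t2 = AsvTable(t.data.iloc[perm])
        corr2 = nm.correlation_matrix(t2)
        np.testing.assert_allclose(corr.r.values, corr2.r.values, atol=1e-12)

    def test_constant_asv_excluded(self):
        base = np.round(self._lognormal_table(3))
        base[:, 0] = 7.0
        t = AsvTable(pd.DataFrame(base, index=[f"s{i}" for i in range(30)],
                                  columns=[f"t{i}" for i in range(10)]))
        corr = nm.correlation_matrix(t)
        assert corr.excluded == ["t0"]
        assert "t0" not in corr.taxa


class TestRmtThreshold:
    def test_block_matrix_strips_noise(self):
        R = block_correlation(0)
        t = nm.rmt_threshold(R)
        assert 0.2 < t <= 0.9
        net = nm.build_network(R, t)
        between = [e for e in net.edges
                   if (int(e[0][1:]) < 20) != (int(e[1][1:]) < 20)]
        within = [e for e in net.edges
                  if (int(e[0][1:]) < 20) == (int(e[1][1:]) < 20)]
        assert len(between) == 0
        assert len(within) >= 0.8 * 2 * (20 * 19 / 2)

    def test_identity_matrix_degenerate(self):
        R = _corr_df(np.eye(40))
        with pytest.raises(ValueError):
            nm.rmt_threshold(R)

    def test_returned_threshold_in_grid(self):
        R = block_correlation(1)
        grid = np.round(np.arange(0.30, 0.9001, 0.01), 10)
        t = nm.rmt_threshold(R, t_grid=grid)
        assert np.any(np.isclose(grid, t))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="30"):
            nm.rmt_threshold(_corr_df(np.eye(10)))


class TestBuildNetwork:
    def test_triangle_at_threshold(self):
        R = _corr_df(np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1]]))
        net = nm.build_network(R, 0.8)
        assert net.graph.number_of_edges() == 3
        assert net.graph["a0"]["a2"]["sign"] == -1

    def test_edge_monotonicity_in_threshold(self):
        R = block_correlation(2)
        edges = {}
        for t in (0.3, 0.5, 0.7, 0.95):
            net = nm.build_network(R, t)
            edges[t] = {frozenset(e[:2]) for e in net.edges}
        assert edges[0.95] <= edges[0.7] <= edges[0.5] <= edges[0.3]

    def test_threshold_one_near_empty_warns(self):
        rng = np.random.default_rng(3)
        M = rng.uniform(-0.5, 0.5, (10, 10))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        with pytest.warns(UserWarning, match="empty"):
            net = nm.build_network(_corr_df(M), 1.0)
        assert net.graph.number_of_edges() == 0


class TestTopology:
    def test_complete_graph(self):
        topo = nm.topology(CoNetwork(nx.complete_graph(4), 0.5),
                           n_rewire_null=5, seed=0)
        assert topo.avg_degree == pytest.approx(3.0)
        assert topo.diameter == 1
        assert topo.avg_clustering == pytest.approx(1.0)

    def test_path_graph(self):
        topo = nm.topology(CoNetwork(nx.path_graph(4), 0.5),
                           n_rewire_null=5, seed=0)
        assert topo.diameter == 3
        assert topo.avg_clustering == pytest.approx(0.0)
        assert topo.avg_degree == pytest.approx(1.5)

    def test_two_triangles_modularity_half(self):
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        topo = nm.topology(CoNetwork(G, 0.5), n_rewire_null=10, seed=0)
        assert topo.modularity == pytest.approx(0.5)

    def test_edgeless_graph_missing_metrics(self):
        G = nx.empty_graph(3)
        topo = nm.topology(CoNetwork(G, 0.5), n_rewire_null=5, seed=0)
        assert np.isnan(topo.avg_degree)


class TestModules:
    @pytest.mark.parametrize("G,q_expected", [
        (nx.complete_graph(4), 0.0),
        (nx.path_graph(4), 1 / 6),
        (nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]), 0.5),
        (nx.cycle_graph(5), None),
        (nx.barbell_graph(3, 0), None),
        (nx.star_graph(5), None),
    ])
    def test_greedy_matches_brute_force(self, G, q_expected):
        part = nm.greedy_modularity_partition(G)
        q = nm.newman_q(G, part)
        assert q == pytest.approx(brute_force_best_q(G), abs=1e-12)
        if q_expected is not None:
            assert q == pytest.approx(q_expected, abs=1e-12)

    def test_two_triangles_sizes_and_large_flag(self):
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        mods = nm.modules(CoNetwork(G, 0.5))
        assert sorted(mods.sizes.values()) == [3, 3]
        assert not any(mods.large.values())

    def test_module_fractions_from_partition(self):
        G = nx.Graph([(f"t{i}", f"t{j}") for i, j in
                      itertools.combinations(range(5), 2)])
        part = TaxonPartition(abundant={"t0"}, rare={"t1", "t2", "t3", "t4"},
                              intermediate=set(),
                              mean_rel_abund=pd.Series(0.1, index=[f"t{i}" for i in range(5)]))
        mods = nm.modules(CoNetwork(G, 0.5), part)
        assert mods.fractions.loc[1, "rare"] == pytest.approx(0.8)
        assert mods.large[1]

    def test_deterministic_membership(self):
        G = nx.barbell_graph(4, 1)
        m1 = nm.modules(CoNetwork(G, 0.5)).membership
        m2 = nm.modules(CoNetwork(G, 0.5)).membership
        assert m1 == m2


class TestComplexity:
    def _net_and_table(self):
        G = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("d", "e")])
        rows = pd.DataFrame(
            [[1, 1, 1, 1, 1], [1, 1, 1, 0, 0], [0, 0, 1, 1, 1], [1, 0, 0, 0, 1]],
            index=["s1", "s2", "s3", "s4"], columns=list("abcde"))
        return CoNetwork(G, 0.5), AsvTable(rows)

    def test_composite_mean_zero(self):
        net, table = self._net_and_table()
        score = nm.sample_complexity(net, table)
        assert score.scores.dropna().mean() == pytest.approx(0.0, abs=1e-9)

    def test_triangle_sample_ranks_higher_than_sparse(self):
        net, table = self._net_and_table()
        score = nm.sample_complexity(net, table)
        assert score.scores["s2"] > score.scores["s4"]  # triangle vs single edge

    def test_identical_samples_all_missing(self):
        net, _ = self._net_and_table()
        rows = pd.DataFrame([[1, 1, 1, 1, 1]] * 3, index=["s1", "s2", "s3"],
                            columns=list("abcde"))
        with pytest.warns(UserWarning, match="constant"):
            score = nm.sample_complexity(net, AsvTable(rows))
        assert score.scores.isna().all()


class TestComplexityVsRatio:
    def test_affine_relationship_r_one(self):
        scores = pd.Series([0.0, 1.0, 2.0, 3.0], index=list("wxyz"))
        ratios = pd.DataFrame({"cn": [1.0, 1.5, 2.0, 2.5]}, index=list("wxyz"))
        fake = nm.ComplexityScore(scores, pd.DataFrame(index=scores.index))
        out = nm.complexity_vs_ratio(fake, ratios, "cn")
        assert out["r"] == pytest.approx(1.0)
        assert np.sign(out["slope"]) == np.sign(out["r"])

    def test_constant_predictor_rejected(self):
        scores = pd.Series([0.0, 1.0, 2.0], index=list("xyz"))
        ratios = pd.DataFrame({"cn": [1.0, 1.0, 1.0]}, index=list("xyz"))
        fake = nm.ComplexityScore(scores, pd.DataFrame(index=scores.index))
        with pytest.raises(ValueError, match="constant"):
            nm.complexity_vs_ratio(fake, ratios, "cn")


def test_pure_noise_threshold_strips_noise():
    """On correlations of independent lognormal counts the selected cutoff
    should land at or above nearly all of the spurious |r| mass."""
    hits = 0
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        counts = np.round(rng.lognormal(3, 1, size=(30, 200)))
        t = AsvTable(pd.DataFrame(counts, index=[f"s{i}" for i in range(30)],
                                  columns=[f"t{i}" for i in range(200)]))
        corr = nm.correlation_matrix(t)
        q99 = np.quantile(np.abs(corr.r.values[np.triu_indices(len(corr.taxa), 1)]), 0.99)
        try:
            thr = nm.rmt_threshold(corr)
        except ValueError:
            continue
        if thr >= q99:
            hits += 1
    assert hits >= 4
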