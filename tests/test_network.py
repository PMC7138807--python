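import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soilbiogeo import (aggregate_to_genus, betweenness, build_network,
                        compare_core_subnetworks, correlation_matrix,
                        er_null_ensemble, fdr_adjust, keystone_taxa, topology)
from soilbiogeo.io import Lineage, OtuTable
from soilbiogeo.network import _igraph_topology, _sample_gnm_edges
import igraph as ig


def table_from_counts(counts):
    counts = np.asarray(counts)
    return OtuTable([f"s{i}" for i in range(counts.shape[0])],
                    [f"o{j}" for j in range(counts.shape[1])], counts)


class TestCorrelationMatrix:
    def test_monotone_and_antimonotone_pairs(self):
        # constant row totals, so closure preserves each column's ranks
        n = 8
        up = np.arange(1, n + 1)
        counts = np.column_stack([up, 2 * up, 100 - 3 * up])
        r, p, dropped = correlation_matrix(table_from_counts(counts))
        assert r.loc["o0", "o1"] == pytest.approx(1.0)
        assert r.loc["o0", "o2"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_definition(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 1000, size=(21, 6))
        table = table_from_counts(counts)
        r, p, _ = correlation_matrix(table)
        rel = table.relative_abundance()
        for i, j in itertools.combinations(range(6), 2):
            ranks_i = stats.rankdata(rel[:, i])
            ranks_j = stats.rankdata(rel[:, j])
            expected = np.corrcoef(ranks_i, ranks_j)[0, 1]
            assert r.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_taxa_reported(self):
        # equal row totals with a constant column -> constant relative abundance
        counts = np.array([[1, 9, 5], [2, 8, 5], [3, 7, 5], [4, 6, 5],
                           [5, 5, 5], [6, 4, 5]])
        r, p, dropped = correlation_matrix(table_from_counts(counts))
        assert dropped == ["o2"]
        assert list(r.index) == ["o0", "o1"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            correlation_matrix(table_from_counts(np.ones((4, 3), dtype=int)))


class TestFdrAdjust:
    def test_hand_applied_step_up(self):
        q = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_p_unchanged(self):
        q = fdr_adjust(np.array([0.2, 0.2, 0.2]))
        assert np.allclose(q, 0.2)

    def test_single_test_identity(self):
        assert fdr_adjust(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.5]))


class TestBuildNetwork:
    def matrices(self, r01, q01):
        ids = ["a", "b", "c"]
        r = np.eye(3)
        r[0, 1] = r[1, 0] = r01
        p = np.ones((3, 3))
        # BH over the 3-test upper-triangle family: q(p01) = 3 * p01
        p[0, 1] = p[1, 0] = q01
        p[0, 2] = p[2, 0] = 1.0
        p[1, 2] = p[2, 1] = 1.0
        return pd.DataFrame(r, ids, ids), pd.DataFrame(p, ids, ids)

    def test_edge_present_when_both_thresholds_met(self):
        r, p = self.matrices(0.61, 0.002)  # q = 0.006 < 0.01
        g = build_network(r, p)
        assert g.has_edge("a", "b")
        assert g.edges["a", "b"]["r"] == pytest.approx(0.61)
        assert g.edges["a", "b"]["q"] == pytest.approx(0.006)

    def test_edge_absent_when_q_fails(self):
        r, p = self.matrices(0.61, 0.02)  # q = 0.06 > 0.01
        assert not build_network(r, p).has_edge("a", "b")

    def test_strong_negative_correlation_excluded_by_default(self):
        r, p = self.matrices(-0.9, 1e-6)
        assert build_network(r, p).number_of_edges() == 0
        assert build_network(r, p, use_absolute=True).has_edge("a", "b")

    def test_isolated_nodes_kept_unless_dropped(self):
        r, p = self.matrices(0.9, 1e-6)
        assert set(build_network(r, p).nodes) == {"a", "b", "c"}
        assert set(build_network(r, p, drop_isolated=True).nodes) == {"a", "b"}

    def test_planted_guild_edges_recovered_with_high_precision(self):
        from soilbiogeo import SyntheticConfig, generate_dataset, rarefy
        cfg = SyntheticConfig(n_otus=150, n_core=0, n_env_responders=0,
                              spatial_sd=0.0, guild_strength=1.0, noise_sd=0.5,
                              base_log_sd=1.0, seed=4)
        _, table, _, truth = generate_dataset(cfg)
        r, p, _ = correlation_matrix(rarefy(table, seed=1))
        net = build_network(r, p)
        planted = {frozenset(e) for e in truth.guild_edges}
        found = {frozenset(e) for e in net.edges()}
        assert found, "no edges recovered"
        precision = len(found & planted) / len(found)
        assert precision >= 0.9

    def test_invariant_to_library_size_rescaling(self):
        # per-sample depth factors cancel in total-sum scaling, so the rank
        # correlations (and hence the network) cannot change
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 500, size=(15, 10))
        factors = rng.integers(1, 20, size=(15, 1))
        r1, _, _ = correlation_matrix(table_from_counts(counts))
        r2, _, _ = correlation_matrix(table_from_counts(counts * factors))
        assert np.allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-12)


class TestAggregateToGenus:
    def test_counts_summed_by_genus(self):
        lineages = [Lineage.parse("k__B; g__X"), Lineage.parse("k__B; g__X")]
        t = OtuTable(["s0", "s1"], ["o0", "o1"], np.array([[1, 3], [2, 4]]), lineages)
        g = aggregate_to_genus(t)
        assert g.otu_ids == ["X"]
        assert np.array_equal(g.counts, [[4], [6]])

    def test_unassigned_dropped_with_conservation(self, synthetic_rarefied):
        with pytest.warns(UserWarning, match="genus assignment"):
            g = aggregate_to_genus(synthetic_rarefied)
        assigned = [j for j, l in enumerate(synthetic_rarefied.lineages)
                    if l.genus is not None]
        assert g.counts.sum() == synthetic_rarefied.counts[:, assigned].sum()

    def test_no_assignments_rejected(self):
        lineages = [Lineage.parse("k__B; g__")]
        t = OtuTable(["s0"], ["o0"], np.array([[1]]), lineages)
        with pytest.raises(ValueError, match="no genus"):
            aggregate_to_genus(t)


class TestTopology:
    def test_triangle(self):
        t = topology(nx.complete_graph(3))
        assert (t.average_path_length, t.diameter, t.density, t.clustering) == (1, 1, 1, 1)

    def test_three_node_path(self):
        t = topology(nx.path_graph(3))
        assert t.average_path_length == pytest.approx(4 / 3)
        assert t.diameter == 2 and t.clustering == 0

    def test_star_k14(self):
        t = topology(nx.star_graph(4))
        assert t.clustering == 0 and t.density == pytest.approx(4 / 10)
        assert t.mean_degree == pytest.approx(8 / 5)

    def test_disconnected_pairs_excluded_and_reported(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        t = topology(g)
        assert t.average_path_length == 1.0
        assert t.fraction_unreachable_pairs == pytest.approx(4 / 6)

    def test_igraph_and_networkx_routes_agree(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = int(rng.integers(5, 25))
            m = int(rng.integers(n - 1, n * (n - 1) // 2))
            edges = _sample_gnm_edges(n, m, rng)
            gnx = nx.Graph()
            gnx.add_nodes_from(range(n))
            gnx.add_edges_from(map(tuple, edges))
            t1 = topology(gnx)
            t2 = _igraph_topology(ig.Graph(n=n, edges=edges.tolist()))
            assert t1.average_path_length == pytest.approx(t2.average_path_length)
            assert t1.diameter == t2.diameter
            assert t1.clustering == pytest.approx(t2.clustering, abs=1e-12)
            assert t1.density == pytest.approx(t2.density)


class TestErNullEnsemble:
    def test_every_replicate_has_exact_edge_count(self):
        ens = er_null_ensemble(30, 60, n_reps=25, seed=0)
        assert all(t.n_edges == 60 for t in ens.replicates)
        assert all(t.density == pytest.approx(2 * 60 / (30 * 29)) for t in ens.replicates)

    def test_mean_clustering_near_analytic_expectation(self):
        n, m, reps = 100, 500, 100
        ens = er_null_ensemble(n, m, n_reps=reps, seed=1)
        cc = np.array([t.clustering for t in ens.replicates])
        expected = 2 * m / (n * (n - 1))
        se = cc.std(ddof=1) / np.sqrt(reps)
        assert abs(cc.mean() - expected) <= 3 * se + 0.01 * expected

    def test_sampled_edges_are_distinct_and_in_range(self):
        rng = np.random.default_rng(2)
        for n in (5, 17, 100):
            m = n * (n - 1) // 2  # complete graph: every index must decode uniquely
            edges = _sample_gnm_edges(n, m, rng)
            assert len({tuple(e) for e in edges.tolist()}) == m
            assert (edges[:, 0] > edges[:, 1]).all()
            assert edges.max() < n

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            er_null_ensemble(4, 7, n_reps=1)

    def test_reproducible_under_seed(self):
        a = er_null_ensemble(20, 40, n_reps=5, seed=3)
        b = er_null_ensemble(20, 40, n_reps=5, seed=3)
        assert [t.diameter for t in a.replicates] == [t.diameter for t in b.replicates]


def brute_force_betweenness(g):
    """Oracle: enumerate all shortest paths between every pair directly."""
    bc = dict.fromkeys(g.nodes, 0.0)
    for s, t in itertools.combinations(g.nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        shortest = nx.shortest_path_length(g, s, t)
        paths = [p for p in nx.all_simple_paths(g, s, t, cutoff=shortest)
                 if len(p) - 1 == shortest]
        for v in g.nodes:
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            bc[v] += through / len(paths)
    return bc


class TestBetweenness:
    def test_star_center_closed_form(self):
        n = 7
        bc = betweenness(nx.star_graph(n - 1))
        assert bc[0] == pytest.approx((n - 1) * (n - 2) / 2)

    def test_path_middle_node(self):
        assert betweenness(nx.path_graph(3))[1] == pytest.approx(1.0)

    def test_all_graphs_on_four_nodes_exhaustively(self):
        nodes = range(4)
        pairs = list(itertools.combinations(nodes, 2))
        for bits in range(2 ** len(pairs)):
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(e for k, e in enumerate(pairs) if bits >> k & 1)
            expected = brute_force_betweenness(g)
            got = betweenness(g)
            for v in nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-9)

    def test_random_graphs_up_to_eight_nodes(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(5, 9))
            m = int(rng.integers(0, n * (n - 1) // 2 + 1))
            edges = _sample_gnm_edges(n, m, rng) if m else np.empty((0, 2), int)
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(map(tuple, edges))
            expected = brute_force_betweenness(g)
            got = betweenness(g)
            for v in g.nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-9)


class TestKeystones:
    def test_star_center_is_keystone(self):
        report = keystone_taxa(nx.star_graph(5), k=1)
        assert report.keystones == [0]

    def test_k_equals_n_ranked_consistently(self):
        g = nx.path_graph(5)
        report = keystone_taxa(g, k=5)
        bc = report.betweenness
        assert sorted(report.keystones, key=lambda v: -bc[v]) == report.keystones \
            or all(bc[report.keystones[i]] >= bc[report.keystones[i + 1]] for i in range(4))

    def test_planted_bridge_between_blocks_ranks_first(self):
        g = nx.Graph()
        for offset, names in ((0, "abcde"), (10, "vwxyz")):
            for u, v in itertools.combinations(names, 2):
                g.add_edge(u, v)
        g.add_edge("a", "bridge")
        g.add_edge("bridge", "v")
        report = keystone_taxa(g, k=1)
        assert report.keystones == ["bridge"]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="k exceeds"):
            keystone_taxa(nx.path_graph(3), k=4)


class TestCoreSubnetworks:
    def test_core_equals_all_nodes_rejected(self):
        g = nx.path_graph(4)
        with pytest.raises(ValueError, match="non-empty"):
            compare_core_subnetworks(g, set(g.nodes))

    def test_symmetric_construction_not_significant(self):
        # two identical components; core = one of them -> identical betweenness
        g = nx.Graph()
        g.add_edges_from([("a1", "a2"), ("a2", "a3"), ("a3", "a4")])
        g.add_edges_from([("b1", "b2"), ("b2", "b3"), ("b3", "b4")])
        tc, to, (w, p) = compare_core_subnetworks(g, {"a1", "a2", "a3", "a4"})
        assert p > 0.05
        assert tc.n_edges == to.n_edges

    def test_wilcoxon_matches_exact_enumeration(self):
        # 8-node graph with all-distinct betweenness values: 4 core vs 4 other
        g = nx.Graph([(0, 1), (0, 3), (0, 6), (1, 2), (1, 3), (1, 5), (2, 3),
                      (2, 4), (2, 6), (3, 4), (3, 6), (4, 5), (5, 7)])
        core = {0, 1, 2, 3}
        _, _, (u_obs, p) = compare_core_subnetworks(g, core)
        bc = betweenness(g)
        values = np.array([bc[v] for v in g.nodes])
        assert len(set(values)) == 8  # no ties: the exact null applies
        # oracle: enumerate all C(8,4) group assignments, build the U
        # distribution, and form the two-sided exact p the standard way
        core_idx = [i for i, v in enumerate(g.nodes) if v in core]
        u_list = []
        for comb in itertools.combinations(range(8), 4):
            x = values[list(comb)]
            y = values[[i for i in range(8) if i not in comb]]
            u = sum((xi > yi) for xi in x for yi in y)
            u_list.append(u)
        u_list = np.array(u_list)
        p_le = np.mean(u_list <= u_obs)
        p_ge = np.mean(u_list >= u_obs)
        p_exact = min(1.0, 2 * min(p_le, p_ge))
        assert p == pytest.approx(p_exact)
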