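import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from endocore.io import AbundanceTable
from endocore.network import (
    EdgeRule,
    HubRule,
    build_network,
    centralities,
    hub_core,
    hubs_from_centralities,
    spearman_matrix,
    topology,
)


def _equal_sum_table(columns: dict[str, list[int]]):
    """Build a table with equal sample sums so relative abundance preserves
    within-taxon ranks of the given count vectors."""
    frame = pd.DataFrame(columns)
    total = frame.sum(axis=1).max() + 5
    frame["filler"] = total - frame.sum(axis=1)
    frame.index = [f"s{i+1}" for i in range(len(frame))]
    return AbundanceTable(frame)


class TestSpearmanMatrix:
    def test_perfect_monotone_pair(self):
        table = _equal_sum_table({"x": [1, 2, 3, 4, 5], "y": [2, 4, 6, 8, 10]})
        rho, p = spearman_matrix(table, min_prevalence=1)
        assert rho.at["x", "y"] == pytest.approx(1.0)
        # exact two-sided permutation p: only the two perfectly monotone
        # orderings of 5 ranks reach |rho| = 1
        assert p.at["x", "y"] == pytest.approx(2 / 120)

    def test_reversal_gives_minus_one(self):
        table = _equal_sum_table({"x": [1, 2, 3, 4, 5], "y": [5, 4, 3, 2, 1]})
        rho, _ = spearman_matrix(table, min_prevalence=1)
        assert rho.at["x", "y"] == pytest.approx(-1.0)

    def test_tied_vectors_match_midrank_and_permutation_oracles(self):
        x = [1, 2, 2, 4]
        y = [3, 1, 4, 4]
        table = _equal_sum_table({"x": x, "y": y})
        rho, p = spearman_matrix(table, min_prevalence=1)
        # oracle 1: Pearson on midranks
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        expected_rho = stats.pearsonr(rx, ry).statistic
        assert rho.at["x", "y"] == pytest.approx(expected_rho)
        # oracle 2: exact permutation p over all 4! label permutations
        obs = abs(expected_rho)
        hits = total = 0
        for perm in itertools.permutations(ry):
            r = stats.pearsonr(rx, np.array(perm)).statistic
            hits += abs(r) >= obs - 1e-12
            total += 1
        assert p.at["x", "y"] == pytest.approx(hits / total)

    def test_constant_taxon_recorded_missing(self):
        table = _equal_sum_table({"x": [1, 2, 3, 4, 5], "c": [3, 3, 3, 3, 3]})
        rho, p = spearman_matrix(table, min_prevalence=1)
        assert math.isnan(rho.at["x", "c"])
        assert math.isnan(p.at["x", "c"])

    def test_prevalence_filter_drops_sparse_taxa(self):
        table = _equal_sum_table(
            {"common": [1, 2, 3, 4, 5], "sparse": [9, 0, 0, 0, 0]}
        )
        rho, _ = spearman_matrix(table, min_prevalence=3)
        assert "sparse" not in rho.columns
        assert "common" in rho.columns

    def test_needs_four_samples(self):
        table = _equal_sum_table({"x": [1, 2, 3], "y": [3, 2, 1]})
        with pytest.raises(ValueError, match="4 samples"):
            spearman_matrix(table)


class TestBuildNetwork:
    def _mats(self, entries, taxa):
        rho = pd.DataFrame(np.eye(len(taxa)), index=taxa, columns=taxa)
        p = pd.DataFrame(np.zeros((len(taxa), len(taxa))), index=taxa, columns=taxa)
        for a, b, r, pv in entries:
            rho.loc[a, b] = rho.loc[b, a] = r
            p.loc[a, b] = p.loc[b, a] = pv
        return rho, p

    def test_threshold_is_strict(self):
        rho, p = self._mats([("a", "b", 0.59, 0.001)], ["a", "b"])
        net = build_network(rho, p)
        assert net.number_of_edges() == 0

    def test_negative_edge_recorded_with_sign(self):
        rho, p = self._mats([("a", "b", -0.8, 0.01)], ["a", "b"])
        net = build_network(rho, p)
        assert net.edges[("a", "b")]["sign"] == -1

    def test_isolated_taxa_excluded(self):
        rho, p = self._mats([("a", "b", 0.9, 0.001)], ["a", "b", "c"])
        net = build_network(rho, p)
        assert set(net.nodes) == {"a", "b"}

    def test_matches_brute_force_double_filter(self, rng):
        taxa = [f"t{i}" for i in range(10)]
        for _ in range(20):
            r = rng.uniform(-1, 1, size=(10, 10))
            r = (r + r.T) / 2
            np.fill_diagonal(r, 1.0)
            pv = rng.uniform(0, 0.2, size=(10, 10))
            pv = (pv + pv.T) / 2
            rho = pd.DataFrame(r, index=taxa, columns=taxa)
            p = pd.DataFrame(pv, index=taxa, columns=taxa)
            net = build_network(rho, p, EdgeRule())
            expected = {
                frozenset((a, b))
                for a, b in itertools.combinations(taxa, 2)
                if abs(rho.at[a, b]) > 0.6 and p.at[a, b] < 0.05
            }
            assert {frozenset(e) for e in net.edges} == expected

    def test_misaligned_matrices_rejected(self):
        rho, p = self._mats([], ["a", "b"])
        with pytest.raises(ValueError, match="aligned"):
            build_network(rho, p.rename(index={"a": "z"}, columns={"a": "z"}))


class TestTopology:
    def test_triangle(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        topo = topology(net)
        assert topo.avgK == pytest.approx(2.0)
        assert topo.avgCC == pytest.approx(1.0)
        assert topo.avg_path == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "n_nodes, n_edges, expected_avgk",
        [(225, 4065, 36.1), (191, 1970, 20.6)],
    )
    def test_average_degree_from_node_edge_counts(self, n_nodes, n_edges, expected_avgk):
        net = nx.gnm_random_graph(n_nodes, n_edges, seed=1)
        topo = topology(net, seed=0)
        assert round(topo.avgK, 1) == expected_avgk

    def test_avgk_identity(self, rng):
        for seed in range(5):
            net = nx.gnm_random_graph(12, int(rng.integers(5, 40)), seed=seed)
            net.remove_nodes_from(list(nx.isolates(net)))
            if net.number_of_nodes() == 0:
                continue
            topo = topology(net, seed=0)
            assert topo.avgK == 2 * net.number_of_edges() / net.number_of_nodes()

    def test_empty_network_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            topo = topology(nx.Graph())
        assert topo.n_nodes == 0

    def test_sign_percentages(self):
        net = nx.Graph()
        net.add_edge("a", "b", sign=1)
        net.add_edge("b", "c", sign=-1)
        topo = topology(net)
        assert topo.pct_positive_edges == pytest.approx(50.0)
        assert topo.pct_negative_edges == pytest.approx(50.0)


def _brute_force_centralities(net):
    """Oracle: all-pairs path enumeration for the three centralities."""
    nodes = sorted(net.nodes)
    n = len(nodes)
    deg = {v: net.degree[v] / (n - 1) for v in nodes}
    # all shortest paths by BFS enumeration
    btw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(net, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(v in p for p in paths) / len(paths)
            btw[v] += frac
    scale = (n - 1) * (n - 2) / 2
    btw = {v: b / scale for v, b in btw.items()}
    clo = {}
    for v in nodes:
        lengths = nx.single_source_shortest_path_length(net, v)
        reach = len(lengths) - 1
        if reach == 0:
            clo[v] = 0.0
        else:
            clo[v] = (reach / sum(lengths.values())) * (reach / (n - 1))
    return deg, btw, clo


class TestCentralities:
    def test_star_center_extremal(self):
        net = nx.star_graph(3)  # center 0, leaves 1..3
        cent = centralities(net)
        assert cent.loc[0].tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_path_graph_betweenness(self):
        net = nx.path_graph(["A", "B", "C"])
        cent = centralities(net)
        assert cent.at["B", "betweenness_centrality"] == pytest.approx(1.0)
        assert cent.at["A", "betweenness_centrality"] == pytest.approx(0.0)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for seed in range(25):
            net = nx.gnp_random_graph(8, 0.35, seed=seed)
            net.remove_nodes_from(list(nx.isolates(net)))
            if net.number_of_nodes() < 3:
                continue
            cent = centralities(net)
            deg, btw, clo = _brute_force_centralities(net)
            for v in net.nodes:
                assert cent.at[v, "degree_centrality"] == pytest.approx(deg[v])
                assert cent.at[v, "betweenness_centrality"] == pytest.approx(btw[v])
                assert cent.at[v, "closeness_centrality"] == pytest.approx(clo[v])


class TestHubCore:
    def _frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["degree_centrality", "closeness_centrality", "betweenness_centrality"],
            index=[f"t{i}" for i in range(len(rows))],
        )

    def test_all_thresholds_exceeded_is_hub(self):
        cent = self._frame([[0.25, 0.40, 0.40]])
        assert hubs_from_centralities(cent) == ["t0"]

    def test_boundary_equality_is_not_hub(self):
        cent = self._frame([[0.25, 0.40, 0.35]])
        assert hubs_from_centralities(cent) == []

    def test_matches_brute_force_triple_filter(self, rng):
        for _ in range(20):
            cent = self._frame(rng.uniform(0, 0.6, size=(15, 3)))
            rule = HubRule()
            hubs = hubs_from_centralities(cent, rule)
            expected = {
                t
                for t in cent.index
                if cent.at[t, "degree_centrality"] > 0.2
                and cent.at[t, "closeness_centrality"] > 0.35
                and cent.at[t, "betweenness_centrality"] > 0.35
            }
            assert set(hubs) == expected
            degs = [cent.at[t, "degree_centrality"] for t in hubs]
            assert degs == sorted(degs, reverse=True)

    def test_sample_order_invariance_of_network(self, demo_dataset):
        (table, *_), _ = demo_dataset
        rho1, p1 = spearman_matrix(table)
        shuffled = AbundanceTable(table.counts.iloc[::-1])
        rho2, p2 = spearman_matrix(shuffled)
        net1 = build_network(rho1, p1)
        net2 = build_network(rho2, p2)
        assert set(map(frozenset, net1.edges)) == set(map(frozenset, net2.edges))
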