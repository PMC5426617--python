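import itertools

import networkx as nx
import numpy as np
import pytest

from cooccurnet import (
    average_degree,
    compute_statistics,
    diameter,
    global_clustering,
    max_modularity,
    mean_path_length,
    mixing_table,
    partition_modularity,
    summarize_ensemble,
)
from cooccurnet.netstats import DegenerateGraphError


def _random_graph(rng, n_max=12):
    n = int(rng.integers(3, n_max + 1))
    p = float(rng.uniform(0.15, 0.7))
    return nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))


def _brute_clustering(g):
    triples = closed = 0
    for k in g.nodes():
        for i, j in itertools.combinations(g.neighbors(k), 2):
            triples += 1
            closed += g.has_edge(i, j)
    if triples == 0:
        return None
    return closed / triples


class TestBasicStatistics:
    def test_average_degree_cases(self):
        assert average_degree(nx.complete_graph(3)) == 2.0
        assert average_degree(nx.path_graph(3)) == pytest.approx(4 / 3)

    def test_average_degree_singleton_convention(self):
        g = nx.path_graph(3)
        g.add_node("isolated")
        assert average_degree(g) == pytest.approx(4 / 3)
        assert average_degree(g, include_singletons=True) == pytest.approx(1.0)

    def test_average_degree_empty_graph_errors(self):
        with pytest.raises(DegenerateGraphError):
            average_degree(nx.Graph())

    def test_mean_path_length_cases(self):
        assert mean_path_length(nx.complete_graph(5)) == 1.0
        assert mean_path_length(nx.path_graph(3)) == pytest.approx(4 / 3)

    def test_diameter_cases(self):
        assert diameter(nx.complete_graph(4)) == 1
        assert diameter(nx.path_graph(5)) == 4

    def test_path_statistics_use_largest_component(self):
        g = nx.disjoint_union(nx.path_graph(4), nx.complete_graph(2))
        assert diameter(g) == 3
        assert mean_path_length(g) == pytest.approx(nx.average_shortest_path_length(nx.path_graph(4)))

    def test_clustering_triangle_and_star(self):
        assert global_clustering(nx.complete_graph(3)) == 1.0
        assert global_clustering(nx.star_graph(4)) == 0.0

    def test_clustering_cycle_with_chord(self):
        g = nx.cycle_graph(4)
        g.add_edge(0, 2)
        assert global_clustering(g) == pytest.approx(0.75)

    def test_clustering_no_paths_errors(self):
        g = nx.Graph([(0, 1)])
        with pytest.raises(DegenerateGraphError):
            global_clustering(g)


class TestOracleEquivalence:
    def test_matrix_recipe_equals_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(200):
            g = _random_graph(rng)
            expected = _brute_clustering(g)
            if expected is None:
                continue
            assert global_clustering(g) == pytest.approx(expected, abs=1e-12)
            assert global_clustering(g) == pytest.approx(nx.transitivity(g), abs=1e-12)
            checked += 1
        assert checked > 100

    def test_path_statistics_match_networkx(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            g = _random_graph(rng)
            sub = g.subgraph(max(nx.connected_components(g), key=len))
            if sub.number_of_nodes() < 2:
                continue
            assert mean_path_length(g) == pytest.approx(
                nx.average_shortest_path_length(sub), abs=1e-12
            )
            assert diameter(g) == nx.diameter(sub)

    def test_statistics_invariant_under_relabeling(self):
        rng = np.random.default_rng(3)
        g = _random_graph(rng, n_max=10)
        mapping = {v: f"node_{v**2 + 7}" for v in g.nodes()}
        h = nx.relabel_nodes(g, mapping)
        for fn in (average_degree, mean_path_length, diameter):
            assert fn(g) == pytest.approx(fn(h))
        if g.number_of_edges() > 0:
            assert max_modularity(g)[0] == pytest.approx(max_modularity(h)[0])


class TestModularity:
    def test_two_disjoint_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        q, partition = max_modularity(g)
        assert q == pytest.approx(0.5)
        groups = {frozenset(v for v, c in partition.items() if c == cc)
                  for cc in set(partition.values())}
        assert groups == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_greedy_is_nonnegative(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            g = _random_graph(rng)
            if g.number_of_edges() == 0:
                continue
            assert max_modularity(g)[0] >= -1e-12

    def test_exhaustive_optimum_on_two_triangles(self):
        # the greedy answer equals the true optimum over all 6-node partitions
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        best = -1.0
        nodes = list(g.nodes())
        for labels in itertools.product(range(3), repeat=6):
            groups = {}
            for v, c in zip(nodes, labels):
                groups.setdefault(c, set()).add(v)
            best = max(best, nx.algorithms.community.modularity(g, groups.values()))
        assert max_modularity(g)[0] == pytest.approx(best)

    def test_edgeless_graph_errors(self):
        g = nx.Graph()
        g.add_nodes_from([1, 2])
        with pytest.raises(DegenerateGraphError):
            max_modularity(g)

    def test_partition_modularity_fixed_labels(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        by_component = {v: "a" if v < 3 else "b" for v in g.nodes()}
        assert partition_modularity(g, by_component) == pytest.approx(0.5)
        assert partition_modularity(g, {v: "x" for v in g.nodes()}) == pytest.approx(0.0)

    def test_partition_modularity_matches_formula(self):
        rng = np.random.default_rng(23)
        g = _random_graph(rng)
        while g.number_of_edges() == 0:
            g = _random_graph(rng)
        labels = {v: "abc"[v % 3] for v in g.nodes()}
        m = g.number_of_edges()
        e = {c: 0.0 for c in "abc"}
        a = {c: 0.0 for c in "abc"}
        for u, v in g.edges():
            if labels[u] == labels[v]:
                e[labels[u]] += 1 / m
            a[labels[u]] += 0.5 / m
            a[labels[v]] += 0.5 / m
        expected = sum(e[c] - a[c] ** 2 for c in "abc")
        assert partition_modularity(g, labels) == pytest.approx(expected, abs=1e-12)


class TestMixingTable:
    def test_single_cross_edge_splits_symmetrically(self):
        g = nx.Graph([("u", "v")])
        table = mixing_table(g, {"u": "X", "v": "Y"})
        assert table.loc["X", "Y"] == pytest.approx(0.5)
        assert table.loc["Y", "X"] == pytest.approx(0.5)
        assert table.loc["All", "All"] == pytest.approx(1.0)

    def test_within_and_cross_fractions(self):
        g = nx.Graph()
        g.add_edges_from([(f"a{i}", f"a{i+1}") for i in range(4)])  # 4 within-A
        g.add_edge("a0", "b0")  # 1 cross A-B
        labels = {v: ("A" if v.startswith("a") else "B") for v in g.nodes()}
        table = mixing_table(g, labels)
        assert table.loc["A", "A"] == pytest.approx(0.8)
        assert table.loc["A", "B"] == pytest.approx(0.1)
        assert table.loc["B", "A"] == pytest.approx(0.1)

    def test_grand_total_and_symmetry(self):
        rng = np.random.default_rng(9)
        g = nx.gnp_random_graph(12, 0.4, seed=4)
        labels = {v: "pqr"[int(rng.integers(3))] for v in g.nodes()}
        table = mixing_table(g, labels)
        body = table.drop(index="All", columns="All")
        assert body.to_numpy().sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(body.to_numpy(), body.to_numpy().T, atol=1e-12)

    def test_unlabeled_nodes_become_other(self):
        g = nx.Graph([("u", "v")])
        table = mixing_table(g, {})
        assert table.loc["Other", "Other"] == pytest.approx(1.0)


class TestSummaries:
    def test_mean_path_length_bounded_by_diameter(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            g = _random_graph(rng)
            try:
                assert mean_path_length(g) <= diameter(g) + 1e-12
            except DegenerateGraphError:
                continue

    def test_ensemble_summary_shapes(self):
        graphs = [nx.gnp_random_graph(15, 0.3, seed=s) for s in range(5)]
        frame, summary = summarize_ensemble(graphs)
        assert len(frame) == 5
        assert summary["clustering"]["n"] <= 5
        assert np.isfinite(summary["average_degree"]["mean"])

    def test_degenerate_graphs_reported_as_none(self):
        stats = compute_statistics(nx.Graph([(0, 1)]))
        assert stats.clustering is None
        assert stats.n == 2 and stats.m == 1
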