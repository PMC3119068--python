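import math

import networkx as nx
import numpy as np
import pytest

import oracles
from conftest import net_from_graph, random_graph_suite
from hmmnet.metrics import (
    CentralityRecord,
    betweenness,
    centrality_records,
    closeness,
    component_summary,
    connected_components,
    count_tree_components,
    degree_histogram,
    density,
    diameter,
    fit_loglog_quadratic,
    global_transitivity,
    mean_distance,
    size_density_correlation,
    summarize_components,
    top_k,
)


class TestDegreeHistogram:
    def test_triangle(self):
        hist = degree_histogram(nx.complete_graph(3))
        assert hist.counts == {2: 3}
        assert hist.mean_degree == 2.0

    def test_star(self):
        hist = degree_histogram(nx.star_graph(3))
        assert hist.counts == {1: 3, 3: 1}

    def test_matches_direct_recount(self):
        g = nx.gnp_random_graph(30, 0.2, seed=42)
        hist = degree_histogram(g)
        recount = {}
        for v in g.nodes:
            d = sum(1 for _ in g.neighbors(v))
            recount[d] = recount.get(d, 0) + 1
        assert hist.counts == recount
        assert hist.n_vertices == g.number_of_nodes()


class TestQuadraticFit:
    def test_exact_interpolation(self):
        # counts chosen so log2(N_k) = 3 - 0.5 x - 0.1 x^2 exactly
        degrees = [1, 2, 4, 8]
        counts = {}
        for k in degrees:
            x = math.log2(k)
            counts[k] = 2 ** (3 - 0.5 * x - 0.1 * x * x)
        hist = degree_histogram(nx.complete_graph(3))  # dummy summary fields
        hist = type(hist)(
            counts=counts, min_degree=1, max_degree=8, mean_degree=2, median_degree=2
        )
        fit = fit_loglog_quadratic(hist)
        assert fit.c0 == pytest.approx(3.0, abs=1e-9)
        assert fit.c1 == pytest.approx(-0.5, abs=1e-9)
        assert fit.c2 == pytest.approx(-0.1, abs=1e-9)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(7)
        counts = {int(k): int(c) for k, c in zip(rng.integers(1, 50, 8), rng.integers(1, 500, 8))}
        hist = degree_histogram(nx.complete_graph(3))
        hist = type(hist)(
            counts=counts, min_degree=1, max_degree=50, mean_degree=1, median_degree=1
        )
        fit = fit_loglog_quadratic(hist)
        x = np.log2(list(counts.keys()))
        y = np.log2(list(counts.values()))
        X = np.column_stack([np.ones_like(x), x, x**2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert (fit.c0, fit.c1, fit.c2) == pytest.approx(tuple(beta), abs=1e-8)

    def test_underdetermined_raises(self):
        hist = degree_histogram(nx.path_graph(2))  # single distinct degree
        with pytest.raises(ValueError):
            fit_loglog_quadratic(hist)


class TestDensity:
    def test_full_network_value(self):
        # 11,929 models and 151,461 similarity edges give density ~0.002
        assert density(11929, 151461) == pytest.approx(0.00213, abs=5e-5)
        assert round(density(11929, 151461), 3) == 0.002

    def test_complete_graph_is_one(self):
        assert density(70, 70 * 69 // 2) == 1.0

    def test_path_on_three(self):
        assert density(3, 2) == pytest.approx(2 / 3)

    def test_too_few_vertices(self):
        with pytest.raises(ValueError):
            density(1, 0)


class TestComponents:
    def test_two_triangles(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        summaries = summarize_components(g)
        assert len(summaries) == 2
        for s in summaries:
            assert s.density == 1.0
            assert s.diameter == 1
            assert s.is_clique and not s.is_tree

    def test_path_is_tree(self):
        s, = summarize_components(nx.path_graph(4))
        assert s.diameter == 3
        assert s.is_tree and not s.is_clique
        assert s.mean_distance == pytest.approx(5 / 3)

    def test_sizes_partition_vertices(self):
        g = nx.gnp_random_graph(40, 0.08, seed=3)
        g.remove_nodes_from([v for v, d in list(g.degree()) if d == 0])
        comps = connected_components(g)
        assert sum(len(c) for c in comps) == g.number_of_nodes()

    def test_clique_iff_diameter_one(self):
        for g in random_graph_suite(30, 10, seed=5):
            for s in summarize_components(g):
                assert s.is_clique == (s.diameter == 1)
                assert s.is_clique == (s.density == 1.0)

    def test_tree_count(self):
        forest = nx.disjoint_union_all(
            [nx.path_graph(3), nx.path_graph(4), nx.path_graph(2)]
        )
        assert count_tree_components(forest) == 3
        mixed = nx.disjoint_union(nx.complete_graph(3), nx.path_graph(2))
        assert count_tree_components(mixed) == 1

    def test_tree_count_matches_cycle_detection(self):
        for g in random_graph_suite(30, 12, seed=11):
            expected = sum(
                1
                for comp in nx.connected_components(g)
                if not _has_cycle(g.subgraph(comp))
            )
            assert count_tree_components(g) == expected


def _has_cycle(graph):
    """DFS cycle detection, independent of edge-count arithmetic."""
    seen = set()
    for start in graph.nodes:
        if start in seen:
            continue
        stack = [(start, None)]
        while stack:
            node, parent = stack.pop()
            if node in seen:
                return True
            seen.add(node)
            stack.extend((nb, node) for nb in graph.neighbors(node) if nb != parent)
    return False


class TestCentralities:
    def test_complete_graph_betweenness_zero(self):
        btw = betweenness(nx.complete_graph(10))
        assert all(v == 0.0 for v in btw.values())

    def test_path_betweenness(self):
        btw = betweenness(nx.path_graph(3))
        assert btw[1] == 1.0
        assert btw[0] == btw[2] == 0.0

    def test_complete_graph_closeness_one(self):
        cl = closeness(nx.complete_graph(8))
        assert all(v == pytest.approx(1.0) for v in cl.values())

    def test_path_closeness(self):
        cl = closeness(nx.path_graph(3))
        assert cl[0] == pytest.approx(2 / 3)
        assert cl[1] == pytest.approx(1.0)
        assert cl[2] == pytest.approx(2 / 3)

    def test_cycle_closeness(self):
        cl = closeness(nx.cycle_graph(4))
        assert all(v == pytest.approx(3 / 4) for v in cl.values())

    def test_closeness_refuses_disconnected(self):
        g = nx.disjoint_union(nx.path_graph(2), nx.path_graph(2))
        with pytest.raises(ValueError):
            closeness(g)

    def test_mean_distance_and_diameter_examples(self):
        g = nx.complete_graph(6)
        assert mean_distance(g) == 1.0
        assert diameter(g) == 1
        p4 = nx.path_graph(4)
        assert mean_distance(p4) == pytest.approx(5 / 3)
        assert diameter(p4) == 3

    def test_closeness_one_iff_adjacent_to_all(self):
        g = nx.star_graph(5)
        cl = closeness(g)
        assert cl[0] == pytest.approx(1.0)
        assert all(cl[v] < 1.0 for v in range(1, 6))


class TestTransitivity:
    @pytest.mark.parametrize(
        "graph, expected",
        [
            (nx.complete_graph(3), 1.0),
            (nx.path_graph(3), 0.0),
            (nx.complete_graph(4), 1.0),
        ],
    )
    def test_examples(self, graph, expected):
        assert global_transitivity(graph) == pytest.approx(expected)

    def test_k4_minus_edge(self):
        g = nx.complete_graph(4)
        g.remove_edge(0, 1)
        # 2 triangles, 8 connected triples
        assert global_transitivity(g) == pytest.approx(0.75)


class TestSizeDensityCorrelation:
    def _summary(self, size, dens):
        return type(
            "S", (), {"size": size, "density": dens}
        )()

    def test_perfect_discordance(self):
        summaries = [self._summary(3, 0.9), self._summary(4, 0.5), self._summary(5, 0.1)]
        res = size_density_correlation(summaries)
        assert res.tau == pytest.approx(-1.0)
        assert res.n == 3

    def test_all_ties_give_zero(self):
        summaries = [self._summary(s, 0.5) for s in (3, 4, 5, 6)]
        res = size_density_correlation(summaries)
        assert res.tau == 0.0

    def test_small_components_excluded(self):
        summaries = [self._summary(2, 1.0)] * 5 + [
            self._summary(3, 0.9),
            self._summary(4, 0.5),
            self._summary(5, 0.1),
        ]
        assert size_density_correlation(summaries).n == 3

    def test_too_few_raises(self):
        with pytest.raises(ValueError):
            size_density_correlation([self._summary(3, 0.5)])

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            sizes = rng.integers(3, 30, 8)
            dens = rng.uniform(0.05, 1.0, 8).round(2)
            summaries = [self._summary(int(s), float(d)) for s, d in zip(sizes, dens)]
            res = size_density_correlation(summaries)
            expected = oracles.brute_kendall_tau_b([s.size for s in summaries],
                                                   [s.density for s in summaries])
            assert res.tau == pytest.approx(expected, abs=1e-12)
            assert 0 < res.p_value <= 1


class TestTopK:
    def _records(self, values):
        return [
            CentralityRecord(sid=f"d{i:04d}a_", sccs=None, degree=v, betweenness=float(v), closeness=0.5)
            for i, v in enumerate(values)
        ]

    def test_tie_broken_by_sid(self):
        recs = self._records([5, 5, 1])
        top = top_k(recs, "degree", 2)
        assert [r.sid for r in top] == ["d0000a_", "d0001a_"]

    def test_k_larger_than_records(self):
        recs = self._records([3, 2, 1])
        assert len(top_k(recs, "betweenness", 10)) == 3

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            top_k(self._records([1]), "pagerank", 1)

    def test_planted_hub_ranks_first(self):
        g = nx.star_graph(6)
        g.add_edge(1, 2)
        records = centrality_records(net_from_graph(g))
        top = top_k(records, "degree", 1)
        assert top[0].sid == "0"


@pytest.fixture(scope="module")
def graphs():
    return random_graph_suite(25, 12, seed=99)


class TestOracleAgreementSmoke:
    """Small-scale agreement with the brute-force oracles; the full
    200-graph equivalence sweep lives in the acceptance suite."""

    def test_betweenness(self, graphs):
        for g in graphs:
            expected = oracles.brute_betweenness(g)
            actual = betweenness(g)
            for v in g.nodes:
                assert actual[v] == pytest.approx(expected[v], abs=1e-9)

    def test_distances(self, graphs):
        for g in graphs:
            for comp in nx.connected_components(g):
                sub = g.subgraph(comp)
                if sub.number_of_nodes() < 2:
                    continue
                assert diameter(sub) == oracles.brute_diameter(sub)
                assert mean_distance(sub) == pytest.approx(
                    oracles.brute_mean_distance(sub)
                )
                expected_cl = oracles.brute_closeness(sub)
                actual_cl = closeness(sub)
                for v in sub.nodes:
                    assert actual_cl[v] == pytest.approx(expected_cl[v])

    def test_transitivity(self, graphs):
        for g in graphs:
            assert global_transitivity(g) == pytest.approx(
                oracles.brute_transitivity(g), abs=1e-12
            )
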