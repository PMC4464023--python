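import math
import random

import networkx as nx
import numpy as np
import pytest

from protnet import (InteractionNetwork, average_clustering_coefficient,
                     average_path_length, diameter, erdos_renyi,
                     make_fixture_network, modularity,
                     scale_free_fitting_index, topology_report, transitivity)
from protnet.topology import sffi_from_degrees


# -- independent brute-force oracles ----------------------------------------

def brute_transitivity(g: nx.Graph) -> float:
    nodes = list(g.nodes())
    triangles = triples = 0
    for v in nodes:
        nbrs = list(g.neighbors(v))
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                triples += 1
                if g.has_edge(nbrs[i], nbrs[j]):
                    triangles += 1
    return 3 * (triangles / 3) / triples if triples else 0.0


def brute_acc(g: nx.Graph) -> float:
    total = 0.0
    for v in g.nodes():
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for i in range(k) for j in range(i + 1, k)
                    if g.has_edge(nbrs[i], nbrs[j]))
        total += links / (k * (k - 1) / 2)
    return total / g.number_of_nodes()


def floyd_warshall_largest_component(g: nx.Graph):
    comp = max(nx.connected_components(g), key=len)
    nodes = sorted(comp)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    INF = math.inf
    d = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    for a, b in g.subgraph(nodes).edges():
        d[idx[a]][idx[b]] = d[idx[b]][idx[a]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[k][j] + d[i][k]
    vals = [d[i][j] for i in range(n) for j in range(n) if i != j]
    return sum(vals) / len(vals), max(vals)


def random_small_graphs(n_graphs=30, max_nodes=12, seed=0):
    rnd = random.Random(seed)
    for _ in range(n_graphs):
        n = rnd.randint(3, max_nodes)
        p = rnd.uniform(0.15, 0.8)
        g = nx.gnp_random_graph(n, p, seed=rnd.randrange(10 ** 6))
        yield g


# -- worked examples ---------------------------------------------------------

class TestExamples:
    def test_triangle(self, triangle):
        assert transitivity(triangle) == 1.0
        assert average_clustering_coefficient(triangle) == 1.0

    def test_star_has_no_triangles(self):
        assert transitivity(make_fixture_network("star", 5)) == 0.0

    def test_path3(self):
        p3 = make_fixture_network("path", 3)
        assert average_clustering_coefficient(p3) == 0.0
        assert average_path_length(p3) == pytest.approx(4 / 3)
        assert diameter(p3) == 2

    def test_complete_graph(self):
        k5 = nx.complete_graph(5)
        assert average_path_length(k5) == 1.0
        assert diameter(k5) == 1

    def test_edgeless_path_metrics_undefined(self):
        with pytest.raises(ValueError):
            average_path_length(InteractionNetwork(["A", "B"], []))

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            transitivity(InteractionNetwork(["A", "B"], [(0, 1)]))


class TestSFFI:
    def test_perfect_power_law_scores_one(self):
        # exact histogram P(k) ~ k^-2 over powers of two
        degrees = []
        for k in (1, 2, 4, 8, 16, 32, 64):
            degrees.extend([k] * (4096 // (k * k)))
        assert sffi_from_degrees(degrees) == pytest.approx(1.0)

    def test_regular_graph_undefined(self):
        with pytest.raises(ValueError):
            scale_free_fitting_index(nx.cycle_graph(10))

    def test_er_graph_fits_poorly(self):
        values = [scale_free_fitting_index(erdos_renyi(1890, 4714, seed=s))
                  for s in range(3)]
        # Poisson-like degree distributions are far from a log-log line
        assert 0.1 < np.mean(values) < 0.6


class TestModularity:
    def test_two_disjoint_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        assert modularity(g) == pytest.approx(0.5)

    def test_complete_graph_single_community(self):
        assert modularity(nx.complete_graph(6)) == pytest.approx(0.0)

    def test_ring_of_cliques_strongly_modular(self):
        net = make_fixture_network("ring_of_cliques", 4, clique_size=5)
        assert modularity(net) > 0.6


class TestReport:
    def test_triangle_report_flags_undefined_sffi(self, triangle):
        rep = topology_report(triangle)
        assert rep.sffi is None
        assert (rep.apl, rep.diameter) == (1.0, 1)
        assert (rep.acc, rep.transitivity, rep.modularity) == (1.0, 1.0, 0.0)

    def test_report_row_has_table_column_order(self, triangle):
        row = topology_report(triangle).to_tsv_row("tri")
        assert row.split("\t")[0] == "tri"
        assert "NA" in row


class TestAgainstBruteForce:
    def test_transitivity_and_acc_match_triple_counting(self):
        for g in random_small_graphs(seed=1):
            if g.number_of_edges() == 0:
                continue
            assert transitivity(g) == pytest.approx(brute_transitivity(g))
            assert average_clustering_coefficient(g) == pytest.approx(brute_acc(g))

    def test_apl_and_diameter_match_floyd_warshall(self):
        for g in random_small_graphs(seed=2):
            if g.number_of_edges() == 0:
                continue
            apl, diam = floyd_warshall_largest_component(g)
            assert average_path_length(g) == pytest.approx(apl)
            assert diameter(g) == diam

    def test_metrics_invariant_under_relabeling(self):
        rnd = random.Random(3)
        for g in random_small_graphs(n_graphs=10, seed=3):
            if g.number_of_edges() < 2:
                continue
            perm = list(g.nodes())
            rnd.shuffle(perm)
            h = nx.relabel_nodes(g, dict(zip(g.nodes(), perm)))
            assert transitivity(h) == pytest.approx(transitivity(g))
            assert average_clustering_coefficient(h) == pytest.approx(
                average_clustering_coefficient(g))
            assert average_path_length(h) == pytest.approx(average_path_length(g))
            assert diameter(h) == diameter(g)
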