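import itertools

import networkx as nx
import numpy as np
import pytest

from satkit._align import revcomp
from satkit.clustering import (RepeatCluster, build_read_graph, classify_shape,
                               cluster_density, connected_components,
                               select_candidate_clusters)

from conftest import mutate, random_seq


def graph_from_edges(n, edges):
    """A ReadGraph-shaped object built directly from an edge list."""
    from satkit.clustering import ReadGraph
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return ReadGraph(g, {i: "A" * 100 for i in range(n)})


class TestBuildReadGraph:
    def test_identical_reads_give_one_full_identity_edge(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 100)
        rg = build_read_graph({"a": seq, "b": seq})
        assert rg.graph.number_of_edges() == 1
        assert rg.graph.edges["a", "b"]["identity"] == 100.0

    def test_unrelated_reads_give_no_edge(self):
        rng = np.random.default_rng(1)
        rg = build_read_graph({"a": random_seq(rng, 100),
                               "b": random_seq(rng, 100)})
        assert rg.graph.number_of_edges() == 0

    def test_reverse_complement_reads_are_linked(self):
        rng = np.random.default_rng(2)
        seq = random_seq(rng, 100)
        rg = build_read_graph({"a": seq, "b": revcomp(seq)})
        assert rg.graph.has_edge("a", "b")
        assert not rg.graph.edges["a", "b"]["same_strand"]

    def test_tandem_tiling_reads_form_single_component(self):
        rng = np.random.default_rng(3)
        monomer = random_seq(rng, 50)
        array = monomer * 10  # 500 bp tandem
        reads = {f"r{i}": array[s:s + 100]
                 for i, s in enumerate(range(0, 401, 50))}
        rg = build_read_graph(reads)
        assert nx.number_connected_components(rg.graph) == 1

    def test_seeded_and_exact_modes_agree_on_small_input(self):
        rng = np.random.default_rng(4)
        seq = random_seq(rng, 120)
        reads = {f"r{i}": seq[s:s + 80] for i, s in enumerate(range(0, 41, 20))}
        reads["lone"] = random_seq(rng, 80)
        seeded = build_read_graph(reads)
        exact = build_read_graph(reads, exact=True)
        assert set(map(frozenset, seeded.graph.edges)) == \
            set(map(frozenset, exact.graph.edges))

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            build_read_graph({})


class TestComponents:
    def test_two_triangles(self):
        rg = graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        clusters = connected_components(rg)
        assert [len(c) for c in clusters] == [3, 3]

    def test_genome_proportion_sums_to_100(self):
        rg = graph_from_edges(10, [(0, 1), (2, 3), (3, 4)])
        clusters = connected_components(rg)
        assert sum(c.genome_proportion for c in clusters) == pytest.approx(100.0)

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(5, 51))
            edges = [(int(a), int(b)) for a, b in
                     rng.integers(0, n, size=(n, 2)) if a != b]
            rg = graph_from_edges(n, edges)
            clusters = connected_components(rg)
            # oracle: boolean transitive closure (Warshall)
            reach = [[False] * n for _ in range(n)]
            for i in range(n):
                reach[i][i] = True
            for a, b in edges:
                reach[a][b] = reach[b][a] = True
            for k in range(n):
                for i in range(n):
                    if reach[i][k]:
                        for j in range(n):
                            if reach[k][j]:
                                reach[i][j] = True
            oracle = set()
            seen = set()
            for i in range(n):
                if i not in seen:
                    comp = frozenset(j for j in range(n) if reach[i][j])
                    oracle.add(comp)
                    seen |= comp
            assert {frozenset(c.members) for c in clusters} == oracle

    def test_component_order_is_input_order_invariant(self):
        rng = np.random.default_rng(8)
        seq = random_seq(rng, 100)
        reads = {"a": seq, "b": seq, "c": random_seq(rng, 100)}
        shuffled = dict(reversed(list(reads.items())))
        c1 = connected_components(build_read_graph(reads))
        c2 = connected_components(build_read_graph(shuffled))
        assert [sorted(map(str, c.members)) for c in c1] == \
            [sorted(map(str, c.members)) for c in c2]


class TestDensityAndShape:
    def test_density_values(self):
        rg = graph_from_edges(1, [])
        assert cluster_density(RepeatCluster(1, [0]), rg) == 0.0
        rg = graph_from_edges(2, [(0, 1)])
        assert cluster_density(RepeatCluster(1, [0, 1]), rg) == 1.0
        k4 = graph_from_edges(4, list(itertools.combinations(range(4), 2)))
        assert cluster_density(RepeatCluster(1, list(range(4))), k4) == 3.0

    def test_empty_cluster_density_raises(self):
        rg = graph_from_edges(2, [(0, 1)])
        with pytest.raises(ValueError):
            cluster_density(RepeatCluster(1, []), rg)

    def test_path_graph_is_linear(self):
        rg = graph_from_edges(20, [(i, i + 1) for i in range(19)])
        assert classify_shape(RepeatCluster(1, list(range(20))), rg) == "linear"

    @pytest.mark.parametrize("n", [10, 20, 37, 64, 100])
    def test_cycle_graphs_are_rings(self, n):
        rg = graph_from_edges(n, [(i, (i + 1) % n) for i in range(n)])
        assert classify_shape(RepeatCluster(1, list(range(n))), rg) == "ring"

    def test_short_monomer_tandem_reads_are_globular_and_dense(self):
        # reads from a 20-bp monomer array align at every phase: the
        # component is near-complete, far denser than the 0.1 cutoff
        rng = np.random.default_rng(9)
        monomer = random_seq(rng, 20)
        array = monomer * 40
        reads = {}
        for i in range(60):
            s = int(rng.integers(0, len(array) - 100))
            reads[f"r{i}"] = mutate(array[s:s + 100], 2, rng)
        rg = build_read_graph(reads)
        clusters = connected_components(rg)
        big = clusters[0]
        assert big.shape == "globular"
        assert big.density > 1.0

    def test_tandem_cluster_density_exceeds_one_with_500_reads(self):
        rng = np.random.default_rng(10)
        monomer = random_seq(rng, 60)
        array = monomer * 100  # 6 kb
        reads = {}
        for i in range(500):
            s = int(rng.integers(0, len(array) - 100))
            reads[f"r{i}"] = mutate(array[s:s + 100], 3, rng)  # ~3% divergence
        rg = build_read_graph(reads)
        clusters = connected_components(rg)
        assert len(clusters[0]) >= 490
        assert clusters[0].density > 1.0


class TestSelection:
    def test_selection_rules(self):
        mk = lambda shape, dens: RepeatCluster(1, [0, 1, 2], density=dens,
                                               shape=shape)
        assert select_candidate_clusters([mk("globular", 0.05)]) == []
        assert select_candidate_clusters([mk("linear", 5.0)]) == []
        ring = mk("ring", 1.9)
        assert select_candidate_clusters([ring]) == [ring]
        boundary = mk("globular", 0.1)
        assert select_candidate_clusters([boundary]) == []  # strictly above
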