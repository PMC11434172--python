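"""Correlation calling, graph construction, clusters and symmetric difference."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from smg.graph import (
    average_degree,
    build_positive_graph,
    canonical_edge,
    connected_components,
    is_negative_correlation,
    is_positive_correlation,
    negative_edges,
    symmetric_difference,
)

from conftest import random_table


def dm_from(entries, taxa):
    dm = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for (u, v), d in entries.items():
        dm.loc[u, v] = dm.loc[v, u] = d
    return dm


class TestCorrelationCalls:
    def test_zero_distance_is_positive(self):
        assert is_positive_correlation(0.0, 10)

    def test_indicative_pair_is_not_positive(self):
        # the O/P construction guarantees d = 2(n-1) >= n-1
        assert not is_positive_correlation(18.0, 10)

    def test_threshold_is_strict(self):
        assert not is_positive_correlation(9.0, 10)
        assert is_positive_correlation(np.nextafter(9.0, 0.0), 10)

    def test_small_sample_count_rejected(self):
        with pytest.raises(ValueError, match="n_samples"):
            is_positive_correlation(0.0, 1)

    def test_reversed_profile_is_negative(self):
        assert is_negative_correlation([0, 1, 2], [2, 1, 0])

    def test_profile_not_negative_with_itself(self):
        assert not is_negative_correlation([0, 1, 2], [0, 1, 2])

    def test_scaled_complement_is_negative(self, rng):
        # c * (1 - g) is exactly negatively correlated with g for any c > 0
        g = rng.random(8)
        for c in (0.1, 1.0, 16.0):
            assert is_negative_correlation(g, c * (1.0 - g))

    def test_negativity_is_symmetric(self, rng):
        for _ in range(20):
            a, b = rng.random(6), rng.random(6)
            assert is_negative_correlation(a, b) == is_negative_correlation(b, a)

    def test_negative_edges_match_pairwise_calls(self, rng):
        table = random_table(rng, 8, 5)
        edges = negative_edges(table)
        for i, u in enumerate(table.index):
            for v in table.index[i + 1 :]:
                expected = is_negative_correlation(
                    table.loc[u].to_numpy(), table.loc[v].to_numpy()
                )
                assert (canonical_edge(u, v) in edges) == expected


class TestPositiveGraph:
    def test_all_far_gives_edgeless_graph(self):
        dm = dm_from({("a", "b"): 5, ("a", "c"): 9, ("b", "c"): 7}, list("abc"))
        g = build_positive_graph(dm, n_samples=3)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == set("abc")

    def test_single_close_pair(self):
        dm = dm_from({("a", "b"): 0.5, ("a", "c"): 5, ("b", "c"): 5}, list("abc"))
        g = build_positive_graph(dm, n_samples=3)
        assert set(map(frozenset, g.edges)) == {frozenset({"a", "b"})}
        assert g.edges["a", "b"]["distance"] == 0.5

    def test_identical_taxa_always_linked(self):
        dm = dm_from({("a", "b"): 0.0}, list("ab"))
        g = build_positive_graph(dm, n_samples=12)
        assert g.has_edge("a", "b")

    def test_requires_sample_count(self):
        dm = dm_from({}, list("ab"))
        with pytest.raises(ValueError, match="n_samples"):
            build_positive_graph(dm)


class TestComponentsAndDegree:
    def test_edgeless_graph_gives_singletons(self):
        g = nx.empty_graph(["a", "b", "c"])
        assert connected_components(g) == [{"a"}, {"b"}, {"c"}]

    def test_path_is_single_component(self):
        g = nx.path_graph(["a", "b", "c"])
        assert connected_components(g) == [{"a", "b", "c"}]

    def test_component_order_is_deterministic(self):
        g = nx.empty_graph(["z", "m", "a"])
        g.add_edge("z", "m")
        assert connected_components(g) == [{"a"}, {"m", "z"}]

    @pytest.mark.parametrize(
        "graph, expected",
        [
            (nx.path_graph(3), 4 / 3),
            (nx.empty_graph(5), 0.0),
            (nx.complete_graph(4), 3.0),
        ],
    )
    def test_average_degree(self, graph, expected):
        assert average_degree(graph) == pytest.approx(expected)

    def test_average_degree_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="no vertices"):
            average_degree(nx.Graph())


class TestSymmetricDifference:
    def build(self, vertices, edges):
        g = nx.Graph()
        g.add_nodes_from(vertices)
        g.add_edges_from(edges)
        return g

    def test_textbook_example(self):
        g1 = self.build("abcd", [("a", "b"), ("b", "c")])
        g2 = self.build("abcd", [("b", "c"), ("c", "d")])
        diff = symmetric_difference(g1, g2)
        assert diff.changed_edges == {("a", "b"), ("c", "d")}
        assert diff.magnitude == 2

    def test_self_difference_is_empty(self):
        g = self.build("abc", [("a", "b")])
        assert symmetric_difference(g, g).magnitude == 0

    def test_single_new_edge(self):
        g1 = self.build("ab", [])
        g2 = self.build("ab", [("a", "b")])
        assert symmetric_difference(g1, g2).magnitude == 1

    def test_vertex_mismatch_rejected(self):
        with pytest.raises(ValueError, match="harmonize"):
            symmetric_difference(self.build("ab", []), self.build("ac", []))

    def test_count_identity_on_random_graphs(self, rng):
        for _ in range(25):
            nodes = list(range(12))
            g1 = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
            g2 = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
            diff = symmetric_difference(g1, g2)
            e1 = {canonical_edge(*e) for e in g1.edges}
            e2 = {canonical_edge(*e) for e in g2.edges}
            assert diff.magnitude == len(e1) + len(e2) - 2 * len(e1 & e2)
            # commutative
            assert symmetric_difference(g2, g1).changed_edges == diff.changed_edges
            # degree sum = 2 |E|
            assert sum(diff.degrees().values()) == 2 * diff.magnitude
            assert set(diff.degrees()) == set(nodes)
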