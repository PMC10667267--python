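"""PPI graph building, Cytoscape-convention centralities, key-target filter."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm.ppi_topology import (
    CentralityReport,
    build_graph,
    centralities,
    filter_key_targets,
    subgraph,
)
from netpharm.target_sets import TargetSet

from oracles import brute_force_centralities


class TestBuildGraph:
    def test_dedup_reversed_pairs_and_drop_self_loops(self):
        g = build_graph([("A", "B"), ("B", "A"), ("A", "A")])
        assert g.nodes == ["A", "B"] and g.edges == [("A", "B")]

    def test_restriction_keeps_isolated_members(self):
        g = build_graph([("A", "B"), ("C", "D")], restrict_to=TargetSet("t", {"A", "B", "C"}))
        assert g.nodes == ["A", "B", "C"]
        assert g.edges == [("A", "B")]
        assert centralities(g).degree["C"] == 0

    def test_malformed_row_reports_line_number(self):
        with pytest.raises(ValueError, match="row 2"):
            build_graph([("A", "B"), ("C",)])

    def test_score_column_thresholding(self):
        rows = [("A", "B", 0.9), ("B", "C", 0.2), ("C", "D", 0.7)]
        g = build_graph(rows, score_min=0.5)
        assert g.edges == [("A", "B"), ("C", "D")]

    def test_restricted_counts_match_brute_force_filter(self):
        rng = np.random.default_rng(3)
        names = [f"N{i}" for i in range(40)]
        rows = [(names[rng.integers(40)], names[rng.integers(40)]) for _ in range(300)]
        keep = set(rng.choice(names, size=24, replace=False))
        g = build_graph(rows, restrict_to=TargetSet("k", keep))
        brute_edges = {tuple(sorted((a, b))) for a, b in rows
                       if a != b and a in keep and b in keep}
        assert g.n_nodes == 24 and set(g.edges) == brute_edges


class TestCentralities:
    def test_path_graph_hand_values(self):
        g = build_graph([("A", "B"), ("B", "C")])
        rep = centralities(g)
        assert rep.betweenness["B"] == pytest.approx(1.0)
        assert rep.closeness["B"] == pytest.approx(1.0)
        assert rep.closeness["A"] == pytest.approx(2 / 3)
        assert rep.degree == {"A": 1, "B": 2, "C": 1}

    def test_star_center_dominates(self):
        g = build_graph([("HUB", x) for x in "ABCD"])
        rep = centralities(g)
        assert rep.degree["HUB"] == 4
        assert rep.betweenness["HUB"] == pytest.approx(1.0)
        assert rep.closeness["HUB"] == pytest.approx(1.0)
        assert rep.betweenness["A"] == 0.0

    def test_complete_graph_betweenness_zero_closeness_one(self):
        g = build_graph(list(itertools.combinations("ABCDE", 2)))
        rep = centralities(g)
        assert all(rep.betweenness[n] == pytest.approx(0.0) for n in g.nodes)
        assert all(rep.closeness[n] == pytest.approx(1.0) for n in g.nodes)

    def test_disconnected_closeness_is_component_local(self):
        g = build_graph([("A", "B"), ("B", "C"), ("X", "Y")])
        rep = centralities(g)
        assert rep.closeness["X"] == pytest.approx(1.0)  # its 2-node component
        assert rep.closeness["A"] == pytest.approx(2 / 3)
        wf = centralities(g, wf_closeness=True)
        assert wf.closeness["X"] == pytest.approx(1.0 * 1 / 4)  # rescaled by (|comp|-1)/(n-1)

    def test_isolated_nodes_score_zero(self):
        g = build_graph([("A", "B")], restrict_to=TargetSet("t", {"A", "B", "Z"}))
        rep = centralities(g)
        assert rep.betweenness["Z"] == 0.0 and rep.closeness["Z"] == 0.0

    def test_matches_exhaustive_path_oracle_on_small_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(2, 8))
            nodes = [f"V{i}" for i in range(n)]
            edges = [(a, b) for a, b in itertools.combinations(nodes, 2)
                     if rng.random() < 0.45]
            g = build_graph(edges, restrict_to=TargetSet("t", set(nodes)))
            rep = centralities(g)
            deg, bc, cc = brute_force_centralities(nodes, edges)
            for v in nodes:
                assert rep.degree[v] == deg[v]
                assert rep.betweenness[v] == pytest.approx(bc[v], abs=1e-10)
                assert rep.closeness[v] == pytest.approx(cc[v], abs=1e-10)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.integers(0, 12), st.integers(0, 12)), max_size=40))
    def test_degree_sum_is_twice_edge_count(self, pairs):
        rows = [(f"N{a}", f"N{b}") for a, b in pairs if a != b]
        if not rows:
            return
        g = build_graph(rows)
        rep = centralities(g)
        assert sum(rep.degree.values()) == 2 * g.n_edges


class TestFilterAndSubgraph:
    def test_inclusive_boundaries(self):
        g = build_graph([("A", "B")])
        rep = CentralityReport(degree={"A": 4, "B": 3}, betweenness={"A": 0.01, "B": 0.5},
                               closeness={"A": 0.5, "B": 0.9})
        key = filter_key_targets(g, rep)
        assert key.genes == {"A"}  # exactly at every threshold -> included

    def test_zero_thresholds_return_every_node(self):
        g = build_graph([("A", "B")], restrict_to=TargetSet("t", {"A", "B", "Z"}))
        rep = centralities(g)
        assert filter_key_targets(g, rep, 0, 0.0, 0.0).genes == {"A", "B", "Z"}
        # any positive degree threshold excludes the isolated node
        assert "Z" not in filter_key_targets(g, rep, 1, 0.0, 0.0).genes

    def test_monotone_in_each_threshold(self):
        rng = np.random.default_rng(9)
        nodes = [f"N{i}" for i in range(15)]
        edges = [(a, b) for a, b in itertools.combinations(nodes, 2) if rng.random() < 0.3]
        g = build_graph(edges)
        rep = centralities(g)
        base = filter_key_targets(g, rep, 2, 0.0, 0.2).genes
        for deg, bc, cc in [(3, 0.0, 0.2), (2, 0.01, 0.2), (2, 0.0, 0.4)]:
            assert filter_key_targets(g, rep, deg, bc, cc).genes <= base

    def test_negative_threshold_rejected(self):
        g = build_graph([("A", "B")])
        with pytest.raises(ValueError, match="non-negative"):
            filter_key_targets(g, None, -1, 0.0, 0.0)

    def test_subgraph_identity_singleton_and_brute_force_edges(self):
        rng = np.random.default_rng(13)
        nodes = [f"N{i}" for i in range(12)]
        edges = [(a, b) for a, b in itertools.combinations(nodes, 2) if rng.random() < 0.35]
        g = build_graph(edges, restrict_to=TargetSet("t", set(nodes)))
        assert subgraph(g, TargetSet("all", set(nodes))).edges == g.edges
        single = subgraph(g, TargetSet("one", {"N0"}))
        assert single.n_nodes == 1 and single.n_edges == 0
        keep = set(rng.choice(nodes, size=6, replace=False))
        sub = subgraph(g, TargetSet("k", keep))
        assert set(sub.edges) == {tuple(sorted(e)) for e in edges
                                  if e[0] in keep and e[1] in keep and e[0] != e[1]}
        with pytest.raises(KeyError, match="MISSING"):
            subgraph(g, TargetSet("bad", {"MISSING"}))

    def test_induced_subgraph_centralities_are_recomputed(self):
        # a path A-B-C-D: B is central; restricted to {A,B}, B's closeness changes
        g = build_graph([("A", "B"), ("B", "C"), ("C", "D")])
        full = centralities(g)
        sub = centralities(subgraph(g, TargetSet("k", {"A", "B"})))
        assert sub.closeness["B"] != pytest.approx(full.closeness["B"])
        assert sub.betweenness["B"] == 0.0
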