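"""Graph construction, degree/betweenness statistics, power-law fit."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hubnet.graph import (
    GraphInputError,
    betweenness_centrality,
    build_graph,
    fit_power_law,
    node_degrees,
)
from oracles import (
    brute_force_betweenness,
    normal_equation_loglog_fit,
    random_connected_graph,
)


class TestBuildGraph:
    def test_all_edges_pass_threshold(self):
        g = build_graph([("A", "B", 0.9), ("B", "C", 0.8), ("A", "C", 0.75)], 0.7)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3

    def test_duplicate_rows_keep_max_confidence(self):
        g = build_graph([("A", "B", 0.9), ("A", "B", 0.6)], 0.7)
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["confidence"] == 0.9

    def test_reversed_duplicate_collapses(self):
        g = build_graph([("A", "B", 0.8), ("B", "A", 0.95)], 0.7)
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["confidence"] == 0.95

    def test_all_filtered_is_empty_graph_error(self):
        with pytest.raises(GraphInputError, match="empty graph"):
            build_graph([("A", "B", 0.65)], 0.7)

    def test_malformed_row_names_line(self):
        with pytest.raises(GraphInputError, match="row 2"):
            build_graph([("A", "B", 0.9), ("C", "not-a-number", "x")], 0.7)

    def test_self_loop_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="self-loop"):
            g = build_graph([("A", "A", 0.9), ("A", "B", 0.8)], 0.7)
        assert g.number_of_edges() == 1

    def test_string_integer_scale_autodetected(self):
        g = build_graph([("A", "B", 900), ("B", "C", 400)], 0.7)
        assert g.has_edge("A", "B") and not g.has_edge("B", "C")
        assert g["A"]["B"]["confidence"] == pytest.approx(0.9)


class TestDegrees:
    def test_triangle_all_degree_two(self):
        g = build_graph([("A", "B", 1), ("B", "C", 1), ("A", "C", 1)], 0.7)
        assert node_degrees(g) == {"A": 2, "B": 2, "C": 2}

    def test_star_and_isolated(self, star5):
        star5.add_node("X")
        deg = node_degrees(star5)
        assert deg["H"] == 4 and deg["L1"] == 1 and deg["X"] == 0


class TestBetweenness:
    def test_path_midpoint(self, path3):
        bc = betweenness_centrality(path3)
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_center(self, star5):
        bc = betweenness_centrality(star5)
        assert bc["H"] == pytest.approx(1.0)
        assert all(bc[v] == 0.0 for v in bc if v != "H")

    def test_five_cycle_each_mediates_one_pair_unit(self):
        # brute-force enumeration: each node lies inside exactly one of
        # the six normalized pair-units -> bc = 1/6
        g = nx.cycle_graph(5)
        oracle = brute_force_betweenness(g)
        bc = betweenness_centrality(g)
        for v in g.nodes:
            assert oracle[v] == pytest.approx(1 / 6)
            assert bc[v] == pytest.approx(oracle[v], abs=1e-12)

    def test_under_three_nodes_warns_and_zeroes(self):
        g = nx.Graph([("A", "B")])
        with pytest.warns(UserWarning):
            assert betweenness_centrality(g) == {"A": 0.0, "B": 0.0}

    def test_complete_graph_all_zero(self):
        bc = betweenness_centrality(nx.complete_graph(6))
        assert all(v == 0.0 for v in bc.values())

    def test_matches_brute_force_on_random_small_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            g = random_connected_graph(rng, n_max=8)
            bc = betweenness_centrality(g)
            oracle = brute_force_betweenness(g)
            for v in g.nodes:
                assert bc[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_disconnected_pairs_contribute_zero(self):
        g = nx.path_graph(["A", "B", "C"])
        g.add_edge("X", "Y")  # separate component
        bc = betweenness_centrality(g)
        oracle = brute_force_betweenness(g)
        for v in g.nodes:
            assert bc[v] == pytest.approx(oracle[v], abs=1e-12)
        # normalizer counts all 5 nodes: (4*3)/2 = 6 pairs
        assert bc["B"] == pytest.approx(1 / 6)

    def test_shortcut_edge_never_raises_mediator_bc(self):
        # adding an edge across a path cannot increase the bc of the
        # node it bypasses
        for n in range(4, 8):
            g = nx.path_graph(n)
            before = betweenness_centrality(g)
            g2 = g.copy()
            g2.add_edge(0, n - 1)
            after = betweenness_centrality(g2)
            for v in range(1, n - 1):
                assert after[v] <= before[v] + 1e-12

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_degree_sum_conservation_and_bc_range(self, seed):
        g = random_connected_graph(np.random.default_rng(seed))
        assert sum(node_degrees(g).values()) == 2 * g.number_of_edges()
        bc = betweenness_centrality(g)
        assert all(0.0 <= v <= 1.0 for v in bc.values())


class TestPowerLawFit:
    def test_exact_powerlaw_recovered(self):
        # counts proportional to d^-2 over d in {1,2,4,8}
        degrees = {}
        i = 0
        for d, c in [(1, 64), (2, 16), (4, 4), (8, 1)]:
            for _ in range(c):
                degrees[f"n{i}"] = d
                i += 1
        fit = fit_power_law(degrees)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.exponent_b == pytest.approx(-2.0)

    def test_uniform_degrees_error(self):
        with pytest.raises(GraphInputError, match="insufficient degree diversity"):
            fit_power_law({"a": 3, "b": 3, "c": 3})

    def test_matches_normal_equations_on_random_graph(self):
        g = nx.barabasi_albert_graph(200, 3, seed=5)
        degrees = dict(g.degree())
        fit = fit_power_law(degrees)
        a, b, r2 = normal_equation_loglog_fit(degrees)
        assert fit.coefficient_a == pytest.approx(a, abs=1e-9)
        assert fit.exponent_b == pytest.approx(b, abs=1e-9)
        assert fit.r_squared == pytest.approx(r2, abs=1e-9)
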