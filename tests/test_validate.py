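"""Leave-k-out deletion design, retention frequencies, and accuracy."""

import networkx as nx
import pytest

from conftest import TABLE2_ROWS
from hubnet.prioritize import compute_node_stats, rank_nodes
from hubnet.validate import (
    design_deletions,
    level_accuracy,
    overall_accuracy,
    retention_frequencies,
    run_test_network,
    run_validation,
)
from oracles import brute_force_betweenness

POOL = [f"N{i:02d}" for i in range(22)]
HUBS = POOL[:5]


class TestDesignDeletions:
    def test_default_design_has_97_networks(self):
        d = design_deletions(POOL, HUBS, seed=1)
        assert d.n_networks == 97
        assert len(d.levels[1]) == 22
        for k in (2, 3, 4):
            assert len(d.levels[k]) == 25

    def test_level_one_only_is_22(self):
        d = design_deletions(POOL, HUBS, levels=[1], seed=1)
        assert d.n_networks == 22
        assert all(len(s.nodes) == 1 for s in d.levels[1])
        assert {next(iter(s.nodes)) for s in d.levels[1]} == set(POOL)

    def test_level3_sets_have_three_members_one_designated_hub(self):
        d = design_deletions(POOL, HUBS, seed=3)
        for s in d.levels[3]:
            assert len(s.nodes) == 3
            assert s.designated_hub in HUBS
            assert s.designated_hub in s.nodes
            assert len(s.nodes & set(POOL)) == 3

    def test_each_hub_designated_in_repeats_slots_per_level(self):
        d = design_deletions(POOL, HUBS, repeats=5, seed=0)
        for k in (2, 3, 4):
            for h in HUBS:
                assert sum(s.designated_hub == h for s in d.levels[k]) == 5

    def test_same_seed_reproduces_design(self):
        d1 = design_deletions(POOL, HUBS, seed=11)
        d2 = design_deletions(POOL, HUBS, seed=11)
        assert d1.levels == d2.levels

    def test_hub_outside_pool_errors(self):
        with pytest.raises(ValueError, match="not in pool"):
            design_deletions(POOL, ["GHOST"], seed=0)

    def test_oversized_level_errors(self):
        with pytest.raises(ValueError):
            design_deletions(POOL[:3], POOL[:2], levels=[4], seed=0)


class TestRunTestNetwork:
    def _graph(self):
        g = nx.barabasi_albert_graph(30, 2, seed=9)
        return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})

    def test_deleting_isolated_node_keeps_top5(self):
        g = self._graph()
        g.add_node("ISO")
        base = rank_nodes(compute_node_stats(g))[:5]
        assert run_test_network(g, {"ISO"}) == base

    def test_deleted_hub_absent_from_top5(self):
        g = self._graph()
        top = rank_nodes(compute_node_stats(g))[0]
        assert top not in run_test_network(g, {top})

    def test_top5_matches_brute_force_recomputation(self):
        g = nx.relabel_nodes(
            nx.barabasi_albert_graph(12, 2, seed=4), lambda i: f"N{i:02d}"
        )
        deletion = {"N00", "N03"}
        got = run_test_network(g, deletion)
        h = g.copy()
        h.remove_nodes_from(deletion)
        bc = brute_force_betweenness(h)
        deg = dict(h.degree())
        expected = sorted(h.nodes, key=lambda v: (-bc[v], -deg[v], v))[:5]
        assert got == expected

    def test_too_few_remaining_nodes_errors(self):
        g = nx.path_graph([f"N{i}" for i in range(6)])
        with pytest.raises(ValueError, match="remain"):
            run_test_network(g, {"N0", "N1"})


class TestRetentionAndAccuracy:
    def test_hand_tally_fixture(self):
        hubs = ["A", "B", "C"]
        results = {
            1: [["A", "B", "X", "Y", "Z"], ["A", "C", "X", "Y", "Z"]],
            2: [["X", "Y", "Z", "W", "V"], ["A", "B", "C", "X", "Y"]],
        }
        t = retention_frequencies(results, hubs)
        assert t.frequencies.loc[1].tolist() == [2, 1, 1]
        assert t.frequencies.loc[2].tolist() == [1, 1, 1]
        assert t.n_networks == {1: 2, 2: 2}

    def test_full_retention_and_full_deletion(self):
        hubs = ["A"]
        t = retention_frequencies({1: [["A"] + list("WXYZ")] * 22}, hubs)
        assert t.frequencies.loc[1, "A"] == 22
        t0 = retention_frequencies({1: [list("VWXYZ")] * 22}, hubs)
        assert t0.frequencies.loc[1, "A"] == 0

    @pytest.mark.parametrize(
        "freqs,acc,n", [TABLE2_ROWS[k] for k in sorted(TABLE2_ROWS)]
    )
    def test_published_level_accuracies(self, freqs, acc, n):
        assert round(level_accuracy(freqs, n), 3) == acc

    def test_full_retention_accuracy_one(self):
        assert level_accuracy((25, 25, 25, 25, 25), 25) == 1.0

    def test_overall_accuracy_is_mean_of_levels_not_pooled(self):
        levels = [
            level_accuracy(freqs, n) for freqs, _, n in TABLE2_ROWS.values()
        ]
        overall = overall_accuracy(levels)
        assert round(overall, 3) == 0.776
        assert overall == pytest.approx(0.7763, abs=1e-4)  # printed precision
        total_freq = sum(sum(freqs) for freqs, _, _ in TABLE2_ROWS.values())
        total_nets = sum(n for _, _, n in TABLE2_ROWS.values())
        assert (total_freq, total_nets) == (374, 97)
        pooled = total_freq / (5 * total_nets)
        assert round(pooled, 3) == 0.771
        assert abs(overall - pooled) > 1e-3

    def test_single_level_identity(self):
        assert overall_accuracy([0.5]) == 0.5

    def test_accuracy_bounds(self):
        assert 0.0 <= level_accuracy((0, 0, 0, 0, 0), 10) <= 1.0
        with pytest.raises(ValueError):
            level_accuracy((11,), 10, n_hubs=1)
        with pytest.raises(ValueError):
            level_accuracy((1,), 0, n_hubs=1)


class TestRunValidation:
    def test_end_to_end_table_schema_and_determinism(self):
        from hubnet.simulate import NetworkSimConfig, simulate_ppi

        g, hubs = simulate_ppi(NetworkSimConfig(seed=5))
        t1, d1 = run_validation(g, hubs, seed=5)
        t2, _ = run_validation(g, hubs, seed=5)
        assert t1.equals(t2)
        assert list(t1.columns) == ["level", *hubs, "accuracy", "n_networks"]
        assert t1["level"].tolist() == ["1", "2", "3", "4", "Overall"]
        assert t1["n_networks"].tolist() == [22, 25, 25, 25, 97]
        accs = t1.loc[t1["level"] != "Overall", "accuracy"]
        assert ((accs >= 0) & (accs <= 1)).all()
        # a deleted hub cannot be retained: frequency bounded by the
        # number of sets not containing it
        for h in hubs:
            lvl1 = t1.loc[t1["level"] == "1", h].iloc[0]
            assert lvl1 <= 21

    def test_level1_accuracy_floor_with_strong_hubs(self):
        # each hub is absent from exactly one level-1 network, so a
        # perfectly robust network retains hubs in all other 21
        from hubnet.simulate import NetworkSimConfig, simulate_ppi

        g, hubs = simulate_ppi(NetworkSimConfig(seed=23))
        t, _ = run_validation(g, hubs, levels=[1], seed=23)
        acc = t.loc[t["level"] == "1", "accuracy"].iloc[0]
        assert acc >= (22 - 5) / 22
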