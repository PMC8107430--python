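"""Edge-list loading, interconnectivity statistics, and the permutation null."""

import dataclasses
import math

import numpy as np
import pytest

from pdgene.network import (
    CrossMode,
    EdgeListParseError,
    InteractionNetwork,
    PermutationConfig,
    Statistic,
    cross_set_stats,
    exact_within_pvalue,
    load_edge_list,
    permutation_test,
    sample_null_statistics,
    summarize_null,
    within_set_stats,
)


class TestLoadEdgeList:
    def test_confidence_filter_is_strict(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\t401\nA\tC\t400\nA\tD\t1000\n")
        net = load_edge_list(path)
        assert net.graph.has_edge("A", "B") and net.graph.has_edge("A", "D")
        assert "C" not in net.nodes
        assert net.confidence("A", "B") == pytest.approx(0.401)

    def test_duplicate_pair_stored_once(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\t500\nB\tA\t600\n")
        net = load_edge_list(path)
        assert net.n_edges == 1
        assert net.confidence("A", "B") == pytest.approx(0.6)  # keeps the higher

    def test_self_loop_dropped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tA\t900\nA\tB\t900\n")
        with caplog.at_level("WARNING", logger="pdgene.network"):
            net = load_edge_list(path)
        assert net.n_edges == 1
        assert "self-loop" in caplog.text

    def test_header_tolerated_and_bad_score_located(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("protein1\tprotein2\tcombined_score\nA\tB\t500\nA\tC\tbad\n")
        with pytest.raises(EdgeListParseError) as err:
            load_edge_list(path)
        assert err.value.row == 3

    def test_score_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\t1500\n")
        with pytest.raises(EdgeListParseError):
            load_edge_list(path)


class TestSetStatistics:
    def test_triangle(self):
        net = InteractionNetwork()
        for a, b in [("A", "B"), ("B", "C"), ("A", "C")]:
            net.add_edge(a, b, 0.9)
        assert within_set_stats(net, {"A", "B", "C"}) == (3, 3)

    def test_edges_leaving_the_set_do_not_count(self):
        net = InteractionNetwork()
        net.add_edge("A", "B", 0.9)
        assert within_set_stats(net, {"A", "C"}) == (0, 0)

    def test_five_node_manual_enumeration(self, five_node_net):
        # members {A,B,E}: edges A-B, B-E, A-E all inside -> 3 connected, 3 edges
        assert within_set_stats(five_node_net, {"A", "B", "E"}) == (3, 3)
        # members {A,C,D}: only C-D inside
        assert within_set_stats(five_node_net, {"A", "C", "D"}) == (2, 1)

    def test_genes_absent_from_network_contribute_nothing(self, five_node_net):
        assert within_set_stats(five_node_net, {"A", "B", "ZZZ"}) == (2, 1)

    def test_cross_basic(self):
        net = InteractionNetwork()
        net.add_edge("X", "Y", 0.9)
        assert cross_set_stats(net, {"X"}, {"Y"}) == (1, 1)
        assert cross_set_stats(net, {"X"}, {"Z"}) == (0, 0)

    def test_cross_manual_count(self):
        net = InteractionNetwork()
        net.add_edge("X1", "Y1", 0.9)
        net.add_edge("X2", "Y1", 0.9)
        net.add_node("Y2")
        assert cross_set_stats(net, {"X1", "X2"}, {"Y1", "Y2"}) == (1, 2)

    def test_overlapping_sets_rejected(self, five_node_net):
        with pytest.raises(ValueError, match="disjoint"):
            cross_set_stats(five_node_net, {"A", "B"}, {"B", "C"})


def grid_net(n=10, extra=()):
    """Path graph 0-1-...-(n-1) plus extra edges, nodes named N00.."""
    net = InteractionNetwork()
    names = [f"N{i:02d}" for i in range(n)]
    for a, b in zip(names, names[1:]):
        net.add_edge(a, b, 0.9)
    for i, j in extra:
        net.add_edge(names[i], names[j], 0.9)
    return net, names


class TestPermutationTest:
    def test_observed_zero_gives_p_one(self, five_node_net):
        five_node_net.add_node("Q")
        five_node_net.add_node("R")
        res = permutation_test(five_node_net, {"Q", "R"}, Statistic.WITHIN_EDGES,
                               PermutationConfig(n_permutations=500, seed=3))
        assert res.observed == 0
        assert res.p_empirical == 1.0
        assert not res.p_is_floor

    def test_add_one_estimator_and_floor_flag(self):
        null = np.array([0, 1, 2, 3, 4])
        res = summarize_null(Statistic.WITHIN_EDGES, 3, null, seed=0)
        assert res.n_null_geq == 2  # ties count toward r
        assert res.p_empirical == pytest.approx(3 / 6)
        assert not res.p_is_floor
        res = summarize_null(Statistic.WITHIN_EDGES, 10, null, seed=0)
        assert res.n_null_geq == 0 and res.p_is_floor
        assert res.p_empirical == pytest.approx(1 / 6)
        assert res.report() == "p < 2.0e-01"

    def test_deterministic_given_seed(self, five_node_net):
        cfg = PermutationConfig(n_permutations=2000, seed=11)
        a = permutation_test(five_node_net, {"A", "B", "E"}, Statistic.WITHIN_EDGES, cfg)
        b = permutation_test(five_node_net, {"A", "B", "E"}, Statistic.WITHIN_EDGES, cfg)
        assert a == b
        c = permutation_test(five_node_net, {"A", "B", "E"}, Statistic.WITHIN_EDGES,
                             dataclasses.replace(cfg, seed=12))
        assert c.p_empirical != a.p_empirical or c.n_null_geq != a.n_null_geq

    @pytest.mark.parametrize("statistic", [Statistic.WITHIN_EDGES,
                                           Statistic.WITHIN_CONNECTED])
    def test_monte_carlo_matches_exhaustive_enumeration(self, statistic):
        """On a 10-node universe the empirical p lands within 3 Monte-Carlo
        standard errors of the exact p from complete subset enumeration."""
        net, names = grid_net(10, extra=[(0, 5), (2, 7), (3, 9)])
        genes = {names[0], names[1], names[5]}
        n_perm = 40000
        res = permutation_test(net, genes, statistic,
                               PermutationConfig(n_permutations=n_perm, seed=5))
        exact = exact_within_pvalue(net, len(genes), res.observed, statistic)
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.p_empirical - exact) <= 3 * se + 1 / n_perm

    def test_six_node_universe_size_two(self):
        net, names = grid_net(6)
        genes = {names[2], names[3]}  # adjacent: observed 1 edge
        n_perm = 30000
        res = permutation_test(net, genes, Statistic.WITHIN_EDGES,
                               PermutationConfig(n_permutations=n_perm, seed=9))
        exact = exact_within_pvalue(net, 2, res.observed, Statistic.WITHIN_EDGES)
        assert exact == pytest.approx(5 / 15)  # 5 path edges of C(6,2)=15 pairs
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.p_empirical - exact) <= 3 * se + 1 / n_perm

    def test_planted_clique_hits_floor(self):
        net = InteractionNetwork()
        clique = [f"C{i}" for i in range(8)]
        for i in range(8):
            for j in range(i + 1, 8):
                net.add_edge(clique[i], clique[j], 0.9)
        for i in range(60):  # sparse background
            net.add_edge(f"B{i}", f"B{(i + 7) % 60}", 0.9)
        n_perm = 5000
        res = permutation_test(net, set(clique), Statistic.WITHIN_EDGES,
                               PermutationConfig(n_permutations=n_perm, seed=2))
        assert res.observed == 28
        assert res.p_is_floor
        assert res.p_empirical <= 1 / n_perm
        assert res.report() == "p < 2.0e-04"

    def test_cross_statistic_null_and_modes(self, five_node_net):
        cfg = PermutationConfig(n_permutations=1000, seed=4)
        res = permutation_test(five_node_net, ({"A", "B"}, {"D", "E"}),
                               Statistic.CROSS_EDGES, cfg)
        assert res.observed == 2  # D-E? no: A-E and B-E cross; D-E is within B set
        fixed = dataclasses.replace(cfg, cross_mode=CrossMode.FIX_A_RESAMPLE_B)
        res2 = permutation_test(five_node_net, ({"A", "B"}, {"D", "E"}),
                                Statistic.CROSS_CONNECTED, fixed)
        assert 0 < res2.p_empirical <= 1

    def test_set_larger_than_universe_rejected(self, five_node_net):
        with pytest.raises(ValueError, match="universe"):
            permutation_test(five_node_net, set("ABCDE"), Statistic.WITHIN_EDGES,
                             PermutationConfig(n_permutations=10, seed=0,
                                               universe=["A", "B", "C"]))

    def test_statistic_set_mismatch_rejected(self, five_node_net):
        with pytest.raises(ValueError, match="pair"):
            permutation_test(five_node_net, {"A", "B"}, Statistic.CROSS_EDGES,
                             PermutationConfig(n_permutations=10, seed=0))

    def test_relabeling_nodes_preserves_null_distribution(self):
        """Exchangeability: permuting node labels leaves the exact null
        tail probability unchanged (it depends only on graph structure)."""
        net, names = grid_net(9, extra=[(0, 4)])
        relabeled = InteractionNetwork()
        perm = {name: f"Z{8 - i}" for i, name in enumerate(names)}
        for a, b in net.graph.edges:
            relabeled.add_edge(perm[a], perm[b], 0.9)
        for observed in (1, 2, 3):
            p1 = exact_within_pvalue(net, 3, observed, Statistic.WITHIN_EDGES)
            p2 = exact_within_pvalue(relabeled, 3, observed, Statistic.WITHIN_EDGES)
            assert p1 == pytest.approx(p2)


def test_custom_universe_restricts_sampling(five_node_net):
    # universe {A,B,E} forms a triangle: every size-3 draw has 3 edges
    cfg = PermutationConfig(n_permutations=200, seed=1, universe=["A", "B", "E"])
    null = sample_null_statistics(five_node_net, Statistic.WITHIN_EDGES, (3,), cfg)
    assert set(null.tolist()) == {3}
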