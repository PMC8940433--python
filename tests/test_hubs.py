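"""Median-threshold hub screen and MCODE complex detection."""

import networkx as nx
import numpy as np
import pytest

from netpharm import hubs, ppi
from netpharm.errors import EmptyNetworkError, NetpharmError, NoModuleError
from netpharm.hubs import MCODEParams, ScreenThresholds
from netpharm.synthetic import FixtureConfig, gen_ppi_edges


def named(graph, prefix="v"):
    return nx.relabel_nodes(graph, {i: f"{prefix}{i}" for i in graph.nodes})


class TestMedianThreshold:
    def test_hand_example(self):
        values = dict(zip("abcdefg", [1, 1, 2, 3, 5, 8, 9]))
        kept = hubs.median_threshold_nodes(values, multiplier=2, strict=True)
        assert kept == {"f", "g"}  # median 3, cutoff 6

    def test_all_equal_strict_empty(self):
        assert hubs.median_threshold_nodes({"a": 4, "b": 4}, 1.0, strict=True) == set()

    def test_multiplier_zero_inclusive_keeps_all(self):
        values = {"a": 1.0, "b": 2.0}
        assert hubs.median_threshold_nodes(values, 0.0, strict=False) == {"a", "b"}

    def test_empty_input_rejected(self):
        with pytest.raises(NetpharmError):
            hubs.median_threshold_nodes({}, 2.0)

    def test_even_count_uses_midpoint_median(self):
        # median of {1,2,3,4} is 2.5; cutoff 5 -> nothing strictly above except none
        kept = hubs.median_threshold_nodes(dict(zip("abcd", [1, 2, 3, 4])), 2.0, True)
        assert kept == set()


class TestPreliminaryHub:
    def test_star_center_alone_is_signaled_empty(self):
        g = nx.star_graph(6)  # degrees {6, 1x6}; median 1, cutoff 2
        with pytest.raises(EmptyNetworkError):
            hubs.preliminary_hub(named(g))

    def test_complete_graph_strict_empty(self):
        with pytest.raises(EmptyNetworkError):
            hubs.preliminary_hub(named(nx.complete_graph(5)))

    def test_planted_module_contained_at_density_contrast(self):
        cfg = FixtureConfig(
            seed=5,
            gene_universe_size=100,
            background_edge_prob=0.02,
            planted_modules=[(8, 1.0)],
            edge_score_range=(700.0, 1000.0),
        )
        from netpharm.synthetic import gene_universe

        edges, modules = gen_ppi_edges(gene_universe(cfg), cfg)
        net = ppi.build_network(edges, min_score=0.0).graph
        prelim, _ = hubs.preliminary_hub(net)
        assert set(modules[0]) <= set(prelim.nodes)


class TestScreenHubs:
    @staticmethod
    def clique_with_chains():
        # K6 with a three-node chain hanging off each clique node; the chain
        # periphery keeps the preliminary hub heterogeneous (and, attaching to
        # low-degree nodes, leaves the clique dominant even on NC)
        g = nx.Graph()
        clique = [f"c{i}" for i in range(6)]
        g.add_edges_from((a, b) for i, a in enumerate(clique) for b in clique[i + 1:])
        for i, c in enumerate(clique):
            g.add_edge(c, f"p{i}")
            g.add_edge(f"p{i}", f"q{i}")
            g.add_edge(f"q{i}", f"r{i}")
        return g, clique

    def test_vertex_transitive_prelim_gives_empty_hub(self):
        # a preliminary hub that is exactly the K6 has all-equal metrics,
        # so nothing strictly exceeds any median
        g, _ = self.clique_with_chains()
        with pytest.raises(EmptyNetworkError):
            hubs.screen_hubs(g, ScreenThresholds(strict=True, degree_multiplier=1.0))

    def test_inclusive_mode_keeps_equal_valued_nodes(self):
        g = named(nx.complete_graph(8))
        result = hubs.screen_hubs(g, ScreenThresholds(strict=False, degree_multiplier=1.0))
        assert set(result.hub.nodes) == set(g.nodes)

    def test_dominant_clique_survives_all_six(self):
        # degree > 0.5×median keeps the clique plus the first pendant of each
        # chain, so stage 2 compares clique against periphery and keeps the clique
        g, clique = self.clique_with_chains()
        result = hubs.screen_hubs(g, ScreenThresholds(degree_multiplier=0.5, strict=True))
        assert set(result.hub.nodes) == set(clique)
        assert set(result.hub.nodes) <= set(result.preliminary_hub.nodes) <= set(g.nodes)
        assert set(result.per_metric_medians) == set(ppi.METRIC_NAMES)

    def test_medians_recorded_match_recount(self):
        g, _ = self.clique_with_chains()
        result = hubs.screen_hubs(g, ScreenThresholds(degree_multiplier=0.5))
        table = ppi.centrality_table(result.preliminary_hub)
        for m in ppi.METRIC_NAMES:
            assert result.per_metric_medians[m] == pytest.approx(float(table[m].median()))


class TestMCODEWeights:
    def test_k4_weight_three_everywhere(self, k4):
        assert all(w == pytest.approx(3.0) for w in hubs.mcode_vertex_weights(k4).values())

    def test_star_center_weight_half(self, star4):
        w = hubs.mcode_vertex_weights(star4)
        assert w["c"] == pytest.approx(0.5)  # 1-core of the star, density 3/6

    def test_single_edge_weight_one(self):
        g = nx.Graph([("a", "b")])
        assert hubs.mcode_vertex_weights(g) == {"a": 1.0, "b": 1.0}


class TestMCODEComplexes:
    def test_k5_and_k3_ranked_by_score(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(3))
        clusters = hubs.mcode_find_complexes(named(g))
        assert [c.score for c in clusters] == [5.0, 3.0]
        assert clusters[0].n == 5 and clusters[1].n == 3
        assert clusters[0].density == 1.0

    def test_haircut_removes_pendant_from_k4(self, k4):
        g = k4.copy()
        g.add_edge("v0", "pend")
        top = hubs.mcode_find_complexes(g, MCODEParams(node_score_cutoff=1.0))[0]
        assert set(top.nodes) == {"v0", "v1", "v2", "v3"}

    def test_empty_edge_graph_yields_no_clusters(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        assert hubs.mcode_find_complexes(g) == []

    def test_score_is_density_times_n(self):
        g = nx.gnp_random_graph(30, 0.3, seed=8)
        for c in hubs.mcode_find_complexes(named(g)):
            sub = g.subgraph(int(v[1:]) for v in c.nodes)
            n, e = sub.number_of_nodes(), sub.number_of_edges()
            dens = 2 * e / (n * (n - 1))
            assert abs(c.score - dens * n) < 1e-12

    def test_deterministic_under_insertion_order(self):
        base = nx.gnp_random_graph(25, 0.25, seed=4)
        base = named(base)
        shuffled = nx.Graph()
        rng = np.random.default_rng(0)
        edges = list(base.edges)
        rng.shuffle(edges)
        shuffled.add_edges_from(edges)
        shuffled.add_nodes_from(base.nodes)
        a = hubs.mcode_find_complexes(base)
        b = hubs.mcode_find_complexes(shuffled)
        assert [c.nodes for c in a] == [c.nodes for c in b]
        assert [c.score for c in a] == [c.score for c in b]

    def test_key_module_is_top_cluster_sorted(self):
        g = named(nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(3)))
        clusters = hubs.mcode_find_complexes(g)
        assert hubs.key_module(clusters) == sorted(clusters[0].nodes)
        with pytest.raises(NoModuleError):
            hubs.key_module([])


class TestPlantedRecovery:
    def test_planted_k8_recovered_and_nesting_holds(self):
        """Scaled-down recovery check; the full 50-replicate version runs in
        the acceptance suite."""
        hits = 0
        for seed in range(10):
            cfg = FixtureConfig(
                seed=seed,
                gene_universe_size=100,
                background_edge_prob=0.05,
                planted_modules=[(8, 1.0)],
            )
            from netpharm.synthetic import gene_universe

            edges, modules = gen_ppi_edges(gene_universe(cfg), cfg)
            net = ppi.build_network(edges, min_score=0.0).graph
            clusters = hubs.mcode_find_complexes(net)
            if set(hubs.key_module(clusters)) == set(modules[0]):
                hits += 1
            try:
                result = hubs.screen_hubs(net)
                key = set(hubs.key_module(hubs.mcode_find_complexes(result.hub)))
                assert key <= set(result.hub.nodes) <= set(
                    result.preliminary_hub.nodes
                ) <= set(net.nodes)
            except (EmptyNetworkError, NoModuleError):
                pass  # an empty screen is a legitimate, signaled outcome
        assert hits >= 8
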