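"""Graph metrics against brute-force oracles; core extraction; hub removal."""

import math

import networkx as nx
import numpy as np
import pytest

from conftest import random_graph
from coexnet import (
    ConfigurationError,
    CoreParams,
    UndefinedMetricError,
    betweenness,
    characteristic_path_length,
    clustering_coefficients,
    connected_components,
    extract_core,
    fixture_graph,
    hub_removal,
    paper_diameter,
    topology_profile,
)
from oracles import (
    brute_betweenness,
    brute_clustering,
    brute_components,
    brute_cpl,
)


class TestMetricOracles:
    def test_all_metrics_match_brute_force_on_200_random_graphs(self):
        """Betweenness, clustering, CPL and components agree exactly with
        exhaustive enumeration oracles on 200 seeded random graphs of
        <= 12 nodes."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            g = random_graph(rng, n_max=12)
            nodes = sorted(g.nodes())
            edges = list(g.edges())

            btw = betweenness(g)
            expected_btw = brute_betweenness(nodes, edges)
            for v in nodes:
                assert btw[v] == pytest.approx(expected_btw[v], abs=1e-9)

            cc, _ = clustering_coefficients(g)
            expected_cc = brute_clustering(nodes, edges)
            for v in nodes:
                assert cc[v] == pytest.approx(expected_cc[v], abs=1e-12)

            comps = connected_components(g)
            assert sorted(map(sorted, comps)) == sorted(
                map(sorted, brute_components(nodes, edges))
            )

            expected_cpl, expected_excl = brute_cpl(nodes, edges)
            if math.isnan(expected_cpl):
                with pytest.raises(UndefinedMetricError):
                    characteristic_path_length(g)
            else:
                cpl, excl = characteristic_path_length(g)
                assert cpl == pytest.approx(expected_cpl, abs=1e-12)
                assert excl == expected_excl

    def test_betweenness_aggregate_matches_oracle_sum(self):
        """Total betweenness equals the oracle's aggregate count of
        intermediate-vertex incidences over all shortest paths."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = random_graph(rng, n_max=10)
            ours = sum(betweenness(g).values())
            oracle = sum(brute_betweenness(sorted(g), list(g.edges())).values())
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_closed_forms(self):
        # path P3: middle node 1.0, endpoints 0
        p3 = fixture_graph("path", n=3)
        assert betweenness(p3) == {0: 0.0, 1: 1.0, 2: 0.0}
        # star center: C(k,2)
        star = fixture_graph("star", n=5)
        assert betweenness(star)[0] == pytest.approx(6.0)
        # complete graph CPL = 1
        k6 = fixture_graph("complete", n=6)
        assert characteristic_path_length(k6)[0] == pytest.approx(1.0)
        # path P4 CPL = 10/6
        p4 = fixture_graph("path", n=4)
        assert characteristic_path_length(p4)[0] == pytest.approx(10 / 6)
        assert paper_diameter(p4) == pytest.approx(10 / 6)
        # triangle clustering 1.0 everywhere; star 0.0 everywhere
        tri = fixture_graph("cycle", n=3)
        assert all(v == 1.0 for v in clustering_coefficients(tri)[0].values())
        assert all(v == 0.0 for v in clustering_coefficients(star)[0].values())

    def test_component_counts(self):
        g = nx.Graph()
        g.add_nodes_from(range(5))
        assert len(connected_components(g)) == 5
        assert len(connected_components(fixture_graph("cycle", n=9))) == 1


class TestTopologyProfile:
    def test_graph_level_summaries(self):
        g = fixture_graph("two_cliques", n1=4, n2=4, bridge=1)
        prof = topology_profile(g)
        assert prof.n_nodes == 8
        assert prof.n_edges == 13
        assert prof.avg_degree == pytest.approx(2 * 13 / 8)
        assert prof.n_connected_components == 1
        # leaves/low-degree checks: betweenness >= 0 everywhere
        assert (prof.per_node["betweenness"] >= 0).all()

    def test_disconnected_pairs_reported(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (2, 3)])
        prof = topology_profile(g)
        assert prof.disconnected_pairs == 4  # pairs across the 2 components
        assert prof.characteristic_path_length == pytest.approx(1.0)


class TestExtractCore:
    def test_zero_threshold_excludes_leaves(self):
        # star leaves have betweenness 0 -> never pass any log threshold
        star = fixture_graph("star", n=6)
        core, hubs = extract_core(star, CoreParams(0.0, 0))
        assert set(core.nodes()) == {0}
        assert hubs == {0}  # degree 5 > 0

    def test_toy_membership_matches_manual_filter(self):
        """Brute-force betweenness drives the same membership decision."""
        g = fixture_graph("two_cliques", n1=6, n2=6, bridge=1)
        params = CoreParams(1.0, 4)
        core, hubs = extract_core(g, params)
        oracle_btw = brute_betweenness(sorted(g), list(g.edges()))
        expected = {v for v, b in oracle_btw.items()
                    if b > 0 and math.log(b) > 1.0}
        assert set(core.nodes()) == expected
        assert hubs == {v for v in expected if g.degree(v) > 4}

    def test_default_params(self):
        p = CoreParams()
        assert p.log_betweenness_threshold == 6.0
        assert p.degree_threshold == 15
        assert p.log_base == "natural"

    def test_invalid_log_base(self):
        with pytest.raises(ConfigurationError):
            CoreParams(log_base="e^2")


class TestHubRemoval:
    def test_k_too_large_rejected(self):
        g = fixture_graph("cycle", n=5)
        with pytest.raises(ConfigurationError):
            hub_removal(g, k=5)

    def test_trajectory_shape_and_intact_start(self):
        g = fixture_graph("preferential_attachment", n=60, m=2, seed=0)
        traj = hub_removal(g, k=10, mode="targeted")
        assert len(traj.steps) == 11  # intact graph + 10 removals
        assert traj.steps["n_removed"].iloc[0] == 0
        assert len(traj.removal_order) == 10

    def test_targeted_removes_by_original_degree(self):
        g = fixture_graph("preferential_attachment", n=50, m=2, seed=1)
        degs = dict(g.degree())
        traj = hub_removal(g, k=5, mode="targeted")
        expected = [v for v, _ in sorted(
            degs.items(), key=lambda kv: (-kv[1], str(kv[0])))][:5]
        assert traj.removal_order == expected

    def test_random_mode_seeded(self):
        g = fixture_graph("erdos_renyi", n=40, mean_degree=5, seed=2)
        a = hub_removal(g, k=8, mode="random", seed=5)
        b = hub_removal(g, k=8, mode="random", seed=5)
        assert a.removal_order == b.removal_order

    def test_removing_almost_everything_yields_undefined_cpl(self):
        g = fixture_graph("path", n=5)
        traj = hub_removal(g, k=4, mode="targeted")
        assert math.isnan(
            traj.steps["characteristic_path_length"].iloc[-1]
        )

    def test_targeted_attack_hurts_more_than_random(self):
        """Attack tolerance of heavy-tailed graphs: removing the top-degree
        hubs stretches (or shatters) paths at least as much as random
        removal in >= 95% of paired runs."""
        wins = 0
        n_pairs = 20
        for seed in range(n_pairs):
            g = fixture_graph("preferential_attachment", n=500, m=2,
                              seed=seed)
            targ = hub_removal(g, k=50, mode="targeted",
                               recompute_metrics_every=50)
            rand = hub_removal(g, k=50, mode="random", seed=seed + 1000,
                               recompute_metrics_every=50)
            t_cpl = targ.steps["characteristic_path_length"].iloc[-1]
            r_cpl = rand.steps["characteristic_path_length"].iloc[-1]
            wins += t_cpl >= r_cpl
        assert wins / n_pairs >= 0.95

    def test_targeted_never_decreases_components_on_scale_free(self):
        g = fixture_graph("preferential_attachment", n=200, m=2, seed=3)
        traj = hub_removal(g, k=30, mode="targeted")
        comps = traj.steps["n_components"].to_numpy()
        assert (np.diff(comps) >= 0).all()
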