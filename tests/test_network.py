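"""Pearson matrix, thresholded network construction, degree-law fit,
precision and the threshold sweep."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexnet import (
    ConfigurationError,
    DegenerateDistributionError,
    GeneSetCollection,
    InsufficientDataError,
    NetworkConfig,
    UndefinedMetricError,
    build_network,
    degree_distribution_fit,
    fixture_graph,
    network_precision,
    non_isolated_nodes,
    pearson_matrix,
    threshold_sweep,
)
from oracles import pearson_sigma_formula


def _expr(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes,
                        columns=[f"s{j}" for j in range(values.shape[1])])


class TestPearsonMatrix:
    def test_diagonal_is_one_and_symmetric(self):
        rng = np.random.default_rng(0)
        corr, excluded = pearson_matrix(_expr(rng.normal(size=(6, 10))))
        assert excluded == []
        np.testing.assert_array_equal(np.diag(corr.values), 1.0)
        np.testing.assert_allclose(corr.values, corr.values.T)
        assert np.all(np.abs(corr.values) <= 1.0)

    def test_perfect_anticorrelation(self):
        corr, _ = pearson_matrix(_expr([[1, 2, 3, 4], [4, 3, 2, 1]]))
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_sigma_formula_oracle(self):
        """100 random 10x8 matrices agree with the two-pass textbook
        formula to 1e-12."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            x = rng.normal(size=(10, 8))
            corr, _ = pearson_matrix(_expr(x))
            for i in range(10):
                for j in range(i + 1, 10):
                    expected = pearson_sigma_formula(x[i], x[j])
                    assert corr.iloc[i, j] == pytest.approx(expected,
                                                            abs=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            pearson_matrix(_expr([[1, 2], [2, 1]]))

    def test_zero_variance_genes_reported_and_excluded(self):
        x = np.vstack([np.ones(8), np.random.default_rng(1).normal(size=(3, 8))])
        corr, excluded = pearson_matrix(_expr(x))
        assert excluded == ["g0"]
        assert "g0" not in corr.index


class TestBuildNetwork:
    def test_tau_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            NetworkConfig(pcc_threshold=1.0001)
        with pytest.raises(ConfigurationError):
            NetworkConfig(pcc_threshold=0.0)

    def test_tau_one_keeps_only_collinear_pairs(self):
        x = np.array([[1.0, 2, 3, 4], [2.0, 4, 6, 8], [4.0, 3, 2, 1],
                      [1.0, 5, 2, 7]])
        net = build_network(_expr(x), NetworkConfig(pcc_threshold=1.0))
        assert set(map(frozenset, net.edges())) == {frozenset(("g0", "g1"))}

    def test_absolute_mode_includes_negative_edges(self):
        x = np.array([[1.0, 2, 3, 4], [4.0, 3, 2, 1]])
        pos = build_network(_expr(x), NetworkConfig(0.9))
        ab = build_network(_expr(x), NetworkConfig(0.9, use_absolute_pcc=True))
        assert pos.number_of_edges() == 0
        assert ab.number_of_edges() == 1

    def test_planted_modules_recovered_background_suppressed(self, planted_triple):
        """tau=0.70: >= 80% of within-module pairs are edges, <= 0.1% of
        background pairs are."""
        _, datasets, module_map = planted_triple
        net = build_network(datasets[0], NetworkConfig(0.70))
        modules: dict[str, set] = {}
        for g, m in module_map.items():
            if m.startswith("shared_") or m.startswith("ds0_"):
                modules.setdefault(m, set()).add(g)
        within_hits = within_tot = 0
        for genes in modules.values():
            gl = sorted(genes)
            for i in range(len(gl)):
                for j in range(i + 1, len(gl)):
                    within_tot += 1
                    within_hits += net.has_edge(gl[i], gl[j])
        assert within_hits / within_tot >= 0.80
        module_genes = set().union(*modules.values())
        bg_edges = sum(
            1 for u, v in net.edges()
            if u not in module_genes and v not in module_genes
        )
        n_bg = len(net) - len(module_genes)
        assert bg_edges / (n_bg * (n_bg - 1) / 2) <= 1e-3

    def test_isolated_nodes_kept_but_flagged(self, planted_triple):
        _, datasets, _ = planted_triple
        net = build_network(datasets[0], NetworkConfig(0.70))
        active = non_isolated_nodes(net)
        assert len(active) < net.number_of_nodes()
        assert all(net.degree(n) > 0 for n in active)

    def test_edge_weights_carry_pcc_at_least_tau(self, planted_triple):
        _, datasets, _ = planted_triple
        net = build_network(datasets[0], NetworkConfig(0.70))
        assert net.number_of_edges() > 0
        assert all(w >= 0.70 for _, _, w in net.edges(data="weight"))


class TestDegreeDistributionFit:
    def test_preferential_attachment_heavy_tail(self):
        """Growth-model graphs: steep negative log-log slope, decent R^2
        (Monte-Carlo over 10 seeds)."""
        slopes, r2s = [], []
        for seed in range(10):
            g = fixture_graph("preferential_attachment", n=2000, m=3,
                              seed=seed)
            fit = degree_distribution_fit(g)
            slopes.append(fit["slope"])
            r2s.append(fit["r_squared"])
        assert -3.5 <= np.mean(slopes) <= -1.5
        assert np.mean(r2s) >= 0.7

    def test_complete_graph_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            degree_distribution_fit(nx.complete_graph(10))

    def test_heavy_tail_fits_better_than_poisson(self):
        """Paired comparison: the log-log fit is tighter on a
        preferential-attachment graph than on an Erdos-Renyi graph of the
        same size (Poisson degrees are not a power law)."""
        wins = 0
        for seed in range(10):
            ba = fixture_graph("preferential_attachment", n=2000, m=5,
                               seed=seed)
            er = fixture_graph("erdos_renyi", n=2000, mean_degree=10,
                               seed=seed)
            wins += (degree_distribution_fit(ba)["r_squared"]
                     > degree_distribution_fit(er)["r_squared"])
        assert wins >= 8


class TestNetworkPrecision:
    def _net(self, n=10):
        g = nx.path_graph(n)
        return nx.relabel_nodes(g, {i: f"g{i}" for i in range(n)})

    def test_all_annotated(self):
        net = self._net()
        annot = GeneSetCollection(terms={"T": frozenset(net.nodes())})
        assert network_precision(net, annot) == 1.0

    def test_none_annotated(self):
        net = self._net()
        annot = GeneSetCollection(terms={"T": frozenset(["other"])})
        assert network_precision(net, annot) == 0.0

    def test_fractional_counting(self):
        net = self._net(100)
        annotated = frozenset(f"g{i}" for i in range(31))
        annot = GeneSetCollection(terms={"T": annotated})
        assert network_precision(net, annot) == pytest.approx(0.31)

    def test_empty_network_undefined(self):
        with pytest.raises(UndefinedMetricError):
            network_precision(nx.Graph(), GeneSetCollection(
                terms={"T": frozenset(["x"])}))

    def test_invariant_to_edge_structure(self):
        annot = GeneSetCollection(
            terms={"T": frozenset(f"g{i}" for i in range(5))})
        path = self._net(10)
        dense = nx.relabel_nodes(nx.complete_graph(10),
                                 {i: f"g{i}" for i in range(10)})
        assert network_precision(path, annot) == network_precision(dense, annot)


class TestThresholdSweep:
    def test_empty_grid_rejected(self, planted_triple):
        with pytest.raises(ConfigurationError):
            threshold_sweep(planted_triple[1][0], [])

    def test_counts_non_increasing_in_tau(self, planted_triple):
        """Nesting: raising tau can only remove genes and edges."""
        _, datasets, _ = planted_triple
        grid = [0.70, 0.76, 0.82, 0.88]
        table = threshold_sweep(datasets[0], grid)
        assert list(table["tau"]) == grid
        assert (table["n_edges"].diff().dropna() <= 0).all()
        assert (table["n_genes"].diff().dropna() <= 0).all()

    def test_nested_edge_sets(self, planted_triple):
        _, datasets, _ = planted_triple
        lo = build_network(datasets[0], NetworkConfig(0.70))
        hi = build_network(datasets[0], NetworkConfig(0.85))
        hi_edges = set(map(frozenset, hi.edges()))
        lo_edges = set(map(frozenset, lo.edges()))
        assert hi_edges <= lo_edges

    def test_sweep_from_weighted_network_matches_rebuild(self, planted_triple):
        _, datasets, _ = planted_triple
        base = build_network(datasets[0], NetworkConfig(0.70))
        from_net = threshold_sweep(base, [0.70, 0.80])
        from_expr = threshold_sweep(datasets[0], [0.70, 0.80])
        pd.testing.assert_frame_equal(from_net, from_expr)

    def test_precision_non_decreasing_and_fragmentation(self, planted_triple):
        """On planted data, module-term precision grows (or holds) with tau
        while the graph eventually fragments into more components."""
        from coexnet import matched_gene_sets

        _, datasets, module_map = planted_triple
        annot = matched_gene_sets(module_map, 0, (5, 10), seed=0)
        grid = [0.70, 0.76, 0.82, 0.88]
        table = threshold_sweep(datasets[0], grid, annot=annot)
        prec = table["precision"].to_numpy()
        assert (np.diff(prec) >= -1e-12).all()
        # fragmentation: once tau cuts into module edges the surviving
        # subgraph splits into more components than the tau=0.70 baseline
        wide = threshold_sweep(datasets[0], [0.70, 0.80, 0.90, 0.93])
        assert wide["n_components"].max() > wide["n_components"].iloc[0]
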