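"""Network inference: correlation, modules, glasso support, penalty selection,
Granger orientation."""

import networkx as nx
import numpy as np
import pytest

from weaknodes.netinfer import (GlassoConfig, TimeSeriesPanel,
                                compute_correlation, detect_modules,
                                infer_interactions, orient_links,
                                select_penalty)
from weaknodes.network import BrainNetwork
from weaknodes.synthgen import (GroundTruth, sample_gaussian_series,
                                sample_var_series)


def panel_from(values, **kw):
    values = np.asarray(values, dtype=float)
    return TimeSeriesPanel(values, list(range(values.shape[0])), **kw)


class TestPanelValidation:
    def test_constant_row_rejected_with_ids(self):
        vals = np.vstack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match=r"\[1\]"):
            panel_from(vals)

    def test_non_finite_rejected(self):
        vals = np.ones((2, 4)) * np.nan
        with pytest.raises(ValueError, match="finite"):
            panel_from(vals)


class TestCorrelation:
    def test_unit_diagonal_and_antisymmetry(self):
        x = np.arange(6.0)
        c = compute_correlation(panel_from(np.vstack([x, -x + 0.5])))
        assert c.r[0, 0] == pytest.approx(1.0)
        assert c.r[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        # direct formula on these 4 points
        expected = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        c = compute_correlation(panel_from(np.vstack([x, y])))
        assert c.r[0, 1] == pytest.approx(expected)
        assert expected == pytest.approx(0.9827076298239908)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((5, 40))
        scaled = vals * rng.uniform(0.5, 3.0, size=(5, 1)) \
            + rng.normal(size=(5, 1))
        a = compute_correlation(panel_from(vals)).r
        b = compute_correlation(panel_from(scaled)).r
        assert np.allclose(a, b, atol=1e-10)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            compute_correlation(panel_from(np.random.default_rng(1)
                                           .standard_normal((3, 2))))


class TestDetectModules:
    def test_two_perfect_blocks(self):
        t = np.arange(12.0)
        # two blocks of perfectly correlated nodes, independent across blocks
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal((2, 12))
        vals = np.vstack([a, 2 * a + 1, 3 * a, b, -b, b + 4])
        part = detect_modules(compute_correlation(panel_from(vals)), 0.5)
        labs = [part.labels[i] for i in range(6)]
        assert labs[0] == labs[1] == labs[2]
        assert labs[3] == labs[4] == labs[5]
        assert labs[0] != labs[3]

    def test_all_correlated_single_module(self):
        a = np.arange(10.0)
        vals = np.vstack([a, 2 * a, a + 3])
        part = detect_modules(compute_correlation(panel_from(vals)), 0.5)
        assert part.n_modules() == 1

    def test_edgeless_binarization_warns_and_isolates(self):
        rng = np.random.default_rng(8)
        vals = rng.standard_normal((4, 2000))
        with pytest.warns(UserWarning, match="edgeless"):
            part = detect_modules(compute_correlation(panel_from(vals)), 0.99)
        assert part.n_modules() == 4

    def test_recovers_planted_modules(self, example3_truth):
        """Thresholded-correlation communities match the planted partition."""
        from sklearn.metrics import adjusted_rand_score

        gt = example3_truth
        x = sample_gaussian_series(gt.precision, 5000, 0.1, seed=21)
        panel = TimeSeriesPanel(x, sorted(gt.graph.nodes))
        part = detect_modules(compute_correlation(panel), threshold=0.08)
        truth = [gt.network.modules[v] for v in panel.node_ids]
        pred = [part.labels[v] for v in panel.node_ids]
        assert adjusted_rand_score(truth, pred) >= 0.9


class TestInferInteractions:
    def test_identity_covariance_gives_edgeless_network(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((4, 20000))
        net = infer_interactions(panel_from(vals), GlassoConfig(penalty=0.05))
        assert net.n_edges == 0

    def test_large_penalty_full_shrinkage(self):
        gt = GroundTruth.from_edges(4, [(0, 1), (1, 2), (2, 3)])
        from weaknodes.synthgen import build_precision
        x = sample_gaussian_series(build_precision(gt, 0.4), 5000, 0.0, seed=1)
        net = infer_interactions(panel_from(x), GlassoConfig(penalty=1.0))
        assert net.n_edges == 0

    def test_zero_penalty_matches_direct_inversion(self):
        """At rho=0 the support equals the inverted empirical covariance's."""
        gt = GroundTruth.from_edges(4, [(0, 1), (1, 2), (2, 3)])
        from weaknodes.synthgen import build_precision
        prec = build_precision(gt, 0.45)
        x = sample_gaussian_series(prec, 50000, 0.0, seed=3)
        corr = np.corrcoef(x)
        inv = np.linalg.inv(corr)  # dense inversion oracle
        floor = 1e-8 * np.abs(np.diag(inv)).max()
        oracle_support = {(i, j) for i in range(4) for j in range(i + 1, 4)
                          if abs(inv[i, j]) > floor}
        net = infer_interactions(panel_from(x), GlassoConfig(penalty=0.0))
        est = {tuple(sorted(e)) for e in net.graph.edges}
        assert est == oracle_support

    def test_edge_count_nonincreasing_in_penalty(self):
        gt = GroundTruth.from_edges(6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5),
                                        (0, 3)])
        from weaknodes.synthgen import build_precision
        x = sample_gaussian_series(build_precision(gt, 0.4), 4000, 0.1, seed=9)
        panel = panel_from(x)
        counts = [infer_interactions(panel, GlassoConfig(penalty=r)).n_edges
                  for r in np.geomspace(1e-3, 1.0, 12)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSelectPenalty:
    def test_two_node_pair_keeps_single_edge(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(4000)
        vals = np.vstack([a, 0.8 * a + 0.6 * rng.standard_normal(4000)])
        rho, net = select_penalty(panel_from(vals), GlassoConfig(grid_size=20))
        assert set(map(tuple, map(sorted, net.graph.edges))) == {(0, 1)}
        # one resolution step denser than rho* must break connectivity
        from weaknodes.netinfer import _glasso_support
        corr = compute_correlation(panel_from(vals)).r
        sup_hi = _glasso_support(corr, GlassoConfig(), rho * 1.05)
        assert not nx.is_connected(nx.from_numpy_array(sup_hi.astype(int)))

    def test_uncorrelated_nodes_never_connected(self):
        # exactly orthogonal (decorrelated) series: identity empirical
        # correlation, so no penalty yields a spanning component
        rng = np.random.default_rng(6)
        raw = rng.standard_normal((50, 5))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        with pytest.raises(RuntimeError, match="no spanning component"):
            select_penalty(panel_from(q.T), GlassoConfig(grid_size=15))

    def test_selected_network_is_sparsest_connected(self, sparse_truth):
        """rho* network spans all nodes; one step denser disconnects."""
        gt = sparse_truth
        n = gt.graph.number_of_nodes()
        x = sample_gaussian_series(gt.precision, 30 * n, 0.1, seed=13)
        panel = TimeSeriesPanel(x, sorted(gt.graph.nodes))
        cfg = GlassoConfig(grid_size=20)
        rho, net = select_penalty(panel, cfg)
        assert nx.is_connected(net.graph)
        from weaknodes.netinfer import _glasso_support
        corr = compute_correlation(panel).r
        sup_hi = _glasso_support(corr, cfg, rho * 1.02)
        assert not nx.is_connected(nx.from_numpy_array(sup_hi.astype(int)))


class TestOrientLinks:
    def test_planted_direction_recovered(self):
        gt = GroundTruth.from_edges(2, [(0, 1)])
        x = sample_var_series(gt, 0.8, 2000, seed=7)
        net = BrainNetwork(nx.Graph([(0, 1)]))
        d = orient_links(net, panel_from(x), max_lag=1, alpha=0.01)
        assert set(d.graph.edges) == {(0, 1)}

    def test_undetermined_direction_keeps_symmetric_link(self):
        rng = np.random.default_rng(100)
        net = BrainNetwork(nx.Graph([(0, 1)]))
        d = orient_links(net, panel_from(rng.standard_normal((2, 2000))),
                         max_lag=1, alpha=0.001)
        assert set(d.graph.edges) == {(0, 1), (1, 0)}

    def test_empty_network_stays_empty(self):
        rng = np.random.default_rng(2)
        net = BrainNetwork(nx.empty_graph(3))
        d = orient_links(net, panel_from(rng.standard_normal((3, 100))))
        assert d.is_directed and d.n_edges == 0

    def test_short_series_rejected(self):
        rng = np.random.default_rng(3)
        net = BrainNetwork(nx.Graph([(0, 1)]))
        with pytest.raises(ValueError, match="short"):
            orient_links(net, panel_from(rng.standard_normal((2, 4))), max_lag=2)
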