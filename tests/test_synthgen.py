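"""Synthetic-cohort generator: planted structure, precision model, sampling."""

import networkx as nx
import numpy as np
import pytest

from weaknodes.synthgen import (BRIDGE, STIMULATED, THIRD, CohortSpec,
                                GroundTruth, build_precision, generate_cohort,
                                generate_modular_graph, sample_gaussian_series,
                                sample_var_series)

from .conftest import EXAMPLE3_SPEC


class TestGenerateModularGraph:
    def test_two_triangles_joined_by_one_bridge(self):
        spec = CohortSpec(module_sizes=(3, 3), intra_density=1.0,
                          n_bridge_nodes=1, bridge_degree_cap=2, seed=0)
        gt = generate_modular_graph(spec)
        g = gt.graph
        assert nx.is_connected(g)
        assert g.number_of_nodes() == 7
        (b,) = gt.planted_bridges
        assert g.degree(b) == 2
        h = g.copy()
        h.remove_node(b)
        comps = [sorted(c) for c in nx.connected_components(h)]
        assert sorted(map(len, comps)) == [3, 3]
        for c in comps:  # each side is a triangle
            assert h.subgraph(c).number_of_edges() == 3

    def test_same_seed_reproduces_edge_set(self):
        spec = CohortSpec(module_sizes=(3, 3), intra_density=1.0,
                          n_bridge_nodes=1, bridge_degree_cap=2, seed=5)
        a = generate_modular_graph(spec)
        b = generate_modular_graph(spec)
        assert set(a.graph.edges) == set(b.graph.edges)
        assert a.planted_bridges == b.planted_bridges
        assert a.directed_edges == b.directed_edges

    def test_planted_bridges_cut_stimulated_from_third(self, example3_truth):
        """Deleting the planted bridges must sever every stimulated-third path."""
        gt = example3_truth
        g = gt.graph.copy()
        g.remove_nodes_from(gt.planted_bridges)
        mods = gt.network.modules
        stim = next(v for v in g if mods[v] == STIMULATED)
        for v in g:
            if mods[v] == THIRD:
                assert not nx.has_path(g, stim, v)

    def test_structural_contract(self, example3_truth):
        gt = example3_truth
        g = gt.graph
        mods = gt.network.modules
        assert nx.is_connected(g)
        cap = EXAMPLE3_SPEC.bridge_degree_cap
        stim_max = max(g.degree(v) for v in g if mods[v] == STIMULATED)
        assert stim_max > cap
        assert all(g.degree(b) <= cap for b in gt.planted_bridges)
        assert all(mods[b] == BRIDGE for b in gt.planted_bridges)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(module_sizes=(2, 3)).validate()
        with pytest.raises(ValueError):
            CohortSpec(n_bridge_nodes=0).validate()
        with pytest.raises(ValueError):
            CohortSpec(intra_density=0.0).validate()
        with pytest.raises(ValueError):
            CohortSpec(module_sizes=(5, 3, 5), n_bridge_nodes=4).validate()
        CohortSpec(n_bridge_nodes=0, regime="resting").validate()  # allowed

    def test_resting_regime_has_no_planted_bridges(self):
        gt = generate_modular_graph(CohortSpec(seed=3, regime="resting"))
        assert gt.planted_bridges == set()
        assert nx.is_connected(gt.graph)
        inter = [e for e in gt.graph.edges
                 if gt.network.modules[e[0]] != gt.network.modules[e[1]]]
        assert len(inter) >= 2


class TestPrecision:
    def test_edgeless_graph_gives_diagonal(self):
        gt = GroundTruth.from_edges(4, [])
        p = build_precision(gt, 0.3)
        assert np.allclose(p, np.eye(4))

    def test_single_edge_block_structure(self):
        gt = GroundTruth.from_edges(2, [(0, 1)])
        p = build_precision(gt, 0.4)
        assert p[0, 1] == pytest.approx(-0.4)
        assert p[0, 0] == pytest.approx(1.4)  # 1 + |row sum|

    def test_support_matches_planted_edges_and_pd(self, example3_truth):
        p = build_precision(example3_truth, 0.3)
        off = np.abs(np.triu(p, 1)) > 0
        edges = {tuple(sorted(e)) for e in example3_truth.graph.edges}
        support = {tuple(e) for e in np.argwhere(off)}
        assert support == edges
        assert np.linalg.eigvalsh(p).min() > 0

    def test_nonpositive_coupling_rejected(self):
        with pytest.raises(ValueError):
            build_precision(GroundTruth.from_edges(2, [(0, 1)]), 0.0)


class TestGaussianSampling:
    def test_diagonal_precision_gives_uncorrelated_series(self):
        x = sample_gaussian_series(np.eye(4), 100_000, 0.0, seed=11)
        c = np.corrcoef(x)
        off = c[np.triu_indices(4, 1)]
        assert np.all(np.abs(off) < 0.02)

    def test_covariance_matches_precision_inverse(self):
        gt = GroundTruth.from_edges(3, [(0, 1), (1, 2)])
        p = build_precision(gt, 0.4)
        x = sample_gaussian_series(p, 200_000, 0.0, seed=2)
        emp = np.cov(x)
        assert np.allclose(emp, np.linalg.inv(p), atol=0.02)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            sample_gaussian_series(np.eye(3), 0, 0.1, seed=0)

    def test_non_pd_precision_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            sample_gaussian_series(bad, 100, 0.1, seed=0)

    def test_reproducible_by_seed(self):
        a = sample_gaussian_series(np.eye(3), 50, 0.1, seed=9)
        b = sample_gaussian_series(np.eye(3), 50, 0.1, seed=9)
        assert np.array_equal(a, b)


class TestVarSampling:
    def test_lagged_correlation_follows_planted_direction(self):
        gt = GroundTruth.from_edges(2, [(0, 1)])  # 0 -> 1
        x = sample_var_series(gt, 0.8, 2000, seed=7)
        fwd = np.corrcoef(x[0, :-1], x[1, 1:])[0, 1]
        bwd = np.corrcoef(x[1, :-1], x[0, 1:])[0, 1]
        assert fwd > bwd
        assert fwd > 0.5

    def test_no_edges_gives_independent_noise(self):
        gt = GroundTruth.from_edges(3, [])
        x = sample_var_series(gt, 0.0, 2000, seed=5)
        c = np.corrcoef(x)
        assert np.all(np.abs(c[np.triu_indices(3, 1)]) < 0.05)

    def test_unstable_coefficient_rejected_with_radius(self):
        gt = GroundTruth.from_edges(2, [(0, 1), (1, 0)])
        with pytest.raises(ValueError, match="spectral radius"):
            sample_var_series(gt, 1.1, 100, seed=0)


class TestCohort:
    def test_singleton_cohort(self):
        spec = CohortSpec(n_subjects=1, module_sizes=(4, 3, 4),
                          intra_density=0.9, n_bridge_nodes=1, T=60, seed=2)
        cohort = generate_cohort(spec)
        assert len(cohort) == 1
        panel, gt = cohort[0]
        assert panel.values.shape == (11, 60)

    def test_reproducible_and_subjects_differ(self):
        spec = CohortSpec(n_subjects=3, module_sizes=(8, 4, 8),
                          intra_density=0.5, n_bridge_nodes=2, T=50, seed=4)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for (pa, ga), (pb, gb) in zip(a, b):
            assert np.array_equal(pa.values, pb.values)
            assert set(ga.graph.edges) == set(gb.graph.edges)
        edge_sets = [frozenset(map(tuple, map(sorted, g.graph.edges)))
                     for _, g in a]
        assert len(set(edge_sets)) > 1  # intra_density < 1: edge noise

    def test_zero_subjects_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortSpec(n_subjects=0, T=50))
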