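"""Weighted pixel graph and Dirichlet-solver behaviour."""

import numpy as np
import pytest

from liverwalker.random_walker import (
    LabelProbabilities,
    MissingSeedsError,
    RandomWalkerParams,
    WeightedPixelGraph,
    assign_labels,
    build_graph,
    edge_weight,
    segment_slice,
    solve_probabilities,
)

from conftest import dense_constrained_solve, random_grid_graph


class TestEdgeWeight:
    def test_equal_intensities_unit_weight(self):
        p = RandomWalkerParams(beta=1.0, omega=0.0, use_spatial=False)
        assert edge_weight(0.5, 0.5, (0, 0), (0, 1), p) == pytest.approx(1.0)

    def test_beta_zero_is_uniform(self):
        p = RandomWalkerParams(beta=0.0, omega=0.0, use_spatial=False)
        assert edge_weight(0.1, 0.9, (0, 0), (0, 1), p) == pytest.approx(1.0)

    def test_unit_contrast_weight(self):
        p = RandomWalkerParams(beta=1.0, omega=0.0, use_spatial=False)
        assert edge_weight(0.0, 1.0, (0, 0), (0, 1), p) == pytest.approx(np.exp(-1.0))

    def test_spatial_term_penalizes_distance(self):
        p = RandomWalkerParams(beta=0.0, omega=0.0, use_spatial=True, lambda_s=2.0)
        near = edge_weight(0.5, 0.5, (0, 0), (0, 1), p)
        far = edge_weight(0.5, 0.5, (0, 0), (1, 1), p)
        assert near == pytest.approx(np.exp(-0.5))
        assert far == pytest.approx(np.exp(-1.0))
        assert far < near

    def test_omega_floor_added(self):
        p = RandomWalkerParams(beta=1.0, omega=0.25, use_spatial=False)
        assert edge_weight(0.0, 1.0, (0, 0), (0, 1), p) == pytest.approx(np.exp(-1.0) + 0.25)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RandomWalkerParams(beta=-1)
        with pytest.raises(ValueError):
            RandomWalkerParams(connectivity=6)
        with pytest.raises(ValueError):
            RandomWalkerParams(use_spatial=True, lambda_s=0.0)


class TestGraphConstruction:
    def test_grid_edge_counts(self):
        seeds = np.zeros((3, 3), int)
        seeds[0, 0] = 1
        g4 = build_graph(np.zeros((3, 3)), seeds, RandomWalkerParams(connectivity=4))
        assert len(g4.weights) == 12  # 2*m*n - m - n
        g8 = build_graph(np.zeros((3, 3)), seeds, RandomWalkerParams(connectivity=8))
        assert len(g8.weights) == 20  # + 2*(m-1)*(n-1) diagonals

    def test_corner_degree_4conn(self):
        seeds = np.zeros((3, 3), int)
        seeds[1, 1] = 1
        g = build_graph(np.zeros((3, 3)), seeds, RandomWalkerParams(connectivity=4, beta=0, omega=0, use_spatial=False))
        deg = g.degrees()
        assert deg[0] == pytest.approx(2.0)  # corner node has 2 unit edges

    def test_laplacian_rows_sum_to_zero(self):
        rng = np.random.default_rng(1)
        g = random_grid_graph(rng)
        rowsum = np.asarray(g.laplacian().sum(axis=1)).ravel()
        assert np.abs(rowsum).max() < 1e-12

    def test_no_seeds_raises(self):
        with pytest.raises(MissingSeedsError):
            build_graph(np.zeros((3, 3)), np.zeros((3, 3), int), RandomWalkerParams())

    def test_incidence_laplacian_identity(self):
        """L = A^T C A links incidence, weights and the Laplacian."""
        rng = np.random.default_rng(2)
        g = random_grid_graph(rng)
        a = g.incidence().toarray()
        c = np.diag(g.weights)
        assert np.allclose(a.T @ c @ a, g.laplacian().toarray(), atol=1e-12)


class TestDirichletSolve:
    def test_uniform_chain_is_linear(self):
        img = np.zeros((5, 1))
        seeds = np.zeros((5, 1), int)
        seeds[0, 0], seeds[4, 0] = 1, 2
        g = build_graph(img, seeds, RandomWalkerParams(beta=0, omega=0, use_spatial=False, connectivity=4))
        probs = solve_probabilities(g)
        assert np.allclose(probs.probs[0], [1.0, 0.75, 0.5, 0.25, 0.0], atol=1e-10)
        labels = assign_labels(probs, seeds)
        # node 2 sits at exactly 0.5 and tie-breaks to the lower label
        assert labels.ravel().tolist() == [1, 1, 1, 2, 2]

    def test_all_seeded_is_one_hot(self):
        seeds = np.array([[1, 2], [2, 1]])
        g = build_graph(np.zeros((2, 2)), seeds, RandomWalkerParams())
        probs = solve_probabilities(g)
        assert set(np.unique(probs.probs)) <= {0.0, 1.0}
        assert np.array_equal(assign_labels(probs, seeds), seeds)

    def test_single_label_is_certain_everywhere(self):
        seeds = np.zeros((4, 4), int)
        seeds[0, 0] = 1
        g = build_graph(np.zeros((4, 4)), seeds, RandomWalkerParams())
        probs = solve_probabilities(g)
        assert np.allclose(probs.probs, 1.0)

    def test_matches_dense_oracle_and_is_harmonic(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            g = random_grid_graph(rng)
            probs = solve_probabilities(g)
            oracle = dense_constrained_solve(g)
            assert np.abs(probs.probs - oracle).max() < 1e-7
            assert np.abs(probs.probs.sum(axis=0) - 1.0).max() < 1e-8

    def test_maximum_principle_on_random_graphs(self):
        """Each unseeded probability lies within its neighbours' hull."""
        rng = np.random.default_rng(9)
        for _ in range(5):
            g = random_grid_graph(rng)
            probs = solve_probabilities(g)
            adj = g.adjacency().tolil().rows
            for node in g.unseeded:
                nb = adj[node]
                for k in range(len(g.labels)):
                    v = probs.probs[k, node]
                    assert min(probs.probs[k, nb]) - 1e-9 <= v <= max(probs.probs[k, nb]) + 1e-9

    def test_seedless_component_gets_uniform_probabilities(self):
        # two disjoint 1-edge components; seeds only in the first
        edges = np.array([[0, 1], [2, 3]])
        g = WeightedPixelGraph(
            shape=(2, 2),
            edges=edges,
            weights=np.ones(2),
            seed_labels=np.array([1, 2, 0, 0]),
            labels=(1, 2),
        )
        probs = solve_probabilities(g)
        assert np.allclose(probs.probs[:, 2:], 0.5)

    def test_tie_breaks_to_lowest_label(self):
        probs = LabelProbabilities(shape=(1, 2), labels=(1, 2), probs=np.array([[0.5, 0.6], [0.5, 0.4]]))
        assert assign_labels(probs).ravel().tolist() == [1, 1]

    def test_beta_zero_depends_only_on_seed_geometry(self):
        """With uniform weights the image content is irrelevant."""
        rng = np.random.default_rng(4)
        seeds = np.zeros((8, 8), int)
        seeds[1, 1], seeds[6, 6] = 1, 2
        p = RandomWalkerParams(beta=0.0, omega=0.0, use_spatial=False, connectivity=4)
        lab_flat, _ = segment_slice(np.zeros((8, 8)), seeds, p)
        lab_noise, _ = segment_slice(rng.random((8, 8)), seeds, p)
        assert np.array_equal(lab_flat, lab_noise)
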