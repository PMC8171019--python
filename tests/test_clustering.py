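"""Weighted k-medians: update rules against hand calculations and oracles."""

import numpy as np
import pytest

from genesieve import ExpressionMatrix, adjusted_rand_index
from genesieve.clustering import (
    WeightedClusterModel,
    assign_cells,
    fit,
    objective_value,
    per_feature_distance,
    update_centers,
    update_delta,
    update_weight_row,
    weighted_distance,
)
from genesieve.errors import ClusteringError


def manhattan_kmedians_oracle(X, K, init_idx, max_iter=100):
    """Plain Manhattan k-medians, written independently of the package code:
    nearest-center assignment (lowest index on ties), per-feature medians,
    empty clusters re-seeded at the cell farthest from its own center."""
    centers = X[np.asarray(init_idx)].astype(float).copy()
    m = X.shape[0]
    a = np.array(
        [min(range(K), key=lambda k: sum(abs(X[i] - centers[k]))) for i in range(m)]
    )
    for k in range(K):
        if not (a == k).any():
            far = max(range(m), key=lambda i: sum(abs(X[i] - centers[a[i]])))
            centers[k] = X[far]
            a[far] = k
    for sweep in range(1, max_iter + 1):
        prev = a.copy()
        a = np.array(
            [min(range(K), key=lambda k: sum(abs(X[i] - centers[k]))) for i in range(m)]
        )
        if sweep > 1 and np.array_equal(a, prev):
            break
        for k in range(K):
            if not (a == k).any():
                far = max(range(m), key=lambda i: sum(abs(X[i] - centers[a[i]])))
                centers[k] = X[far]
                a[far] = k
        for k in range(K):
            members = X[a == k]
            if len(members):
                centers[k] = np.median(members, axis=0)
    return a, centers


class TestPerFeatureDistance:
    def test_identical_points_zero(self):
        np.testing.assert_array_equal(
            per_feature_distance(np.array([1.0, 2.0]), np.array([1.0, 2.0])), [0, 0]
        )

    def test_absolute_difference(self):
        np.testing.assert_array_equal(
            per_feature_distance(np.array([0.0, 4.0]), np.array([1.0, 2.0])), [1, 2]
        )

    def test_matches_scalar_loop(self, rng):
        x, c = rng.random(10), rng.random(10)
        expected = np.array([abs(x[j] - c[j]) for j in range(10)])
        np.testing.assert_allclose(per_feature_distance(x, c), expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            per_feature_distance(np.ones(3), np.ones(4))


class TestWeightedDistance:
    def test_zero_at_center_regardless_of_weights(self, rng):
        c = rng.random(6)
        w = rng.random(6)
        assert weighted_distance(w, c.copy(), c) == 0.0

    def test_uniform_weights_give_scaled_manhattan(self, rng):
        x, c = rng.random(8), rng.random(8)
        w = np.full(8, 1 / 8)
        assert weighted_distance(w, x, c) == pytest.approx(np.abs(x - c).sum() / 8)

    def test_hand_case(self):
        # w=(0.75,0.25), d=(1,2) -> 0.75 + 0.5
        assert weighted_distance(
            np.array([0.75, 0.25]), np.array([1.0, 2.0]), np.array([0.0, 0.0])
        ) == pytest.approx(1.25, abs=1e-9)


class TestAssignment:
    def test_cell_at_center_wins(self):
        centers = np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 9.0]])
        W = np.full((3, 2), 0.5)
        a = assign_cells(np.array([[5.0, 5.0]]), W, centers)
        assert a[0] == 1

    def test_tie_breaks_to_lowest_index(self):
        centers = np.array([[0.0], [2.0], [0.0]])
        W = np.ones((3, 1))
        a = assign_cells(np.array([[1.0]]), W, centers)  # tie between all three
        assert a[0] == 0

    def test_matches_exhaustive_argmin(self, rng):
        X = rng.random((20, 7))
        centers = rng.random((3, 7))
        W = rng.random((3, 7))
        W /= W.sum(axis=1, keepdims=True)
        a = assign_cells(X, W, centers)
        for i in range(20):
            dists = [np.dot(W[k], np.abs(X[i] - centers[k])) for k in range(3)]
            assert a[i] == int(np.argmin(dists))


class TestCenterUpdate:
    def test_odd_cluster_median(self):
        X = np.array([[1.0], [5.0], [9.0]])
        a = np.zeros(3, dtype=int)
        centers = update_centers(X, a, np.ones((1, 1)), np.zeros((1, 1)))
        assert centers[0, 0] == 5.0

    def test_even_cluster_median_is_midpoint(self):
        X = np.array([[1.0], [3.0]])
        a = np.zeros(2, dtype=int)
        centers = update_centers(X, a, np.ones((1, 1)), np.zeros((1, 1)))
        assert centers[0, 0] == 2.0

    def test_zero_weight_zeroes_center_coordinate(self):
        X = np.array([[1.0, 4.0], [3.0, 8.0]])
        a = np.zeros(2, dtype=int)
        W = np.array([[0.0, 1.0]])
        centers = update_centers(X, a, W, np.zeros((1, 2)))
        assert centers[0, 0] == 0.0
        assert centers[0, 1] == 6.0


class TestWeightUpdate:
    def test_single_feature_forced_to_one(self, rng):
        X = rng.random((4, 1))
        w = update_weight_row(X, np.ones(4, dtype=bool), np.array([0.5]), 2.0)
        np.testing.assert_allclose(w, [1.0])

    def test_all_members_at_center_gives_uniform(self):
        X = np.tile([2.0, 7.0, 1.0], (5, 1))
        w = update_weight_row(X, np.ones(5, dtype=bool), X[0], 3.0)
        np.testing.assert_allclose(w, [1 / 3] * 3)

    def test_hand_case(self):
        # cluster {(0,0),(2,4)}, center (1,2), delta=2 -> (0.75, 0.25)
        X = np.array([[0.0, 0.0], [2.0, 4.0]])
        w = update_weight_row(X, np.ones(2, dtype=bool), np.array([1.0, 2.0]), 2.0)
        np.testing.assert_allclose(w, [0.75, 0.25], atol=1e-9)

    def test_raw_row_sums_to_one(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 30))
            X = rng.random((int(rng.integers(2, 15)), n)) * 10
            c = rng.random(n)
            raw = update_weight_row(
                X, np.ones(X.shape[0], dtype=bool), c, float(rng.random() + 0.1),
                return_raw=True,
            )
            assert abs(raw.sum() - 1.0) < 1e-9

    def test_projection_bounds(self, rng):
        X = rng.random((10, 6)) * 100
        w = update_weight_row(X, np.ones(10, dtype=bool), np.zeros(6), 0.01)
        assert (w >= 0).all() and (w <= 1).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-9)


class TestDeltaUpdate:
    def test_hand_case(self):
        # 2 cells, w=(0.5,0.5), d-rows (1,3),(2,0) -> delta = 3/0.5 = 6
        X = np.array([[1.0, 3.0], [2.0, 0.0]])
        c = np.zeros(2)
        d = update_delta(X, np.ones(2, dtype=bool), np.array([0.5, 0.5]), c, 1.0, 99.0)
        assert d == pytest.approx(6.0, abs=1e-9)

    def test_degenerate_cluster_keeps_previous(self):
        X = np.tile([1.0, 2.0], (3, 1))
        d = update_delta(
            X, np.ones(3, dtype=bool), np.array([0.5, 0.5]), X[0], 1.0, 7.5
        )
        assert d == 7.5

    def test_linear_in_c_delta(self, rng):
        X = rng.random((5, 4))
        w = np.full(4, 0.25)
        c = rng.random(4)
        d1 = update_delta(X, np.ones(5, dtype=bool), w, c, 1.0, 1.0)
        d2 = update_delta(X, np.ones(5, dtype=bool), w, c, 2.0, 1.0)
        assert d2 == pytest.approx(2 * d1)


class TestObjective:
    def test_all_cells_at_center_leaves_penalty_only(self):
        X = np.tile([1.0, 2.0], (4, 1))
        W = np.array([[0.6, 0.4]])
        delta = np.array([3.0])
        J = objective_value(X, W, X[:1].copy(), delta, np.zeros(4, dtype=int))
        assert J == pytest.approx(3.0 * (0.36 + 0.16))

    def test_hand_case(self):
        # 1 cluster, 2 cells at d=(1,1) each, uniform w, delta=1, n=2 -> 2.5
        X = np.array([[1.0, 1.0], [1.0, 1.0]])
        centers = np.array([[0.0, 0.0]])
        W = np.array([[0.5, 0.5]])
        J = objective_value(X, W, centers, np.array([1.0]), np.zeros(2, dtype=int))
        assert J == pytest.approx(2.5, abs=1e-9)

    def test_matches_triple_loop(self, rng):
        X = rng.random((12, 5))
        W = rng.random((3, 5))
        W /= W.sum(axis=1, keepdims=True)
        centers = rng.random((3, 5))
        delta = rng.random(3) + 0.5
        a = rng.integers(0, 3, size=12)
        expected = 0.0
        for k in range(3):
            for i in range(12):
                if a[i] == k:
                    for j in range(5):
                        expected += W[k, j] * abs(X[i, j] - centers[k, j])
            for j in range(5):
                expected += delta[k] * W[k, j] ** 2
        assert objective_value(X, W, centers, delta, a) == pytest.approx(expected)


class TestFit:
    def test_separated_blobs_recovered(self, rng):
        blob1 = rng.normal(0, 0.1, size=(30, 5)) + 1
        blob2 = rng.normal(0, 0.1, size=(30, 5)) + 50
        X = np.clip(np.vstack([blob1, blob2]), 0, None)
        truth = np.repeat([0, 1], 30)
        model = fit(X, 2, seed=3)
        assert adjusted_rand_index(truth, model.assignments) == 1.0

    def test_frozen_weights_equal_plain_kmedians(self, rng):
        for trial in range(10):
            X = rng.random((50, 20)) * 10
            model = fit(X, 3, seed=trial, freeze_weights=True, n_init=1)
            a, centers = manhattan_kmedians_oracle(X, 3, model.init_center_indices)
            np.testing.assert_array_equal(model.assignments, a)
            np.testing.assert_allclose(model.centers, centers)

    def test_k_equals_m_every_cell_own_cluster(self, rng):
        X = rng.random((6, 4)) * 5
        model = fit(X, 6, seed=0, n_init=1)
        assert len(set(model.assignments.tolist())) == 6
        # first objective term vanishes: every cell is its own center
        first_term = sum(
            np.abs(X[model.assignments == k] - model.centers[k]) @ model.W[k]
            for k in range(6)
        ).sum()
        assert first_term == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_bit_identical(self, default_dataset):
        x = default_dataset.matrix
        m1 = fit(x, 5, seed=11, max_iter=10)
        m2 = fit(x, 5, seed=11, max_iter=10)
        np.testing.assert_array_equal(m1.assignments, m2.assignments)
        np.testing.assert_array_equal(m1.W, m2.W)

    def test_gene_permutation_equivariance(self, rng):
        X = rng.random((30, 8)) * 10
        perm = rng.permutation(8)
        m1 = fit(X, 3, seed=5, max_iter=20)
        m2 = fit(X[:, perm], 3, seed=5, max_iter=20)
        np.testing.assert_array_equal(m1.assignments, m2.assignments)
        np.testing.assert_allclose(m2.W, m1.W[:, perm], atol=1e-12)

    def test_huge_c_delta_keeps_weights_uniform(self, rng):
        X = rng.random((40, 10)) * 20
        model = fit(X, 3, c_delta=1e9, seed=2)
        assert np.abs(model.W - 0.1).max() < 1e-3

    def test_invalid_k_raises(self, rng):
        X = rng.random((5, 3))
        with pytest.raises(ClusteringError):
            fit(X, 6, seed=0)
        with pytest.raises(ClusteringError):
            fit(X, 1, seed=0)

    def test_row_invariants_on_fitted_model(self, fitted_default):
        W = fitted_default.W
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-9)
        assert (W >= 0).all() and (W <= 1).all()
        assert (fitted_default.delta > 0).all()


def test_model_serialization_round_trip(tmp_path, rng):
    X = rng.random((10, 4)) * 5
    model = fit(X, 2, seed=0, max_iter=5)
    model.gene_ids = ["a", "b", "c", "d"]
    model.cell_ids = [f"c{i}" for i in range(10)]
    model.save(str(tmp_path))
    import json

    meta = json.loads((tmp_path / "model.json").read_text())
    assert meta["n_clusters"] == 2
    assert len(meta["assignments"]) == 10
    header = (tmp_path / "model_weights.tsv").read_text().splitlines()[0]
    assert header.split("\t") == ["a", "b", "c", "d"]
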