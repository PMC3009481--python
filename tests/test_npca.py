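"""Nonnegative PCA: objective/gradient correctness, solvers, recovery."""

import numpy as np
import pytest

from npca_protpat.npca import (
    NonnegativePCA,
    NPCAModel,
    coordinate_update,
    gradient,
    load_model,
    npca_fit,
    objective,
    save_model,
    variance_explained,
)
from npca_protpat.simulate import generate_lowrank


def objective_direct(U, X, alpha):
    """Independent re-implementation: sum the two Frobenius terms term by term."""
    k = U.shape[1]
    data_term = 0.0
    for j in range(X.shape[1]):
        proj = U.T @ X[:, j]
        data_term += float(proj @ proj)
    pen = U.T @ U - np.eye(k)
    pen_term = float(np.sum(pen * pen))
    return 0.5 * data_term - alpha * pen_term


class TestObjective:
    def test_orthonormal_hand_value(self):
        U = np.array([[1.0], [0.0]])
        X = np.array([[1.0, 0.0], [0.0, 0.0]])
        for alpha in (0.0, 3.0, 10.0):
            assert objective(U, X, alpha) == pytest.approx(0.5)

    def test_zero_matrix_only_penalty(self, rng):
        U = np.zeros((4, 1))
        X = np.abs(rng.standard_normal((4, 6)))
        assert objective(U, X, 10.0) == pytest.approx(-10.0)

    def test_matches_independent_evaluation(self, rng):
        U = np.abs(rng.standard_normal((3, 2)))
        X = np.abs(rng.standard_normal((3, 4)))
        assert objective(U, X, 2.0) == pytest.approx(objective_direct(U, X, 2.0))

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="row mismatch"):
            objective(np.ones((3, 2)), np.ones((4, 5)), 1.0)


class TestGradient:
    def test_vanishes_at_orthonormal_with_zero_data(self):
        U = np.eye(3)[:, :2]
        np.testing.assert_allclose(gradient(U, np.zeros((3, 5)), 7.0), 0.0)

    def test_alpha_zero_is_data_term(self, rng):
        U = np.abs(rng.standard_normal((5, 2)))
        X = np.abs(rng.standard_normal((5, 8)))
        np.testing.assert_allclose(gradient(U, X, 0.0), X @ (X.T @ U))

    @pytest.mark.parametrize("alpha", [0.0, 1.0, 10.0])
    def test_matches_finite_differences(self, alpha):
        rng = np.random.default_rng(7)
        for _ in range(5):
            d, k, m = rng.integers(2, 7), rng.integers(1, 4), rng.integers(2, 11)
            U = np.abs(rng.standard_normal((d, k)))
            X = np.abs(rng.standard_normal((d, m)))
            g = gradient(U, X, alpha)
            fd = np.zeros_like(U)
            eps = 1e-6
            for i in range(d):
                for j in range(k):
                    up, dn = U.copy(), U.copy()
                    up[i, j] += eps
                    dn[i, j] -= eps
                    fd[i, j] = (objective(up, X, alpha)
                                - objective(dn, X, alpha)) / (2 * eps)
            assert np.linalg.norm(g - fd) / np.linalg.norm(fd) <= 1e-5


class TestCoordinateUpdate:
    def test_fixed_point_at_interior_maximum(self, rng):
        U = np.abs(rng.standard_normal((4, 2)))
        X = np.abs(rng.standard_normal((4, 6)))
        first = coordinate_update(U, X, 5.0, 2, 1)
        U[2, 1] = first
        again = coordinate_update(U, X, 5.0, 2, 1)
        assert again == pytest.approx(first, abs=1e-8)

    def test_matches_grid_search(self, rng):
        U = np.abs(rng.standard_normal((4, 2)))
        X = np.abs(rng.standard_normal((4, 6)))
        grid = np.arange(0.0, 6.0, 1e-3)
        for s in range(4):
            for l in range(2):
                u_new = coordinate_update(U, X, 5.0, s, l)

                def f(u):
                    V = U.copy()
                    V[s, l] = u
                    return objective(V, X, 5.0)

                best = grid[np.argmax([f(u) for u in grid])]
                assert abs(u_new - best) <= 2e-3

    def test_full_sweep_monotone(self, rng):
        U = np.abs(rng.standard_normal((4, 3)))
        X = np.abs(rng.standard_normal((4, 7)))
        prev = objective(U, X, 4.0)
        for s in range(4):
            for l in range(3):
                U[s, l] = coordinate_update(U, X, 4.0, s, l)
                cur = objective(U, X, 4.0)
                assert cur >= prev - 1e-9
                prev = cur

    def test_alpha_nonpositive_rejected(self, rng):
        with pytest.raises(ValueError, match="alpha > 0"):
            coordinate_update(np.ones((2, 2)), np.ones((2, 3)), 0.0, 0, 0)


class TestFit:
    def test_deterministic_under_seed(self, rng):
        X = np.abs(rng.standard_normal((8, 12)))
        a = npca_fit(X, 3, alpha=10, solver="hybrid", seed=5)
        b = npca_fit(X, 3, alpha=10, solver="hybrid", seed=5)
        np.testing.assert_array_equal(a.U, b.U)
        assert a.n_iter == b.n_iter

    def test_rank_one_direction_recovered(self):
        rng = np.random.default_rng(2)
        a = np.abs(rng.standard_normal(6)) + 0.1
        b = np.abs(rng.standard_normal(10)) + 0.1
        X = np.outer(a, b)
        model = npca_fit(X, 1, alpha=10.0, solver="hybrid", seed=0)
        u = model.U[:, 0]
        cos = abs(u @ a) / (np.linalg.norm(u) * np.linalg.norm(a))
        assert cos >= 0.99

    def test_scaled_identity_gives_permutation_like_pcs(self):
        X = 5.0 * np.eye(3)
        model = npca_fit(X, 3, alpha=50.0, solver="hybrid", seed=1)
        V = model.U / np.linalg.norm(model.U, axis=0, keepdims=True)
        # each normalized column concentrates on a distinct axis
        tops = np.argmax(V, axis=0)
        assert sorted(tops.tolist()) == [0, 1, 2]
        P = np.zeros((3, 3))
        P[tops, np.arange(3)] = 1.0
        assert np.linalg.norm(V - P) <= 1e-2

    def test_nonnegativity_and_trace_contract(self, rng):
        X = np.abs(rng.standard_normal((6, 9)))
        model = npca_fit(X, 2, alpha=5.0, solver="gradient", seed=3, max_iter=50)
        assert model.U.min() >= 0
        assert len(model.objective_trace) == model.n_iter + 1
        np.testing.assert_allclose(model.P, X.T @ model.U)
        assert model.w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_input_validation(self, rng):
        X = np.abs(rng.standard_normal((4, 5)))
        with pytest.raises(ValueError, match="nonnegative"):
            npca_fit(-X, 2)
        with pytest.raises(ValueError, match="k="):
            npca_fit(X, 5)
        with pytest.raises(ValueError, match="coordinate solver"):
            npca_fit(X, 2, alpha=0.0, solver="coordinate")

    def test_gradient_solver_close_to_coordinate(self):
        # normalized fixed-step ascent lands within 2% of the exact
        # per-entry solver's objective on small instances
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = np.abs(rng.standard_normal((8, 15)))
            init = np.abs(rng.standard_normal((8, 3)))
            g = npca_fit(X, 3, alpha=10, solver="gradient", seed=seed, init=init)
            c = npca_fit(X, 3, alpha=10, solver="coordinate", seed=seed, init=init)
            Jg = objective(g.U, X, 10.0)
            Jc = objective(c.U, X, 10.0)
            assert Jg >= Jc - 0.02 * abs(Jc)

    def test_orthonormality_pressure_increases_with_alpha(self):
        devs = {1.0: [], 100.0: []}
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = np.abs(rng.standard_normal((20, 100)))
            for alpha in devs:
                m = npca_fit(X, 3, alpha=alpha, solver="hybrid", seed=seed)
                devs[alpha].append(
                    np.linalg.norm(m.U.T @ m.U - np.eye(3)))
        assert np.mean(devs[100.0]) <= np.mean(devs[1.0])


def matched_correlation(U, U_true):
    k = U_true.shape[1]
    C = np.abs(np.corrcoef(U.T, U_true.T)[:k, k:])
    total = 0.0
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(C), C.shape)
        total += C[i, j]
        C[i, :] = -1
        C[:, j] = -1
    return total / k


class TestRecovery:
    def test_lowrank_factor_recovery(self):
        scores = []
        for seed in range(5):
            X, U_true, _ = generate_lowrank(20, 200, 3, 0.05, seed)
            model = npca_fit(X, 3, alpha="auto", solver="hybrid", seed=seed)
            scores.append(matched_correlation(model.U, U_true))
        assert np.mean(scores) >= 0.9


class TestVarianceExplained:
    def test_single_component_is_one(self, rng):
        X = np.abs(rng.standard_normal((5, 8)))
        model = npca_fit(X, 1, alpha=5.0, seed=0, solver="hybrid")
        np.testing.assert_allclose(variance_explained(model, X), [1.0])

    def test_known_score_variances(self):
        rng = np.random.default_rng(3)
        r0 = 3.0 * rng.standard_normal(500) + 10.0   # variance ~9
        r1 = 1.0 * rng.standard_normal(500) + 10.0   # variance ~1
        X = np.abs(np.vstack([r0, r1]))
        model = npca_fit(X, 2, alpha=5.0, seed=0, max_iter=1)
        model.U = np.eye(2)      # fixed orthonormal nonnegative U
        model.P = X.T @ model.U
        w = variance_explained(model, X)
        assert w[0] == pytest.approx(0.9, abs=0.03)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_scores_error(self):
        model = npca_fit(np.ones((3, 4)), 1, alpha=5.0, seed=0, max_iter=1)
        model.U = np.ones((3, 1))
        with pytest.raises(ValueError, match="constant"):
            variance_explained(model, np.ones((3, 4)))


class TestSerialization:
    def test_round_trip(self, rng, tmp_path):
        X = np.abs(rng.standard_normal((6, 9)))
        model = npca_fit(X, 2, alpha=7.0, seed=11, solver="hybrid")
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_allclose(back.U, model.U)
        np.testing.assert_allclose(back.P, model.P)
        assert back.alpha == model.alpha
        assert back.converged == model.converged
        assert back.seed == model.seed


class TestEstimator:
    def test_fit_transform_returns_meta_samples(self, rng):
        X = np.abs(rng.standard_normal((8, 20)))
        est = NonnegativePCA(n_components=3, alpha=10.0, random_state=0)
        U = est.fit_transform(X)
        np.testing.assert_array_equal(U, est.U_)
        assert est.loadings_.shape == (20, 3)
        assert est.explained_variance_ratio_.sum() == pytest.approx(1.0)

    def test_nnls_embedding_of_training_rows(self, rng):
        # with an exactly column-orthonormal nonnegative U (disjoint
        # supports) and noiseless X = U S, each training row's NNLS
        # embedding against P = X^T U reproduces its meta-sample
        d, k, m = 12, 3, 40
        U = np.zeros((d, k))
        for j, rows in enumerate(np.array_split(np.arange(d), k)):
            U[rows, j] = np.abs(rng.normal(1.0, 0.2, rows.size))
        U /= np.linalg.norm(U, axis=0, keepdims=True)
        S = np.abs(rng.normal(1.0, 0.5, (k, m)))
        X = U @ S
        est = NonnegativePCA(n_components=k, sparseness=None, random_state=0)
        est.fit(X[:4])                     # populate the fitted surface
        est.model_.U, est.model_.k = U, k
        est.loadings_ = X.T @ U
        est.n_features_in_ = m
        U_hat = est.transform(X)
        rel = np.linalg.norm(U_hat - U, axis=1) / np.linalg.norm(U, axis=1)
        assert np.max(rel) <= 1e-3

    def test_sklearn_param_interface(self):
        est = NonnegativePCA(alpha=3.0)
        assert est.get_params()["alpha"] == 3.0
        est.set_params(alpha=4.0, sparseness=0.5)
        assert est.alpha == 4.0 and est.sparseness == 0.5
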