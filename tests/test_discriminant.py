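"""FMGDA learner: means, scatter surrogates, trace-ratio solver, fit."""

import numpy as np
import pytest

from fmgda.discriminant import (
    ConfigurationError,
    DegenerateProblemError,
    FMGDAConfig,
    class_frechet_means,
    euclidean_lda_reference,
    exact_objective,
    fit,
    scatter_surrogates,
    solve_trace_ratio,
    transform,
    transform_set,
)
from fmgda.grassmann import (
    GrassmannPoint,
    LabeledGrassmannSet,
    ShapeError,
    projection_distance,
)
from fmgda.synthetic import GrassmannSimSpec, gen_grassmann_classes

from conftest import random_labeled_set, random_point, random_rotation


class TestClassFrechetMeans:
    def test_identical_points_single_class(self, rng):
        X = random_point(rng, 5, 2)
        data = LabeledGrassmannSet(np.stack([X.basis] * 3), np.zeros(3, int))
        means, gm = class_frechet_means(data)
        assert projection_distance(means[0], X) == pytest.approx(0.0, abs=1e-10)
        assert projection_distance(gm, X) == pytest.approx(0.0, abs=1e-10)

    def test_singleton_classes_are_their_own_means(self, rng):
        pts = [random_point(rng, 6, 2) for _ in range(3)]
        data = LabeledGrassmannSet.from_points(pts, [0, 1, 2])
        means, _ = class_frechet_means(data)
        for m, pt in zip(means, pts):
            assert projection_distance(m, pt) == pytest.approx(0.0, abs=1e-10)

    def test_global_mean_of_orthogonal_lines_beats_grid_oracle(self, rng):
        """Two orthogonal 1-dim classes in D=4: eigen mean cost <= grid min."""
        e = np.eye(4)
        bases = np.stack([e[:, :1]] * 2 + [e[:, 1:2]] * 2)
        data = LabeledGrassmannSet(bases, np.array([0, 0, 1, 1]))
        with pytest.warns(RuntimeWarning):  # perfectly tied spectrum
            _, gm = class_frechet_means(data)
        cost = sum(
            projection_distance(gm, GrassmannPoint(b)) for b in bases
        )
        U = rng.standard_normal((10_000, 4))
        U /= np.linalg.norm(U, axis=1, keepdims=True)
        grid_min = np.min(np.sum(1 - (U @ bases[:, :, 0].T) ** 2, axis=1))
        assert cost <= grid_min + 1e-9
        # the mean lies in the span of the union of the two lines
        proj = gm.basis - e[:, :2] @ (e[:, :2].T @ gm.basis)
        assert np.linalg.norm(proj) == pytest.approx(0.0, abs=1e-8)


class TestScatterSurrogates:
    def test_zero_within_scatter_when_points_equal_class_means(self, rng):
        X0, X1 = random_point(rng, 6, 2), random_point(rng, 6, 2)
        bases = np.stack([X0.basis, X0.basis, X1.basis, X1.basis])
        data = LabeledGrassmannSet(bases, np.array([0, 0, 1, 1]))
        means, gm = class_frechet_means(data)
        A = np.eye(6)[:, :4]
        _, Q = scatter_surrogates(data, means, gm, A)
        assert np.linalg.norm(Q) == pytest.approx(0.0, abs=1e-12)

    def test_single_class_has_zero_between_scatter(self, rng):
        data = random_labeled_set(rng, K=1, n_per_class=5, D=6, p=2)
        means, gm = class_frechet_means(data)
        B, _ = scatter_surrogates(data, means, gm, np.eye(6)[:, :3])
        assert np.linalg.norm(B) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("weighting", ["classwise", "uniform"])
    @pytest.mark.parametrize("seed", range(5))
    def test_surrogate_ratio_equals_exact_ratio_at_A_prev(self, seed, weighting):
        """tr(A^T B~ A)/tr(A^T Q~ A) reproduces d_b/d_w at A = A_prev."""
        rng = np.random.default_rng(seed)
        data = random_labeled_set(rng, K=2, n_per_class=4, D=6, p=1)
        means, gm = class_frechet_means(data)
        A = np.linalg.qr(rng.standard_normal((6, 3)))[0]
        B, Q = scatter_surrogates(data, means, gm, A, weighting)
        surro = np.trace(A.T @ B @ A) / np.trace(A.T @ Q @ A)
        _, _, exact = exact_objective(data, means, gm, A, weighting)
        assert surro == pytest.approx(exact, rel=1e-8)

    def test_between_trace_matches_direct_frobenius_sum(self, rng):
        """tr(A^T B~ A) = sum_k n_k ||A^T(M'_k M'_k^T - M'M'^T)A||_F^2."""
        from fmgda.discriminant import _primed

        data = random_labeled_set(rng, K=2, n_per_class=3, D=6, p=1)
        means, gm = class_frechet_means(data)
        A = np.linalg.qr(rng.standard_normal((6, 3)))[0]
        B, _ = scatter_surrogates(data, means, gm, A)
        Mg = _primed(A, gm.basis, "g")
        direct = 0.0
        for k in range(2):
            Mk = _primed(A, means[k].basis, "k")
            Bk = Mk @ Mk.T - Mg @ Mg.T
            direct += data.class_sizes[k] * np.linalg.norm(A.T @ Bk @ A) ** 2
        assert np.trace(A.T @ B @ A) == pytest.approx(direct, rel=1e-10)

    def test_outputs_symmetric_psd(self, rng):
        data = random_labeled_set(rng, K=3, n_per_class=3, D=8, p=2)
        means, gm = class_frechet_means(data)
        B, Q = scatter_surrogates(data, means, gm, np.eye(8)[:, :4])
        for S in (B, Q):
            np.testing.assert_allclose(S, S.T, atol=1e-12)
            assert np.linalg.eigvalsh(S).min() >= -1e-10


class TestSolveTraceRatio:
    def test_full_dimension_gives_trace_ratio_of_traces(self, rng):
        M1 = rng.standard_normal((4, 4))
        M2 = rng.standard_normal((4, 4))
        B, Q = M1 @ M1.T, M2 @ M2.T + np.eye(4)
        _, lam, _ = solve_trace_ratio(B, Q, d=4)
        assert lam == pytest.approx(np.trace(B) / np.trace(Q), rel=1e-10)

    def test_diagonal_pencil_closed_form(self):
        B = np.diag([4.0, 1.0, 0.0])
        A, lam, _ = solve_trace_ratio(B, np.eye(3), d=1)
        assert lam == pytest.approx(4.0, rel=1e-12)
        assert abs(A[0, 0]) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_lambda_sequence_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        M1, M2 = rng.standard_normal((6, 6)), rng.standard_normal((6, 6))
        _, _, trace = solve_trace_ratio(M1 @ M1.T, M2 @ M2.T + 0.1 * np.eye(6), d=2)
        assert np.all(np.diff(trace) >= -1e-10)

    def test_beats_monte_carlo_candidates(self, rng):
        """lambda* >= the best ratio over many random orthonormal A."""
        M1, M2 = rng.standard_normal((5, 5)), rng.standard_normal((5, 5))
        B, Q = M1 @ M1.T, M2 @ M2.T + 0.1 * np.eye(5)
        _, lam, _ = solve_trace_ratio(B, Q, d=2)
        cands = np.linalg.qr(rng.standard_normal((20_000, 5, 2)))[0]
        num = np.einsum("kdj,de,kej->k", cands, B, cands)
        den = np.einsum("kdj,de,kej->k", cands, Q, cands)
        assert lam >= np.max(num / den) - 1e-10

    def test_zero_within_scatter_raises(self):
        with pytest.raises(DegenerateProblemError, match="regulariz|ridge"):
            solve_trace_ratio(np.eye(3), np.zeros((3, 3)), d=1)

    def test_non_symmetric_input_raises(self, rng):
        M = rng.standard_normal((4, 4))
        with pytest.raises(ShapeError):
            solve_trace_ratio(M, np.eye(4), d=1)


def make_separable_two_class(D=8, p=2, n_per_class=4):
    e = np.eye(D)
    b0, b1 = e[:, :p], e[:, p : 2 * p]
    bases = np.stack([b0] * n_per_class + [b1] * n_per_class)
    labels = np.repeat([0, 1], n_per_class)
    return LabeledGrassmannSet(bases, labels)


class TestFit:
    def test_perfectly_separable_two_classes(self):
        """Zero within-class spread: objective diverges (d_w -> 0 guard) and
        training 1-NN accuracy is perfect."""
        data = make_separable_two_class()
        model = fit(data, FMGDAConfig(target_dim=5))
        assert np.isinf(model.objective_trace[-1]) or model.objective_trace[-1] > 1e6
        from fmgda.experiments import knn_accuracy

        reduced = transform_set(model, data)
        assert knn_accuracy(reduced, reduced) == 1.0

    def test_single_outer_iteration_contract(self, rng):
        """outer_iters=1 equals one surrogate build + one trace-ratio solve."""
        data = random_labeled_set(rng, K=2, n_per_class=4, D=8, p=2)
        cfg = FMGDAConfig(target_dim=4, outer_iters=1)
        model = fit(data, cfg)
        means, gm = class_frechet_means(data)
        A0 = np.eye(8)[:, :4]
        B, Q = scatter_surrogates(data, means, gm, A0)
        A1, _, _ = solve_trace_ratio(B, Q, 4, cfg.trace_ratio_iters, cfg.inner_tol, A0=A0)
        np.testing.assert_allclose(model.A, A1, atol=1e-12)
        assert len(model.lambda_traces) == 1
        assert len(model.objective_trace) == 2

    def test_final_objective_improves_on_moderate_noise_data(self):
        spec = GrassmannSimSpec(
            n_classes=3, n_per_class=20, ambient_dim=40, subspace_dim=5,
            noise=0.3, seed=11,
        )
        data = gen_grassmann_classes(spec)
        model = fit(data, FMGDAConfig(target_dim=10))
        assert model.objective_trace[-1] >= model.objective_trace[0]

    def test_inner_lambda_traces_non_decreasing(self):
        spec = GrassmannSimSpec(
            n_classes=3, n_per_class=10, ambient_dim=20, subspace_dim=3,
            noise=0.3, seed=5,
        )
        model = fit(gen_grassmann_classes(spec), FMGDAConfig(target_dim=8))
        for trace in model.lambda_traces:
            assert np.all(np.diff(trace) >= -1e-10)

    def test_label_permutation_leaves_objective_unchanged(self):
        spec = GrassmannSimSpec(
            n_classes=3, n_per_class=8, ambient_dim=15, subspace_dim=2,
            noise=0.4, seed=3,
        )
        data = gen_grassmann_classes(spec)
        perm = np.array([2, 0, 1])
        permuted = type(data)(data.bases, perm[data.labels])
        m1 = fit(data, FMGDAConfig(target_dim=6))
        m2 = fit(permuted, FMGDAConfig(target_dim=6))
        np.testing.assert_allclose(
            m1.objective_trace, m2.objective_trace, rtol=1e-8
        )

    def test_dimension_constraints_enforced(self, rng):
        data = random_labeled_set(rng, K=2, n_per_class=3, D=6, p=3)
        with pytest.raises(ConfigurationError):
            fit(data, FMGDAConfig(target_dim=2))  # d < p
        with pytest.raises(ConfigurationError):
            fit(data, FMGDAConfig(target_dim=6))  # d = D


class TestTransform:
    def test_identity_mapping_preserves_embedded_subspace(self):
        data = make_separable_two_class(D=8, p=2)
        model = fit(data, FMGDAConfig(target_dim=4, outer_iters=1))
        # rebuild the model with an identity-block mapping
        X = GrassmannPoint(np.eye(8, 2))
        model_id = type(model)(
            A=np.eye(8)[:, :4],
            class_means=model.class_means,
            global_mean=model.global_mean,
            objective_trace=model.objective_trace,
            lambda_traces=model.lambda_traces,
            config=model.config,
        )
        Z = transform(model_id, X)
        np.testing.assert_allclose(np.abs(Z.basis), np.eye(4, 2), atol=1e-12)

    def test_output_is_valid_grassmann_point(self, rng):
        data = random_labeled_set(rng, K=2, n_per_class=4, D=10, p=3)
        model = fit(data, FMGDAConfig(target_dim=5))
        for i in range(data.n_points):
            Z = transform(model, data.point(i))
            assert (Z.ambient_dim, Z.subspace_dim) == (5, 3)
            np.testing.assert_allclose(
                Z.basis.T @ Z.basis, np.eye(3), atol=1e-10
            )

    def test_basis_rotation_invariance(self, rng):
        data = random_labeled_set(rng, K=2, n_per_class=4, D=10, p=3)
        model = fit(data, FMGDAConfig(target_dim=5))
        X = random_point(rng, 10, 3)
        O = random_rotation(rng, 3)
        Z1 = transform(model, X)
        Z2 = transform(model, GrassmannPoint(X.basis @ O))
        assert projection_distance(Z1, Z2) == pytest.approx(0.0, abs=1e-10)

    def test_ambient_mismatch(self, rng):
        data = random_labeled_set(rng, K=2, n_per_class=3, D=8, p=2)
        model = fit(data, FMGDAConfig(target_dim=4))
        with pytest.raises(ShapeError):
            transform(model, random_point(rng, 9, 2))


class TestEuclideanLDAReference:
    def test_symmetric_two_class_direction(self):
        """Two classes symmetric about 0 along x: direction is the x axis."""
        rng = np.random.default_rng(0)
        X = np.vstack(
            [
                np.array([3.0, 0.0]) + 0.1 * rng.standard_normal((30, 2)),
                np.array([-3.0, 0.0]) + 0.1 * rng.standard_normal((30, 2)),
            ]
        )
        y = np.repeat([0, 1], 30)
        w = euclidean_lda_reference(X, y, 1)[:, 0]
        # finite-sample noise allows a degree or two of rotation
        assert abs(w[0]) / np.linalg.norm(w) > 0.98

    def test_rank_bound_at_most_K_minus_1_directions(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 5))
        y = np.repeat(np.arange(3), 20)
        X[y == 1] += 4.0
        X[y == 2] -= 4.0
        mu = X.mean(axis=0)
        Sb = sum(
            (np.sum(y == k)) * np.outer(X[y == k].mean(0) - mu, X[y == k].mean(0) - mu)
            for k in range(3)
        )
        assert np.linalg.matrix_rank(Sb) <= 2

    def test_fisher_direction_matches_angle_grid_oracle(self):
        """2-D two-class problem: LDA direction maximizes the Rayleigh
        quotient over a dense angle grid."""
        rng = np.random.default_rng(2)
        cov = np.array([[1.0, 0.6], [0.6, 1.0]])
        L = np.linalg.cholesky(cov)
        X = np.vstack(
            [
                rng.standard_normal((40, 2)) @ L.T + [2.0, 1.0],
                rng.standard_normal((40, 2)) @ L.T - [2.0, 1.0],
            ]
        )
        y = np.repeat([0, 1], 40)
        w = euclidean_lda_reference(X, y, 1)[:, 0]

        mu = X.mean(0)
        Sb = np.zeros((2, 2))
        for k in (0, 1):
            d = X[y == k].mean(0) - mu
            Sb += 40 * np.outer(d, d)
        Xc = X - mu
        St = Xc.T @ Xc

        def quot(v):
            return (v @ Sb @ v) / (v @ St @ v)

        angles = np.linspace(0, np.pi, 20_000)
        best = max(quot(np.array([np.cos(a), np.sin(a)])) for a in angles)
        assert quot(w / np.linalg.norm(w)) >= best - 1e-6
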