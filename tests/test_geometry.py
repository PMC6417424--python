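"""Projections, normals, shape operators, classifiers and the Lambda map."""

import numpy as np
import pytest

from shellmatch.geometry import (
    classify_curvature,
    compute_unit_normals,
    estimate_shape_operator,
    estimate_shape_operators,
    extended_shape_operator,
    lambda_factor,
    rotation_to,
    spd_sqrt_invsqrt,
    tangent_projection,
    tangential_derivative,
)
from shellmatch.grid import AdaptiveGrid, ScalarField, refine_around_surfaces
from shellmatch.shapes import circle, sphere


def unit(rng, n):
    v = rng.standard_normal(n)
    return v / np.linalg.norm(v)


def block_spd(rng, nv):
    n = len(nv)
    P = tangent_projection(nv)
    G = rng.standard_normal((n, n))
    return P @ (G @ G.T + 3 * np.eye(n)) @ P + np.outer(nv, nv)


def matching_A(rng, M, N, n1, n2):
    """A with A P1 = P2 A satisfying the curvature matching condition."""
    P1, P2 = tangent_projection(n1), tangent_projection(n2)
    R = rotation_to(n2) @ rotation_to(n1).T  # rotation with R n1 = n2
    _, Nir = spd_sqrt_invsqrt(N)
    Mr, _ = spd_sqrt_invsqrt(M)
    return P2 @ Nir @ P2 @ R @ P1 @ Mr @ P1 + np.outer(n2, n1)


class TestProjection:
    def test_axis_case(self):
        assert np.allclose(tangent_projection(np.array([0.0, 1.0])), np.diag([1.0, 0.0]))

    def test_idempotent_symmetric_rank(self, rng):
        for n in (2, 3):
            e = unit(rng, n)
            P = tangent_projection(e)
            assert np.allclose(P @ P, P, atol=1e-14)
            assert np.allclose(P, P.T)
            assert np.allclose(P @ e, 0, atol=1e-14)
            assert np.linalg.matrix_rank(P) == n - 1

    def test_lipschitz_bound(self, rng):
        # |P(e) - P(f)| <= 2 sqrt(n) |e - f|
        for n in (2, 3):
            for _ in range(50):
                e, f = unit(rng, n), unit(rng, n)
                lhs = np.linalg.norm(tangent_projection(e) - tangent_projection(f))
                assert lhs <= 2 * np.sqrt(n) * np.linalg.norm(e - f) + 1e-12

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError):
            tangent_projection(np.array([1.0, 1.0]))


class TestRotationTo:
    def test_maps_en_and_proper(self, rng):
        for n in (2, 3):
            for _ in range(50):
                e = unit(rng, n)
                Q = rotation_to(e)
                en = np.zeros(n)
                en[-1] = 1.0
                assert np.allclose(Q @ en, e, atol=1e-12)
                assert abs(np.linalg.det(Q) - 1.0) < 1e-12
        # near +-e_n as well
        for sign in (1.0, -1.0):
            e = np.array([1e-9, 0.0, sign])
            e /= np.linalg.norm(e)
            Q = rotation_to(e)
            assert np.allclose(Q @ [0, 0, 1], e, atol=1e-8)
            assert abs(np.linalg.det(Q) - 1.0) < 1e-12


class TestBlockIdentity:
    def test_det_and_norm_reduce_to_block(self, rng):
        # for B with w in ker B and im B in v-perp:
        # det(B + v x w) = det(B~), |B + v x w|^2 = 1 + |B~|^2
        for n in (2, 3):
            for _ in range(30):
                v, w = unit(rng, n), unit(rng, n)
                B = tangent_projection(v) @ rng.standard_normal((n, n)) @ tangent_projection(w)
                M = B + np.outer(v, w)
                T = rotation_to(v).T @ M @ rotation_to(w)
                Bt = T[: n - 1, : n - 1]
                assert np.allclose(T[-1, -1], 1.0, atol=1e-12)
                assert np.allclose(np.linalg.det(M), np.linalg.det(Bt), atol=1e-12)
                assert np.allclose(
                    np.sum(M * M), 1 + np.sum(Bt * Bt), atol=1e-12
                )


class TestTangentialDerivative:
    def test_identity_case(self, rng):
        e = unit(rng, 3)
        out = tangential_derivative(np.eye(3), e, e)
        assert np.allclose(out, tangent_projection(e))

    def test_annihilation(self, rng):
        for n in (2, 3):
            n1, n2 = unit(rng, n), unit(rng, n)
            D = rng.standard_normal((n, n))
            out = tangential_derivative(D, n1, n2)
            assert np.abs(out @ n1).max() < 1e-14
            assert np.abs(n2 @ out).max() < 1e-14

    def test_perpendicular_normals_degenerate(self):
        # target normal tangent to the source level set: the extended map
        # P2 1 P1 + n2 x n1 is singular
        n1 = np.array([1.0, 0.0])
        n2 = np.array([0.0, 1.0])
        ext = tangential_derivative(np.eye(2), n1, n2) + np.outer(n2, n1)
        assert abs(np.linalg.det(ext)) < 1e-14

    def test_extended_cauchy_green_identity(self, rng):
        # (D_tg + n2 x n1)^T (D_tg + n2 x n1) = D_tg^T D_tg + n1 x n1
        for n in (2, 3):
            for _ in range(20):
                n1, n2 = unit(rng, n), unit(rng, n)
                D = rng.standard_normal((n, n))
                Dtg = tangential_derivative(D, n1, n2)
                E = Dtg + np.outer(n2, n1)
                assert np.allclose(
                    E.T @ E, Dtg.T @ Dtg + np.outer(n1, n1), atol=1e-13
                )


class TestExtendedOperator:
    def test_zero_operator(self, rng):
        e = unit(rng, 3)
        assert np.allclose(extended_shape_operator(np.zeros((3, 3)), e), np.outer(e, e))

    def test_projection_becomes_identity(self):
        e2 = np.array([0.0, 1.0])
        S = tangent_projection(e2)
        assert np.allclose(extended_shape_operator(S, e2), np.eye(2))

    def test_normal_is_unit_eigenvector(self, rng):
        for _ in range(20):
            e = unit(rng, 3)
            S = rng.standard_normal((3, 3))
            S = 0.5 * (S + S.T)
            out = extended_shape_operator(S, e)
            assert np.abs(out @ e - e).max() < 1e-14


class TestClassifier:
    def test_truncated_abs_printed_rule(self):
        out = classify_curvature(np.diag([2.0, -0.5]), "abs", 1.0)
        assert np.allclose(out, np.diag([2.0, 1.0]), atol=1e-14)

    def test_spd_above_tau_is_fixed_point(self, rng):
        G = rng.standard_normal((3, 3))
        B = G @ G.T + 2 * np.eye(3)  # eigenvalues >= 2 > tau
        assert np.allclose(classify_curvature(B, "abs", 1.0), B, atol=1e-12)

    def test_rotation_equivariance(self, rng):
        for n in (2, 3):
            for _ in range(20):
                B = rng.standard_normal((n, n))
                B = 0.5 * (B + B.T)
                Q = rotation_to(unit(rng, n))
                lhs = classify_curvature(Q.T @ B @ Q, "abs", 0.7)
                rhs = Q.T @ classify_curvature(B, "abs", 0.7) @ Q
                assert np.abs(lhs - rhs).max() < 1e-10

    def test_shift_variant_and_insufficient_shift(self):
        B = np.diag([1.0, -2.0])
        out = classify_curvature(B, "shift", 3.0)
        assert np.allclose(out, np.diag([4.0, 1.0]))
        with pytest.raises(ValueError):
            classify_curvature(B, "shift", 1.0)


class TestSqrt:
    def test_diagonal_cases(self):
        r, ir = spd_sqrt_invsqrt(np.eye(3))
        assert np.allclose(r, np.eye(3)) and np.allclose(ir, np.eye(3))
        r, ir = spd_sqrt_invsqrt(np.diag([4.0, 1.0]))
        assert np.allclose(r, np.diag([2.0, 1.0]))
        assert np.allclose(ir, np.diag([0.5, 1.0]))

    def test_random_spd_residual(self, rng):
        for _ in range(20):
            G = rng.standard_normal((3, 3))
            C = G @ G.T + 0.5 * np.eye(3)
            r, ir = spd_sqrt_invsqrt(C)
            assert np.linalg.norm(r @ r - C) / np.linalg.norm(C) < 1e-10
            assert np.linalg.norm(r @ ir - np.eye(3)) < 1e-10

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            spd_sqrt_invsqrt(np.array([[1.0, 1.0], [0.0, 1.0]]))


class TestLambdaFactor:
    def test_rotation_case(self, rng):
        for n in (2, 3):
            n1 = unit(rng, n)
            Q = rotation_to(unit(rng, n)) @ rotation_to(unit(rng, n)).T
            n2 = Q @ n1
            L = lambda_factor(np.eye(n), np.eye(n), Q, n1, n2)
            assert np.allclose(L, Q, atol=1e-12)

    def test_identity_case(self, rng):
        n1 = unit(rng, 3)
        M = block_spd(rng, n1)
        L = lambda_factor(M, M, np.eye(3), n1, n1)
        assert np.allclose(L, np.eye(3), atol=1e-10)

    @pytest.mark.parametrize("n", [2, 3])
    def test_orthogonality_iff_matching(self, n, rng):
        """Both directions of the curvature-matching equivalence, 100x."""
        for _ in range(100):
            n1, n2 = unit(rng, n), unit(rng, n)
            M, N = block_spd(rng, n1), block_spd(rng, n2)
            A = matching_A(rng, M, N, n1, n2)
            P1, P2 = tangent_projection(n1), tangent_projection(n2)
            # A satisfies the compatibility and matching conditions
            assert np.abs(A @ P1 - P2 @ A).max() < 1e-10
            assert np.abs(A.T @ P2 @ N @ P2 @ A - P1 @ M @ P1).max() < 1e-8
            L = lambda_factor(M, N, A, n1, n2)
            assert np.abs(L.T @ L - np.eye(n)).max() < 1e-10
            # a perturbed A violating the matching condition gives a
            # non-orthogonal Lambda
            A2 = A + 0.3 * P2 @ rng.standard_normal((n, n)) @ P1
            if np.abs(A2.T @ P2 @ N @ P2 @ A2 - P1 @ M @ P1).max() > 1e-3:
                L2 = lambda_factor(M, N, A2, n1, n2)
                assert np.abs(L2.T @ L2 - np.eye(n)).max() > 1e-6


class TestDiscreteRecovery:
    def test_affine_distance_normals_exact(self):
        g = AdaptiveGrid(2, level=4)
        d = ScalarField.from_function(g, lambda X: X[:, 0] - 0.5)
        nf = compute_unit_normals(d)
        assert np.allclose(nf.coeffs, [[1.0, 0.0]], atol=1e-12)

    def test_circle_normals_on_band(self):
        C = circle((0.5, 0.5), 0.25)
        g = refine_around_surfaces(AdaptiveGrid(2, level=4), [(C.sdf, 0.06)], 6)
        d = ScalarField.from_function(g, lambda X: C.sdf(X))
        nf = compute_unit_normals(d)
        pos = g.dof_positions
        rho = np.linalg.norm(pos - 0.5, axis=1)
        band = np.abs(rho - 0.25) < 0.04
        exact = (pos[band] - 0.5) / rho[band, None]
        assert np.abs(nf.coeffs[band] - exact).max() < 10 * 2.0**-6
        assert np.allclose(np.linalg.norm(nf.coeffs[band], axis=1), 1.0, atol=1e-12)

    def test_exact_quadratic_recovery(self):
        g = AdaptiveGrid(2, level=4)
        d = ScalarField.from_function(
            g, lambda X: 1.3 * X[:, 0] ** 2 - 0.4 * X[:, 0] * X[:, 1] + 0.7 * X[:, 1] ** 2
        )
        H = estimate_shape_operator(d, 60)
        assert np.allclose(H, [[2.6, -0.4], [-0.4, 1.4]], atol=1e-9)

    def test_circle_curvature_spectrum(self):
        C = circle((0.5, 0.5), 0.25)
        lvl = 6
        g = refine_around_surfaces(AdaptiveGrid(2, level=4), [(C.sdf, 0.06)], lvl)
        d = ScalarField.from_function(g, lambda X: C.sdf(X))
        pos = g.dof_positions
        rho = np.linalg.norm(pos - 0.5, axis=1)
        band = np.flatnonzero(np.abs(rho - 0.25) < 0.03)
        S = estimate_shape_operators(d, band)
        ev = np.sort(np.linalg.eigvalsh(S), axis=1)
        # eigenvalues {1/rho, 0} within O(h)
        assert np.abs(ev[:, 1] - 1.0 / rho[band]).max() < 8 * 2.0**-lvl
        assert np.abs(ev[:, 0]).max() < 8 * 2.0**-lvl

    def test_sphere_curvature_spectrum(self):
        S3 = sphere((0.5, 0.5, 0.5), 0.3)
        lvl = 4
        g = refine_around_surfaces(AdaptiveGrid(3, level=3), [(S3.sdf, 0.1)], lvl)
        d = ScalarField.from_function(g, lambda X: S3.sdf(X))
        pos = g.dof_positions
        rho = np.linalg.norm(pos - 0.5, axis=1)
        band = np.flatnonzero(np.abs(rho - 0.3) < 0.03)
        S = estimate_shape_operators(d, band)
        ev = np.sort(np.linalg.eigvalsh(S), axis=1)
        assert np.abs(ev[:, 1:] - 1.0 / rho[band, None]).max() < 8 * 2.0**-lvl
        assert np.abs(ev[:, 0]).max() < 8 * 2.0**-lvl
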