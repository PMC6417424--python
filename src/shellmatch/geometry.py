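"""Differential geometry of level sets derived from signed distance fields.

For a signed distance function ``d`` the gradient ``n = grad d`` is the
outward unit normal of the offset surfaces, and the Hessian ``S = D^2 d`` is
their shape operator (principal curvatures and directions, with ``S n = 0``).
This module recovers these fields from discrete data:

* unit normals by a lumped-mass L2 projection of the finite element gradient
  onto nodal multilinear functions, followed by normalization;
* shape operators as Hessians of moving least-squares quadratic fits over
  the ``r`` nearest degrees of freedom of each node;
* the *extended* shape operator ``S_ext = P S P + n (x) n`` (the normal
  direction is completed with eigenvalue one so the operator can be
  inverted), its SPD *classification* (eigenvalue shift, or truncated
  absolute value ``|lambda|_tau = max(|lambda|, tau)``), and matrix square
  roots, all batched over nodes;
* the tangential derivative ``P2 Dphi P1`` and the orthogonality
  factorization ``Lambda[M, N, A] = P2 N^1/2 P2 A P1 M^-1/2 P1 + n2 (x) n1``
  whose orthogonality is equivalent to the curvature matching condition
  ``A^T P2 N P2 A = P1 M P1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .grid import ScalarField, VectorField

__all__ = [
    "GeometryFields",
    "tangent_projection",
    "compute_unit_normals",
    "estimate_shape_operator",
    "estimate_shape_operators",
    "extended_shape_operator",
    "classify_curvature",
    "spd_sqrt_invsqrt",
    "tangential_derivative",
    "lambda_factor",
    "rotation_to",
    "build_geometry_fields",
]


# ----------------------------------------------------------------------
# pointwise linear algebra (batched: leading axes arbitrary)
# ----------------------------------------------------------------------
def tangent_projection(e: np.ndarray) -> np.ndarray:
    """P(e) = 1 - e (x) e, the projection onto the hyperplane e-perp."""
    e = np.asarray(e, dtype=float)
    nrm = np.linalg.norm(e, axis=-1)
    if not np.allclose(nrm, 1.0, atol=1e-8):
        raise ValueError("projection direction must be a unit vector")
    eye = np.eye(e.shape[-1])
    return eye - e[..., :, None] * e[..., None, :]


def rotation_to(e: np.ndarray) -> np.ndarray:
    """A proper rotation Q with Q e_n = e (Householder + sign fix).

    The choice is not unique; downstream quantities (determinants, Frobenius
    norms of rotated blocks) are invariant to it.
    """
    e = np.asarray(e, dtype=float)
    n = e.shape[-1]
    if abs(np.linalg.norm(e) - 1.0) > 1e-8:
        raise ValueError("target direction must be unit length")
    en = np.zeros(n)
    en[-1] = 1.0
    v = e - en
    if np.linalg.norm(v) < 1e-14:
        return np.eye(n)
    H = np.eye(n) - 2.0 * np.outer(v, v) / (v @ v)  # reflection: H e_n = e
    # compose with a flip in the first coordinate to restore det = +1
    F = np.eye(n)
    F[0, 0] = -1.0
    Q = H @ F
    if np.linalg.det(Q) < 0:  # pragma: no cover - defensive
        Q = H
    return Q


def extended_shape_operator(S: np.ndarray, n_vec: np.ndarray) -> np.ndarray:
    """S_ext = P S P + n (x) n; has n as eigenvector with eigenvalue 1."""
    P = tangent_projection(n_vec)
    nn = n_vec[..., :, None] * n_vec[..., None, :]
    return P @ S @ P + nn


def classify_curvature(B: np.ndarray, variant: str = "abs", parameter: float = 1.0):
    """SPD classification of a symmetric matrix (batched).

    ``variant='shift'``: B + mu*1 with mu a strict upper bound for -lambda_min.
    ``variant='abs'``:  eigenvalues mapped through max(|lambda|, tau).
    """
    B = np.asarray(B, dtype=float)
    if not np.allclose(B, np.swapaxes(B, -1, -2), atol=1e-8):
        raise ValueError("classification input must be symmetric")
    if variant == "shift":
        lam = np.linalg.eigvalsh(B)
        if np.any(lam[..., 0] + parameter <= 0):
            raise ValueError("shift parameter is not a strict lower curvature bound")
        return B + parameter * np.eye(B.shape[-1])
    if variant != "abs":
        raise ValueError(f"unknown classifier variant {variant!r}")
    lam, Q = np.linalg.eigh(0.5 * (B + np.swapaxes(B, -1, -2)))
    lam = np.maximum(np.abs(lam), parameter)
    return np.einsum("...ik,...k,...jk->...ij", Q, lam, Q)


def spd_sqrt_invsqrt(C: np.ndarray, truncation: float = 1e-12):
    """Matrix square root and inverse square root of (clamped) SPD matrices."""
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, np.swapaxes(C, -1, -2), atol=1e-8):
        raise ValueError("matrix square root input must be symmetric")
    lam, Q = np.linalg.eigh(C)
    lam = np.maximum(lam, truncation)
    s = np.sqrt(lam)
    root = np.einsum("...ik,...k,...jk->...ij", Q, s, Q)
    invroot = np.einsum("...ik,...k,...jk->...ij", Q, 1.0 / s, Q)
    return root, invroot


def tangential_derivative(Dphi: np.ndarray, n1: np.ndarray, n2: np.ndarray):
    """D_tg phi = P(n2) Dphi P(n1): tangential variation onto the target."""
    P1 = tangent_projection(n1)
    P2 = tangent_projection(n2)
    return P2 @ Dphi @ P1


def lambda_factor(M, N, A, n1, n2, truncation: float = 1e-12) -> np.ndarray:
    """Lambda[M, N, A] = P2 N^1/2 P2 A P1 M^-1/2 P1 + n2 (x) n1 (batched).

    For block-structured SPD M, N (normal direction an eigenvector with
    eigenvalue 1) and A with A P1 = P2 A, orthogonality of the result is
    equivalent to the curvature matching condition A^T P2 N P2 A = P1 M P1.
    """
    P1 = tangent_projection(n1)
    P2 = tangent_projection(n2)
    Nr, _ = spd_sqrt_invsqrt(N, truncation)
    _, Mir = spd_sqrt_invsqrt(M, truncation)
    n2n1 = np.asarray(n2)[..., :, None] * np.asarray(n1)[..., None, :]
    return P2 @ Nr @ P2 @ A @ P1 @ Mir @ P1 + n2n1


# ----------------------------------------------------------------------
# discrete geometry recovery
# ----------------------------------------------------------------------
def compute_unit_normals(d: ScalarField) -> VectorField:
    """Nodal unit normals: lumped L2 projection of the FE gradient.

    Nodes where the projected gradient vanishes (distance-function skeleton)
    keep a zero vector and are flagged in ``normals.skeleton``.
    """
    g = d.grid
    X, w, _ = g.quadrature()
    B_val, B_grad = g.assembly_matrices(X)
    grads = np.stack([Bg @ d.coeffs for Bg in B_grad], axis=1)  # (m, dim)
    mass = B_val.T @ w
    num = B_val.T @ (grads * w[:, None])
    nod = num / np.maximum(mass, 1e-300)[:, None]
    nrm = np.linalg.norm(nod, axis=1)
    skeleton = nrm < 1e-10
    nod[~skeleton] /= nrm[~skeleton, None]
    out = VectorField(g, nod)
    out.skeleton = skeleton
    return out


_QUAD_MONOMIALS = {
    2: [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)],
    3: [
        (0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1),
    ],
}


def _hessian_from_quadratic(dim: int, c: np.ndarray) -> np.ndarray:
    """Hessian of the quadratic with monomial coefficients c (batched)."""
    if dim == 2:
        H = np.empty(c.shape[:-1] + (2, 2))
        H[..., 0, 0] = 2 * c[..., 3]
        H[..., 1, 1] = 2 * c[..., 5]
        H[..., 0, 1] = H[..., 1, 0] = c[..., 4]
        return H
    H = np.empty(c.shape[:-1] + (3, 3))
    H[..., 0, 0] = 2 * c[..., 4]
    H[..., 1, 1] = 2 * c[..., 5]
    H[..., 2, 2] = 2 * c[..., 6]
    H[..., 0, 1] = H[..., 1, 0] = c[..., 7]
    H[..., 0, 2] = H[..., 2, 0] = c[..., 8]
    H[..., 1, 2] = H[..., 2, 1] = c[..., 9]
    return H


def _lstsq_hessians(P0, Pnbr, vals, dim):
    """Batched quadratic least-squares fit; returns Hessians and condition."""
    mono = _QUAD_MONOMIALS[dim]
    dx = Pnbr - P0[:, None, :]  # (N, r, dim)
    scale = np.maximum(np.abs(dx).max(axis=(1, 2)), 1e-300)
    dxs = dx / scale[:, None, None]
    cols = [np.prod([dxs[..., d] ** m[d] for d in range(dim)], axis=0) for m in mono]
    Adm = np.stack(cols, axis=-1)  # (N, r, n_mono)
    AtA = np.einsum("nrm,nrk->nmk", Adm, Adm)
    Atb = np.einsum("nrm,nr->nm", Adm, vals)
    # guard rank deficiency via eigenvalue floor
    lam = np.linalg.eigvalsh(AtA)
    cond = lam[:, -1] / np.maximum(lam[:, 0], 1e-300)
    c = np.linalg.solve(AtA + 1e-12 * np.eye(len(mono)), Atb[..., None])[..., 0]
    H = _hessian_from_quadratic(dim, c)
    # undo coordinate scaling: quadratic coeffs scale like 1/scale^2
    return H / scale[:, None, None] ** 2, cond


def estimate_shape_operators(
    d: ScalarField, nodes: np.ndarray | None = None, r: int | None = None
) -> np.ndarray:
    """Hessians of d at DOF nodes via r-nearest-neighbour quadratic fits."""
    g = d.grid
    dim = g.dim
    if r is None:
        r = 12 if dim == 2 else 30
    n_mono = len(_QUAD_MONOMIALS[dim])
    if nodes is None:
        nodes = np.arange(g.n_dof)
    P = g.dof_positions
    tree = cKDTree(P)
    kmax = min(g.n_dof, r + 1)
    if kmax < n_mono:
        raise ValueError("not enough degrees of freedom for a quadratic fit")
    _, idx = tree.query(P[nodes], k=kmax)
    H, cond = _lstsq_hessians(P[nodes], P[idx], d.coeffs[idx], dim)
    bad = cond > 1e10
    if np.any(bad):
        k2 = min(g.n_dof, 2 * r + 1)
        _, idx2 = tree.query(P[nodes[bad]], k=k2)
        H2, cond2 = _lstsq_hessians(P[nodes[bad]], P[idx2], d.coeffs[idx2], dim)
        if np.any(cond2 > 1e12):
            raise RuntimeError("rank-deficient quadratic fit even after enlarging r")
        H[bad] = H2
    return H


def estimate_shape_operator(d: ScalarField, node: int, r: int | None = None):
    return estimate_shape_operators(d, np.array([node]), r)[0]


@dataclass
class GeometryFields:
    """Per-DOF geometric coefficients of one signed distance field."""

    normals: VectorField              # unit normals n (zero on skeleton nodes)
    shape_ops: np.ndarray             # (N, n, n) Hessians D^2 d
    extended_ops: np.ndarray          # (N, n, n) P S P + n (x) n
    classified: np.ndarray            # (N, n, n) SPD classification C(S_ext)
    sqrt_classified: np.ndarray       # C^{1/2}
    invsqrt_classified: np.ndarray    # C^{-1/2}
    classifier: tuple = ("abs", 1.0)

    @property
    def grid(self):
        return self.normals.grid


def build_geometry_fields(
    d: ScalarField,
    r: int | None = None,
    classifier: tuple = ("abs", 1.0),
    sqrt_truncation: float | None = None,
) -> GeometryFields:
    """All nodal geometry coefficients for one distance field."""
    variant, param = classifier
    if sqrt_truncation is None:
        sqrt_truncation = param / 10.0 if variant == "abs" else 1e-8
    normals = compute_unit_normals(d)
    S = estimate_shape_operators(d, r=r)
    nvals = normals.coeffs.copy()
    # skeleton nodes get an arbitrary unit direction; they never enter band
    # integrals because eta vanishes there
    bad = np.linalg.norm(nvals, axis=1) < 0.5
    nvals[bad] = 0.0
    nvals[bad, 0] = 1.0
    Sext = extended_shape_operator(S, nvals)
    C = classify_curvature(Sext, variant, param)
    Cs, Cis = spd_sqrt_invsqrt(C, sqrt_truncation)
    return GeometryFields(normals, S, Sext, C, Cs, Cis, classifier)
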