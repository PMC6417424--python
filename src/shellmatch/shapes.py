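"""Analytic fixtures and validation probes.

Provides closed shapes with exact signed distances (circle, ellipse,
rounded rectangle, sphere, ellipsoid), the tangentially isometric
oscillation curves that exhibit the lower-semicontinuity failure of the
naive membrane energy, the rank-one segment probing rank-one convexity of
the naive density, the normal-extension construction that transports a
surface diffeomorphism to the narrow band, and rigid-motion test pairs
with their ground-truth deformations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import ellipe

from .energies import cutoff_eta, membrane_density_W
from .grid import AdaptiveGrid, VectorField

__all__ = [
    "AnalyticShape",
    "circle",
    "ellipse",
    "rounded_rectangle",
    "sphere",
    "ellipsoid",
    "OscillationCurve",
    "oscillation_curve",
    "oscillation_r0",
    "oscillation_band_energies",
    "radial_map",
    "rank_one_probe",
    "normal_extension_deformation",
    "rigid_pair",
]


# ----------------------------------------------------------------------
# conic foot points (shared by ellipse and ellipsoid)
# ----------------------------------------------------------------------
def _conic_foot(Xc: np.ndarray, radii: np.ndarray, iters: int = 80):
    """Foot points on the axis-aligned ellipse/ellipsoid sum(x_i/a_i)^2 = 1.

    Solves sum_i (a_i x_i / (t + a_i^2))^2 = 1 for t > -min(a_i^2) by
    bisection refined with Newton; the foot is y_i = a_i^2 x_i/(t + a_i^2).
    Robust for interior and exterior points including the axes.
    """
    X = np.abs(np.asarray(Xc, dtype=float))
    # perturb exact zeros off the symmetry axes so the foot equation is
    # well posed (the centre and the axes are in the skeleton)
    X = np.maximum(X, 1e-13)
    a = np.asarray(radii, dtype=float)
    a2 = a * a

    def F(t):
        return np.sum((a[None, :] * X / (t[:, None] + a2[None, :])) ** 2, axis=1) - 1.0

    lo = np.full(len(X), -a2.min() + 1e-14)
    # F is decreasing in t; F(lo) -> +inf (unless degenerate), F(inf) -> -1
    hi = np.linalg.norm(a[None, :] * X, axis=1) + a2.max()
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        pos = F(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    t = 0.5 * (lo + hi)
    foot = a2[None, :] * X / (t[:, None] + a2[None, :])
    sgn = np.where(np.asarray(Xc, dtype=float) < 0, -1.0, 1.0)
    return foot * sgn


@dataclass
class AnalyticShape:
    """Closed shape with exact signed distance (negative inside)."""

    kind: str
    center: np.ndarray
    params: dict
    dim: int

    # -- distances -----------------------------------------------------
    def sdf(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xc = X - self.center
        if self.kind in ("circle", "sphere"):
            return np.linalg.norm(Xc, axis=1) - self.params["radius"]
        if self.kind in ("ellipse", "ellipsoid"):
            radii = np.asarray(self.params["radii"])
            foot = _conic_foot(Xc, radii)
            d = np.linalg.norm(Xc - foot, axis=1)
            inside = np.sum((Xc / radii) ** 2, axis=1) < 1.0
            return np.where(inside, -d, d)
        if self.kind == "rounded_rectangle":
            half = np.asarray(self.params["half_extents"])
            r = self.params["corner_radius"]
            q = np.abs(Xc) - (half - r)
            outer = np.linalg.norm(np.maximum(q, 0.0), axis=1)
            inner = np.minimum(q.max(axis=1), 0.0)
            return outer + inner - r
        raise ValueError(f"unknown shape kind {self.kind!r}")

    def normal(self, X: np.ndarray) -> np.ndarray:
        """Outward unit normal of the offset surface through each point."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xc = X - self.center
        if self.kind in ("circle", "sphere"):
            n = Xc / np.maximum(np.linalg.norm(Xc, axis=1, keepdims=True), 1e-300)
            return n
        if self.kind in ("ellipse", "ellipsoid"):
            radii = np.asarray(self.params["radii"])
            foot = _conic_foot(Xc, radii)
            g = foot / radii**2  # gradient of the implicit function at the foot
            return g / np.maximum(np.linalg.norm(g, axis=1, keepdims=True), 1e-300)
        # generic fallback: normalized FD gradient of the distance
        eps = 1e-7
        G = np.zeros_like(X)
        for d in range(self.dim):
            e = np.zeros(self.dim)
            e[d] = eps
            G[:, d] = (self.sdf(X + e) - self.sdf(X - e)) / (2 * eps)
        return G / np.maximum(np.linalg.norm(G, axis=1, keepdims=True), 1e-300)

    def foot_point(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X - self.sdf(X)[:, None] * self.normal(X)

    # -- discretizations -------------------------------------------------
    def polygon(self, m: int = 1024) -> np.ndarray:
        if self.dim != 2:
            raise ValueError("polygon() is for 2D shapes")
        t = np.linspace(0, 2 * np.pi, m, endpoint=False)
        if self.kind == "circle":
            r = self.params["radius"]
            pts = np.c_[r * np.cos(t), r * np.sin(t)]
        elif self.kind == "ellipse":
            a, b = self.params["radii"]
            pts = np.c_[a * np.cos(t), b * np.sin(t)]
        elif self.kind == "rounded_rectangle":
            raw = np.c_[np.cos(t), np.sin(t)] * (
                np.max(self.params["half_extents"]) * 2.0
            )
            pts = _conic_like_project(self, raw)
        else:
            raise ValueError(self.kind)
        return pts + self.center

    def mesh(self, subdivisions: int = 4):
        if self.dim != 3:
            raise ValueError("mesh() is for 3D shapes")
        import trimesh

        m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        if self.kind == "sphere":
            verts = m.vertices * self.params["radius"]
        elif self.kind == "ellipsoid":
            verts = m.vertices * np.asarray(self.params["radii"])
        else:
            raise ValueError(self.kind)
        return trimesh.Trimesh(verts + self.center, m.faces, process=False)


def _conic_like_project(shape: AnalyticShape, raw: np.ndarray) -> np.ndarray:
    """Project ray samples onto the zero level set by bisection along rays."""
    out = np.empty_like(raw)
    for i, p in enumerate(raw):
        lo, hi = 0.0, 1.0
        f = lambda s: shape.sdf((shape.center + s * p)[None, :])[0]
        while f(hi) < 0:
            hi *= 1.5
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        out[i] = 0.5 * (lo + hi) * p
    return out


def circle(center=(0.5, 0.5), radius=0.25) -> AnalyticShape:
    return AnalyticShape("circle", np.asarray(center, dtype=float), {"radius": radius}, 2)


def ellipse(center=(0.5, 0.5), radii=(0.3, 0.18)) -> AnalyticShape:
    return AnalyticShape("ellipse", np.asarray(center, dtype=float), {"radii": np.asarray(radii, dtype=float)}, 2)


def rounded_rectangle(center=(0.5, 0.5), half_extents=(0.3, 0.2), corner_radius=0.05):
    return AnalyticShape(
        "rounded_rectangle",
        np.asarray(center, dtype=float),
        {"half_extents": np.asarray(half_extents, dtype=float), "corner_radius": corner_radius},
        2,
    )


def sphere(center=(0.5, 0.5, 0.5), radius=0.25) -> AnalyticShape:
    return AnalyticShape("sphere", np.asarray(center, dtype=float), {"radius": radius}, 3)


def ellipsoid(center=(0.5, 0.5, 0.5), radii=(0.3, 0.22, 0.18)) -> AnalyticShape:
    return AnalyticShape("ellipsoid", np.asarray(center, dtype=float), {"radii": np.asarray(radii, dtype=float)}, 3)


# ----------------------------------------------------------------------
# oscillation curves (tangentially isometric, weakly converging to a circle)
# ----------------------------------------------------------------------
@dataclass
class OscillationCurve:
    xi: np.ndarray        # parameter samples in [0, 2*pi)
    points: np.ndarray    # curve samples (unit-speed parametrization)
    tangents: np.ndarray  # unit tangents d(point)/d(xi)
    r0: float             # radius of the weak-limit circle
    R: float
    k: int

    def closure_gap(self) -> float:
        end = self.points[0] + _osc_increment(self.R, self.k, self.xi[0], 2 * np.pi)
        return float(np.linalg.norm(end - self.points[0]))


def _osc_tangent(R: float, k: int, xi):
    xi = np.asarray(xi, dtype=float)
    er = np.stack([np.cos(xi), np.sin(xi)], axis=-1)
    et = np.stack([-np.sin(xi), np.cos(xi)], axis=-1)
    s = R * np.sin(k * xi)
    c = np.sqrt(np.maximum(1.0 - s * s, 0.0))
    return s[..., None] * er + c[..., None] * et


def _osc_increment(R, k, a, b, steps_per_unit=2000):
    n = max(64, int(np.ceil((b - a) * steps_per_unit)))
    # composite Simpson quadrature of the explicit tangent field
    t = np.linspace(a, b, 2 * n + 1)
    f = _osc_tangent(R, k, t)
    h = (b - a) / (2 * n)
    w = np.ones(2 * n + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return h / 3.0 * np.einsum("m,md->d", w, f)


def oscillation_r0(R: float) -> float:
    """Mean tangential speed (2/pi) E(R): radius of the weak-limit circle."""
    return float(2.0 / np.pi * ellipe(R * R))  # scipy's E takes the parameter m


def oscillation_curve(R: float, k: int, samples: int | None = None) -> OscillationCurve:
    """Closed unit-speed curve whose tangent oscillates radially.

    The tangent field is ``R sin(k xi) e_r(xi) + sqrt(1 - R^2 sin^2(k xi))
    e_theta(xi)`` in the polar frame of the source circle parametrization;
    for integer ``k >= 2`` the curve closes exactly (the radial term has
    zero average and the tangential speed only carries harmonics of order
    2k) and converges, as k grows, to the circle of radius ``r0`` in
    Hausdorff distance but not in tangent direction.
    """
    if not (0 <= R < 1):
        raise ValueError("oscillation amplitude must satisfy 0 <= R < 1")
    if k < 2:
        raise ValueError("need k >= 2 for a closed curve")
    if samples is None:
        samples = max(200 * k, 2000)
    r0 = oscillation_r0(R)
    # cumulative Simpson integral of the tangent field on a fine grid
    from scipy.integrate import cumulative_simpson

    fine = 8 * samples
    t = np.linspace(0.0, 2 * np.pi, fine + 1)
    f = _osc_tangent(R, k, t)
    cum = np.stack(
        [cumulative_simpson(f[:, d], x=t, initial=0.0) for d in range(2)], axis=1
    )
    start = np.array([r0, 0.0])
    pts_fine = start + cum
    idx = np.linspace(0, fine, samples, endpoint=False).astype(int)
    xi = t[idx]
    return OscillationCurve(xi, pts_fine[idx], _osc_tangent(R, k, xi), r0, R, k)


def _osc_alpha_prime(R, k, xi):
    """Derivative of the tangent angle: 1 - d/dxi arcsin(R sin k xi)."""
    s = R * np.sin(k * xi)
    c = np.sqrt(np.maximum(1.0 - s * s, 1e-300))
    return 1.0 - R * k * np.cos(k * xi) / c


def oscillation_band_energies(
    R: float,
    k: int,
    sigma: float,
    lam: float = 1.0,
    mu: float = 1.0,
    n_xi: int | None = None,
    n_r: int = 24,
):
    """Naive membrane band energy of the oscillation map and its weak limit.

    The source surface is the unit circle; both deformations extend along
    offsets of the curve: ``phi_k(r, xi) = curve(xi) + (r-1) * normal(xi)``
    and the weak limit ``phi(r, xi) = r * r0 * e_r(xi)``.  The naive density
    (no projection onto the target tangent space) sees the tangential
    stretch ``(1 + (r-1)(alpha'(xi) - 0))/r`` for the oscillation map and
    the constant ``r0`` for the limit; the energies are integrated in polar
    coordinates with the normalized band cutoff.  ``sigma`` must stay below
    the curve's reach ``~1/(1 + R k)`` for the offset extension to be
    injective.
    """
    max_curv = 1.0 + R * k
    if sigma >= 1.0 / max_curv:
        raise ValueError(
            f"sigma={sigma} exceeds the oscillation curve's reach ~{1.0 / max_curv:.3g}"
        )
    if n_xi is None:
        n_xi = max(400, 80 * k)
    xi = np.linspace(0, 2 * np.pi, n_xi, endpoint=False)
    ap = _osc_alpha_prime(R, k, xi)
    # Gauss-Legendre across the band
    gnodes, gweights = np.polynomial.legendre.leggauss(n_r)
    r = 1.0 + sigma * gnodes
    wr = sigma * gweights

    def naive_W(stretch):
        G = np.zeros(stretch.shape + (2, 2))
        G[..., 0, 0] = stretch**2
        G[..., 1, 1] = 1.0
        return membrane_density_W(G, lam, mu)

    eta = cutoff_eta(r - 1.0, sigma)
    dxi = 2 * np.pi / n_xi
    s_osc = (1.0 + (r[None, :] - 1.0) * ap[:, None]) / r[None, :]
    E_osc = float(
        np.sum(naive_W(s_osc) * eta[None, :] * r[None, :] * wr[None, :]) * dxi
    )
    r0 = oscillation_r0(R)
    s_lim = np.broadcast_to(r0, s_osc.shape)
    E_lim = float(
        np.sum(naive_W(np.asarray(s_lim)) * eta[None, :] * r[None, :] * wr[None, :]) * dxi
    )
    return E_osc, E_lim


# ----------------------------------------------------------------------
# rank-one convexity probe for the naive density
# ----------------------------------------------------------------------
def rank_one_probe(lam: float):
    """Value of the naive tangential density on the rank-one segment.

    ``B(lam) = [[lam, 0], [1-lam, 0]]``; the density is
    ``W_F(B) = F(tr(B^T B), det(B^T B + e2 (x) e2))`` with
    ``F(a, d) = a/2 + d/2 + 1/d - 2``.  Returns ``(B, value)`` where the
    value is computed through the general trace/determinant route; the
    closed form ``t + 1/t - 2`` with ``t = lam^2 + (1-lam)^2`` agrees to
    round-off and is asserted.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lam must lie in [0, 1]")
    B = np.array([[lam, 0.0], [1.0 - lam, 0.0]])
    BtB = B.T @ B
    e2 = np.array([0.0, 1.0])
    a = float(np.trace(BtB))
    d = float(np.linalg.det(BtB + np.outer(e2, e2)))
    value = 0.5 * a + 0.5 * d + 1.0 / d - 2.0
    t = lam**2 + (1 - lam) ** 2
    closed = t + 1.0 / t - 2.0
    if abs(value - closed) > 1e-14 * max(1.0, abs(closed)):
        raise AssertionError("density route disagrees with the closed form")
    return B, value


# ----------------------------------------------------------------------
# normal extension of a surface diffeomorphism to the band
# ----------------------------------------------------------------------
def _smoothstep(t):
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def normal_extension_deformation(
    surface_map: Callable,
    shape1: AnalyticShape,
    shape2: AnalyticShape,
    sigma: float,
    grid: AdaptiveGrid,
) -> VectorField:
    """Extend a surface map ``M1 -> M2`` along normals to the narrow band.

    For a band point ``x = p + s n1(p)`` (foot point decomposition) the
    extension is ``phi(x) = surface_map(p) + s n2(surface_map(p))``, which
    matches all offsets exactly: ``d2(phi(x)) = d1(x)`` within the band.
    Outside ``|d1| <= sigma`` the map is blended smoothly to the identity
    over one extra band width.  ``2 sigma`` must stay below both reaches.
    """
    X = grid.dof_positions
    d1 = shape1.sdf(X)
    blend_out = 2.0 * sigma
    _check_reach(shape1, blend_out)
    _check_reach(shape2, blend_out)
    out = X.copy()
    sel = np.abs(d1) < blend_out
    if np.any(sel):
        foot = shape1.foot_point(X[sel])
        target = np.atleast_2d(surface_map(foot))
        n2 = shape2.normal(target)
        mapped = target + d1[sel, None] * n2
        w = _smoothstep((blend_out - np.abs(d1[sel])) / sigma)[:, None]
        out[sel] = w * mapped + (1.0 - w) * X[sel]
    return VectorField(grid, out)


def _check_reach(shape: AnalyticShape, sigma: float):
    if shape.kind in ("circle", "sphere"):
        reach = shape.params["radius"]
    elif shape.kind in ("ellipse", "ellipsoid"):
        radii = np.asarray(shape.params["radii"])
        reach = float(np.min(radii) ** 2 / np.max(radii))  # min curvature radius
    elif shape.kind == "rounded_rectangle":
        reach = shape.params["corner_radius"]
    else:
        reach = np.inf
    if sigma >= reach:
        raise ValueError(f"band width {sigma} exceeds the shape's reach {reach:.3g}")


def radial_map(shape1: AnalyticShape, shape2: AnalyticShape) -> Callable:
    """Angle-preserving map between two star-shaped fixtures."""

    def f(P):
        P = np.atleast_2d(np.asarray(P, dtype=float))
        U = P - shape1.center
        if shape1.kind == "circle" and shape2.kind == "circle":
            scale = shape2.params["radius"] / shape1.params["radius"]
            return shape2.center + U * scale
        # generic: project the direction onto the target surface
        nrm = np.linalg.norm(U, axis=1, keepdims=True)
        dirs = U / np.maximum(nrm, 1e-300)
        out = np.empty_like(P)
        for i, u in enumerate(dirs):
            lo, hi = 0.0, 1.0
            g = lambda s: shape2.sdf((shape2.center + s * u)[None, :])[0]
            while g(hi) < 0:
                hi *= 1.5
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if g(mid) < 0:
                    lo = mid
                else:
                    hi = mid
            out[i] = shape2.center + 0.5 * (lo + hi) * u
        return out

    return f


# ----------------------------------------------------------------------
# rigid-motion pairs
# ----------------------------------------------------------------------
def rigid_pair(polygon: np.ndarray, angle: float, translation=(0.0, 0.0)):
    """Rotate a 2D polygon about the domain centre and translate it.

    Returns ``(source, target, transform)`` where ``transform`` maps points
    of the source onto the target exactly (the ground-truth deformation for
    recovery metrics).  Raises if the transformed shape leaves the open
    unit square.
    """
    polygon = np.asarray(polygon, dtype=float)
    c = np.full(polygon.shape[1], 0.5)
    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    t = np.asarray(translation, dtype=float)

    def transform(P):
        P = np.atleast_2d(np.asarray(P, dtype=float))
        return (P - c) @ R.T + c + t

    target = transform(polygon)
    if np.any(target <= 0.0) or np.any(target >= 1.0):
        raise ValueError("transformed shape leaves the unit domain")
    return polygon, target, transform
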