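"""Thin-shell matching energies over narrow bands of level sets.

The total energy of a volumetric deformation ``phi: [0,1]^n -> R^n`` is

    E[phi] = E_match + E_mem + E_bend + E_vol

with all surface terms integrated over the narrow band ``{|d1| <= sigma}``
weighted by a normalized smooth cutoff ``eta_sigma(d1)``:

* ``E_match = (1/nu) int eta_sigma(d1) |d2(phi) - d1|^2`` pulls the source
  level sets onto the target ones (penalty, no hard constraint);
* ``E_mem = delta int eta_sigma(d1) W(D_tg phi + n2(phi) (x) n1)`` penalizes
  tangential length/area distortion with a polyconvex density ``W``
  vanishing on SO(n) and calibrated to the Lame-Navier model at the
  identity;
* ``E_bend = delta^3 int eta_sigma(d1) W(Lambda(C1, C2(phi), Dphi))``
  penalizes curvature mismatch through the orthogonality factorization of
  the classified extended shape operators;
* ``E_vol`` regularizes the deformation on the whole domain: either the
  simplified form ``c_vol int W(Dphi)`` (default) or the polyconvex density
  ``alpha |Dphi|^p + beta |Cof Dphi|^q + gamma (det Dphi)^-s`` with the
  +infinity sentinel for non-orientation-preserving deformations.

The discrete energy uses tensor-product 2-point Gauss quadrature per leaf;
cells wholly outside the band are skipped.  Deformed positions are clamped
to the domain (free-boundary handling); clamped coordinates contribute no
gradient.  The gradient is assembled by the chain rule through the sparse
evaluation operators; pointwise derivatives with respect to the deformed
position (through the interpolated target coefficients) use central
differences, all other factors are closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import GeometryFields, classify_curvature, spd_sqrt_invsqrt
from .grid import AdaptiveGrid, ScalarField, VectorField
from .signed_distance import SignedDistanceField

__all__ = [
    "EnergyParams",
    "EnergyBreakdown",
    "ShapePair",
    "EnergyModel",
    "cutoff_eta",
    "membrane_density_W",
    "membrane_density_W_gradient",
    "volume_coefficient_gamma",
    "clamp_to_domain",
    "membrane_energy",
    "bending_energy",
    "matching_energy",
    "volume_energy",
    "total_energy",
    "energy_gradient",
]

_FD_EPS = 1e-6


# ----------------------------------------------------------------------
# parameters
# ----------------------------------------------------------------------
def volume_coefficient_gamma(dim: int, alpha: float, beta: float) -> float:
    """gamma making the polyconvex volume density stationary at rotations:
    (n+1) n^((n-1)/2) (alpha + (n-1) beta) = n^2 gamma."""
    n = dim
    return (n + 1) * n ** ((n - 1) / 2) * (alpha + (n - 1) * beta) / n**2


def _default_volume_params(dim: int):
    # printed calibrations: n=3 -> (4,4,9) alpha=beta=1, gamma=4;
    # n=2 -> (3,3,4) alpha=beta=2, gamma=3*sqrt(2)
    if dim == 3:
        return (4.0, 4.0, 9.0), (1.0, 1.0, 4.0)
    return (3.0, 3.0, 4.0), (2.0, 2.0, 3.0 * np.sqrt(2.0))


@dataclass
class EnergyParams:
    """All model constants.  Lengths are in units of the unit domain."""

    lame_lambda: float = 1.0
    lame_mu: float = 1.0
    shell_thickness: float = 1.0          # delta
    band_width: float = 0.0625            # sigma (2h at level 5)
    penalty: float = 0.002                # nu
    volume_weight: float = 0.025          # c_vol (simplified volume term)
    classifier: tuple = ("abs", 1.0)      # variant, tau or mu-bar
    volume_exponents: tuple | None = None     # (p, q, s)
    volume_coefficients: tuple | None = None  # (alpha_p, beta_q, gamma_s)
    use_full_volume_density: bool = False
    ablate_P2_in_membrane: bool = False
    use_naive_bending: bool = False

    def resolved(self, dim: int) -> "EnergyParams":
        p = self
        if p.volume_exponents is None or p.volume_coefficients is None:
            exps, coefs = _default_volume_params(dim)
            p = replace(
                p,
                volume_exponents=p.volume_exponents or exps,
                volume_coefficients=p.volume_coefficients or coefs,
            )
        p.validate(dim)
        return p

    def validate(self, dim: int) -> None:
        if self.band_width <= 0:
            raise ValueError("band width sigma must be positive")
        if self.penalty <= 0:
            raise ValueError("matching penalty nu must be positive")
        if self.use_full_volume_density:
            pp, qq, ss = self.volume_exponents
            a, b, g = self.volume_coefficients
            n = dim
            if not (pp > n and qq > n and ss > (n - 1) * qq / (qq - n)):
                raise ValueError("volume exponents violate p>n, q>n, s>(n-1)q/(q-n)")
            if min(a, b, g) <= 0:
                raise ValueError("volume coefficients must be positive")
            target = volume_coefficient_gamma(n, a, b)
            if abs(g - target) > 1e-12 * max(1.0, abs(target)):
                raise ValueError(
                    f"volume coefficients not stationary at the identity: "
                    f"gamma={g}, required {target}"
                )


@dataclass
class EnergyBreakdown:
    match: float
    membrane: float
    bending: float
    volume: float

    @property
    def total(self) -> float:
        return self.match + self.membrane + self.bending + self.volume

    def as_tuple(self):
        return (self.match, self.membrane, self.bending, self.volume, self.total)


@dataclass
class ShapePair:
    """Reference/template distance and geometry fields on a shared grid."""

    grid: AdaptiveGrid
    d1: ScalarField
    d2: ScalarField
    geo1: GeometryFields
    geo2: GeometryFields

    def __post_init__(self):
        if isinstance(self.d1, SignedDistanceField):
            self.d1 = self.d1.field
        if isinstance(self.d2, SignedDistanceField):
            self.d2 = self.d2.field


# ----------------------------------------------------------------------
# pointwise densities
# ----------------------------------------------------------------------
_ETA_NORM = 0.4439938161680794  # int_{-1}^{1} exp(-1/(1-u^2)) du


def cutoff_eta(t, sigma: float):
    """Smooth even bump supported on [-sigma, sigma] with unit integral."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t = np.asarray(t, dtype=float)
    u = t / sigma
    out = np.zeros_like(u)
    inside = np.abs(u) < 1.0
    ui = u[inside]
    out[inside] = np.exp(-1.0 / (1.0 - ui * ui))
    return out / (sigma * _ETA_NORM)


def _cofactor(A: np.ndarray) -> np.ndarray:
    """Cofactor matrix (batched), finite for singular A."""
    n = A.shape[-1]
    if n == 2:
        C = np.empty_like(A)
        C[..., 0, 0] = A[..., 1, 1]
        C[..., 0, 1] = -A[..., 1, 0]
        C[..., 1, 0] = -A[..., 0, 1]
        C[..., 1, 1] = A[..., 0, 0]
        return C
    # 3D: the j-th column of Cof is the cross product of the other two
    # columns of A (so that A^T Cof = det(A) * 1)
    C = np.empty_like(A)
    for j in range(3):
        a = A[..., :, (j + 1) % 3]
        b = A[..., :, (j + 2) % 3]
        C[..., :, j] = np.cross(a, b)
    return C


def membrane_density_W(A: np.ndarray, lam: float = 1.0, mu: float = 1.0):
    """Polyconvex density with W(SO(n)) = 0 and Lame-Navier Hessian at 1:

    W(A) = mu/2 |A|^2 + lam/4 (det A)^2 + (mu + lam/2) e^{-(det A - 1)}
           - (n+2) mu / 2 - 3 lam / 4.
    Finite for det A -> 0 (no interpenetration barrier).
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[-1]
    frob2 = np.einsum("...ij,...ij->...", A, A)
    det = np.linalg.det(A)
    # cap the exponent: grossly folded trial configurations get a huge but
    # finite value, so weighted sums and difference quotients stay NaN-free
    # while the Armijo search still rejects the step
    expo = np.minimum(-(det - 1.0), 500.0)
    return (
        0.5 * mu * frob2
        + 0.25 * lam * det**2
        + (mu + 0.5 * lam) * np.exp(expo)
        - 0.5 * (n + 2) * mu
        - 0.75 * lam
    )


def membrane_density_W_gradient(A: np.ndarray, lam: float = 1.0, mu: float = 1.0):
    """dW/dA = mu A + (lam/2 det - (mu + lam/2) e^{-(det-1)}) Cof(A)."""
    A = np.asarray(A, dtype=float)
    det = np.linalg.det(A)
    expo = np.minimum(-(det - 1.0), 500.0)
    scal = 0.5 * lam * det - (mu + 0.5 * lam) * np.exp(expo)
    return mu * A + scal[..., None, None] * _cofactor(A)


def clamp_to_domain(y: np.ndarray) -> np.ndarray:
    """Componentwise projection onto [0, 1]^n (free-boundary handling)."""
    return np.clip(np.asarray(y, dtype=float), 0.0, 1.0)


def _sym(A):
    return 0.5 * (A + np.swapaxes(A, -1, -2))


def _proj(nvec):
    eye = np.eye(nvec.shape[-1])
    return eye - nvec[..., :, None] * nvec[..., None, :]


def _normalize_rows(V):
    nrm = np.linalg.norm(V, axis=-1, keepdims=True)
    return V / np.maximum(nrm, 1e-14)


# ----------------------------------------------------------------------
# the assembled model
# ----------------------------------------------------------------------
class EnergyModel:
    """Discrete total energy and its gradient for a fixed grid and pair.

    All band terms share one precomputed quadrature rule; the breakdown of
    ``total`` therefore equals the independently computed terms exactly.
    """

    def __init__(self, pair: ShapePair, params: EnergyParams):
        self.pair = pair
        self.grid = pair.grid
        self.params = params.resolved(self.grid.dim)
        self._prepare()

    # -- precomputation ------------------------------------------------
    def _prepare(self):
        g = self.grid
        p = self.params
        sigma = p.band_width
        dim = g.dim

        # band leaves: conservative corner test (d1 is 1-Lipschitz)
        corner_d1 = (g.constraints @ self.pair.d1.coeffs)[g.corner_nodes]
        half_diag = g.leaf_h * np.sqrt(dim) / 2
        cmin, cmax = corner_d1.min(axis=1), corner_d1.max(axis=1)
        band_leaves = np.flatnonzero(
            (cmin <= sigma + half_diag) & (cmax >= -sigma - half_diag)
        )
        Xb, wb, _ = g.quadrature(band_leaves)
        li = g.locate_many(Xb)
        d1q = self.pair.d1.evaluate_many(Xb, li)
        keep = cutoff_eta(d1q, sigma) > 0.0  # drop underflowed band edges
        self.Xb, self.wb, self.d1q = Xb[keep], wb[keep], d1q[keep]
        self.eta = cutoff_eta(self.d1q, sigma)
        self.Bb_val, self.Bb_grad = g.assembly_matrices(self.Xb, li[keep])

        # source-side coefficients at band quadrature points
        n1 = _normalize_rows(self.pair.geo1.normals.evaluate_many(self.Xb))
        self.n1 = n1
        self.P1 = _proj(n1)
        C1 = self._interp_classified(self.pair.geo1, self.Xb)
        self.C1 = C1
        _, self.C1_invsqrt = spd_sqrt_invsqrt(C1, self._sqrt_trunc())
        S1 = self._interp_matrix(self.pair.geo1.shape_ops, self.Xb)
        self.S1 = _sym(S1)

        # full-domain quadrature for the volume term
        self.Xv, self.wv, _ = g.quadrature()
        self.Bv_val, self.Bv_grad = g.assembly_matrices(self.Xv)

        self.lumped_mass = np.asarray(self.Bv_val.T @ self.wv).ravel()

    def _sqrt_trunc(self):
        variant, parm = self.params.classifier
        return parm / 10.0 if variant == "abs" else 1e-8

    def _interp_matrix(self, nodal: np.ndarray, X, li=None):
        g = self.grid
        w, li, _, _ = g.interp_weights(X, li)
        node_vals = (self.grid.constraints @ nodal.reshape(len(nodal), -1)).reshape(
            -1, g.dim, g.dim
        )
        return np.einsum("mc,mcij->mij", w, node_vals[g.corner_nodes[li]])

    def _interp_classified(self, geo: GeometryFields, X, li=None):
        """Interpolated classified operator, re-symmetrized and re-clamped."""
        variant, parm = self.params.classifier
        M = _sym(self._interp_matrix(geo.classified, X, li))
        return classify_curvature(M, variant, parm)

    # -- target-side fields at deformed points --------------------------
    def _deformed(self, coeffs: np.ndarray):
        y_raw = np.asarray(self.Bb_val @ coeffs)
        mask = (y_raw > 0.0) & (y_raw < 1.0)
        return clamp_to_domain(y_raw), mask

    def _jacobians(self, coeffs: np.ndarray, B_grad):
        cols = [np.asarray(Bg @ coeffs) for Bg in B_grad]  # each (m, dim)
        return np.stack(cols, axis=2)  # J[m, k, d] = d phi_k / d x_d

    def _target_normals(self, Y, li=None):
        return _normalize_rows(self.pair.geo2.normals.evaluate_many(Y, li))

    # -- individual densities at band points -----------------------------
    def _membrane_arg(self, Y, J):
        if self.params.ablate_P2_in_membrane:
            # naive variant: W of the tangential Cauchy-Green tensor
            JP = J @ self.P1
            return np.swapaxes(JP, -1, -2) @ JP + self.n1[..., :, None] * self.n1[..., None, :]
        n2 = self._target_normals(Y)
        P2 = _proj(n2)
        return P2 @ J @ self.P1 + n2[..., :, None] * self.n1[..., None, :]

    def _membrane_vals(self, Y, J):
        p = self.params
        return membrane_density_W(self._membrane_arg(Y, J), p.lame_lambda, p.lame_mu)

    def _bending_vals(self, Y, J, cache: dict | None = None):
        p = self.params
        if p.use_naive_bending:
            S2 = _sym(self._interp_matrix(self.pair.geo2.shape_ops, Y))
            R = np.swapaxes(J, -1, -2) @ S2 @ J - self.S1
            return np.einsum("...ij,...ij->...", R, R)
        n2 = self._target_normals(Y)
        P2 = _proj(n2)
        C2 = self._interp_classified(self.pair.geo2, Y)
        N_sqrt, _ = spd_sqrt_invsqrt(C2, self._sqrt_trunc())
        L = P2 @ N_sqrt @ P2
        Rm = self.P1 @ self.C1_invsqrt @ self.P1
        n2n1 = n2[..., :, None] * self.n1[..., None, :]
        Lam = L @ J @ Rm + n2n1
        if cache is not None:
            cache["left"], cache["right"], cache["n2n1"] = L, Rm, n2n1
        return membrane_density_W(Lam, p.lame_lambda, p.lame_mu)

    def _volume_density(self, J):
        p = self.params
        if not p.use_full_volume_density:
            return p.volume_weight * membrane_density_W(J, p.lame_lambda, p.lame_mu)
        pp, qq, ss = p.volume_exponents
        a, b, gcoef = p.volume_coefficients
        det = np.linalg.det(J)
        frob = np.sqrt(np.einsum("...ij,...ij->...", J, J))
        cof = _cofactor(J)
        cfro = np.sqrt(np.einsum("...ij,...ij->...", cof, cof))
        out = a * frob**pp + b * cfro**qq
        with np.errstate(divide="ignore", over="ignore"):
            out = out + np.where(det > 0, gcoef * det ** (-ss), np.inf)
        return out

    # -- energies --------------------------------------------------------
    def breakdown(self, phi: VectorField) -> EnergyBreakdown:
        p = self.params
        coeffs = phi.coeffs
        Y, _ = self._deformed(coeffs)
        J = self._jacobians(coeffs, self.Bb_grad)
        weta = self.wb * self.eta
        d2q = self.pair.d2.evaluate_many(Y)
        match = float(np.sum(weta * (d2q - self.d1q) ** 2) / p.penalty)
        mem = p.shell_thickness * float(np.sum(weta * self._membrane_vals(Y, J)))
        bend = p.shell_thickness**3 * float(
            np.sum(weta * self._bending_vals(Y, J))
        )
        Jv = self._jacobians(coeffs, self.Bv_grad)
        vol_density = self._volume_density(Jv)
        vol = float(np.sum(self.wv * vol_density))
        if not np.isfinite(vol):
            vol = np.inf
        return EnergyBreakdown(match, mem, bend, vol)

    def total(self, phi: VectorField) -> float:
        return self.breakdown(phi).total

    # -- gradient --------------------------------------------------------
    def gradient(self, phi: VectorField, lumped: bool = True) -> VectorField:
        """L2 gradient: assembled first variation (optionally mass-divided)."""
        p = self.params
        g = self.grid
        dim = g.dim
        coeffs = phi.coeffs
        Y, mask = self._deformed(coeffs)
        J = self._jacobians(coeffs, self.Bb_grad)
        m = len(Y)
        weta = self.wb * self.eta

        gy = np.zeros((m, dim))     # d(density)/dy per band point
        gJ = np.zeros((m, dim, dim))

        # matching: analytic
        d2q = self.pair.d2.evaluate_many(Y)
        grad_d2 = self.pair.d2.gradient_many(Y)
        gy += (2.0 / p.penalty) * (d2q - self.d1q)[:, None] * grad_d2

        # membrane: analytic in J, finite differences in y
        A = self._membrane_arg(Y, J)
        dW = membrane_density_W_gradient(A, p.lame_lambda, p.lame_mu)
        if p.ablate_P2_in_membrane:
            symW = _sym(dW)
            gJ += p.shell_thickness * 2.0 * (J @ self.P1 @ symW @ self.P1)
        else:
            n2 = self._target_normals(Y)
            P2 = _proj(n2)
            gJ += p.shell_thickness * (P2 @ dW @ self.P1)
            gy += p.shell_thickness * self._fd_y(lambda Yp: self._membrane_vals(Yp, J), Y)

        # bending
        if p.use_naive_bending:
            S2 = _sym(self._interp_matrix(self.pair.geo2.shape_ops, Y))
            R = np.swapaxes(J, -1, -2) @ S2 @ J - self.S1
            gJ += p.shell_thickness**3 * 4.0 * (S2 @ J @ R)
            gy += p.shell_thickness**3 * self._fd_y(
                lambda Yp: self._bending_naive_y(Yp, J), Y
            )
        else:
            cache: dict = {}
            self._bending_vals(Y, J, cache)
            L, Rm, n2n1 = cache["left"], cache["right"], cache["n2n1"]
            Lam = L @ J @ Rm + n2n1
            dWb = membrane_density_W_gradient(Lam, p.lame_lambda, p.lame_mu)
            gJ += p.shell_thickness**3 * (
                np.swapaxes(L, -1, -2) @ dWb @ np.swapaxes(Rm, -1, -2)
            )
            gy += p.shell_thickness**3 * self._fd_y(
                lambda Yp: self._bending_vals(Yp, J), Y
            )

        gy *= weta[:, None] * mask  # clamped coordinates: subgradient zero
        gJ *= weta[:, None, None]

        grad = np.zeros((g.n_dof, dim))
        grad += np.asarray(self.Bb_val.T @ gy)
        for d in range(dim):
            grad += np.asarray(self.Bb_grad[d].T @ gJ[:, :, d])

        # volume term over the whole domain
        Jv = self._jacobians(coeffs, self.Bv_grad)
        if p.use_full_volume_density:
            if not np.isfinite(np.sum(self.wv * self._volume_density(Jv))):
                raise ValueError("gradient undefined: infinite volume energy")
            gJv = self._fd_J(self._volume_density, Jv)
        else:
            gJv = p.volume_weight * membrane_density_W_gradient(
                Jv, p.lame_lambda, p.lame_mu
            )
        gJv = gJv * self.wv[:, None, None]
        for d in range(dim):
            grad += np.asarray(self.Bv_grad[d].T @ gJv[:, :, d])

        if lumped:
            grad = grad / self.lumped_mass[:, None]
        return VectorField(g, grad)

    def _bending_naive_y(self, Y, J):
        S2 = _sym(self._interp_matrix(self.pair.geo2.shape_ops, Y))
        R = np.swapaxes(J, -1, -2) @ S2 @ J - self.S1
        return np.einsum("...ij,...ij->...", R, R)

    def _fd_y(self, f, Y):
        dim = Y.shape[1]
        out = np.zeros_like(Y)
        for d in range(dim):
            e = np.zeros(dim)
            e[d] = _FD_EPS
            fp = f(clamp_to_domain(Y + e))
            fm = f(clamp_to_domain(Y - e))
            out[:, d] = (fp - fm) / (2 * _FD_EPS)
        return out

    def _fd_J(self, f, J):
        dim = J.shape[-1]
        out = np.zeros_like(J)
        for i in range(dim):
            for j in range(dim):
                E = np.zeros((dim, dim))
                E[i, j] = _FD_EPS
                out[..., i, j] = (f(J + E) - f(J - E)) / (2 * _FD_EPS)
        return out


# ----------------------------------------------------------------------
# functional wrappers
# ----------------------------------------------------------------------
def _model(phi, pair, params):
    return EnergyModel(pair, params)


def matching_energy(phi, pair: ShapePair, params: EnergyParams) -> float:
    return _model(phi, pair, params).breakdown(phi).match


def membrane_energy(phi, pair: ShapePair, params: EnergyParams) -> float:
    return _model(phi, pair, params).breakdown(phi).membrane


def bending_energy(phi, pair: ShapePair, params: EnergyParams) -> float:
    return _model(phi, pair, params).breakdown(phi).bending


def volume_energy(phi, pair: ShapePair, params: EnergyParams) -> float:
    return _model(phi, pair, params).breakdown(phi).volume


def total_energy(phi, pair: ShapePair, params: EnergyParams) -> EnergyBreakdown:
    return _model(phi, pair, params).breakdown(phi)


def energy_gradient(phi, pair: ShapePair, params: EnergyParams) -> VectorField:
    return _model(phi, pair, params).gradient(phi)
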