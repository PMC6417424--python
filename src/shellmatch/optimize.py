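"""Minimization: Fletcher-Reeves NCG with Armijo backtracking, wrapped in a
cascadic multilevel scheme.

The coarse-to-fine loop refines the grid around both surfaces, recomputes
distances and geometry coefficients, prolongates the current deformation and
minimizes again.  The per-level schedules follow the narrow-band rule
``sigma = 2h``, divide the matching penalty ``nu`` by a fixed factor per
refinement and halve the volume weight ``c_vol``, so that the match tightens
while the regularization relaxes more slowly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .energies import EnergyModel, EnergyParams, ShapePair
from .geometry import build_geometry_fields
from .grid import AdaptiveGrid, VectorField, prolongate, refine_around_surfaces
from .signed_distance import signed_distance_field

__all__ = [
    "OptimizerConfig",
    "MultilevelSchedule",
    "IterationRecord",
    "ncg_minimize",
    "update_schedule",
    "run_cascadic",
    "CascadicResult",
]


@dataclass
class OptimizerConfig:
    max_iters: int = 500
    armijo_alpha0: float = 1.0
    armijo_backtrack: float = 0.5
    armijo_slope: float = 1e-4
    armijo_min_step: float = 1e-12
    restart_period: int = 50
    grad_tol: float = 1e-6
    energy_tol: float = 1e-10
    dirichlet_boundary: bool = False

    def __post_init__(self):
        if not (0 < self.armijo_backtrack < 1):
            raise ValueError("backtracking factor must be in (0,1)")
        if not (0 < self.armijo_slope < 1):
            raise ValueError("Armijo slope constant must be in (0,1)")


@dataclass
class MultilevelSchedule:
    level_min: int = 4
    level_max: int = 7
    nu0: float = 0.002
    nu_divisor: float = 10.0
    cvol0: float = 0.025
    cvol_factor: float = 0.5

    def __post_init__(self):
        if self.level_min > self.level_max:
            raise ValueError("level_min must not exceed level_max")
        if self.nu_divisor <= 1:
            raise ValueError("nu divisor must exceed 1")
        if not (0 < self.cvol_factor < 1):
            raise ValueError("c_vol factor must be in (0,1)")


@dataclass
class IterationRecord:
    level: int
    iteration: int
    step: float
    match: float
    membrane: float
    bending: float
    volume: float
    total: float


def update_schedule(level: int, schedule: MultilevelSchedule, params: EnergyParams):
    """Per-level parameters: nu/10 per refinement, c_vol/2, sigma = 2h."""
    k = level - schedule.level_min
    if k < 0 or level > schedule.level_max:
        raise ValueError("level outside schedule range")
    return replace(
        params,
        penalty=schedule.nu0 / schedule.nu_divisor**k,
        volume_weight=schedule.cvol0 * schedule.cvol_factor**k,
        band_width=2.0 * 2.0**-level,
    )


def _boundary_mask(grid: AdaptiveGrid) -> np.ndarray:
    P = grid.dof_positions
    return np.any((P <= 0.0) | (P >= 1.0), axis=1)


def ncg_minimize(
    phi0: VectorField,
    model: EnergyModel,
    config: OptimizerConfig | None = None,
    level: int = 0,
):
    """Fletcher-Reeves nonlinear CG with Armijo backtracking.

    Produces a monotone nonincreasing energy sequence; the search direction
    is reset to steepest descent every ``restart_period`` iterations and
    whenever it fails to be a descent direction.  Returns
    ``(phi, records, stalled)``.
    """
    config = config or OptimizerConfig()
    grid = model.grid
    mass = model.lumped_mass[:, None]
    fixed = _boundary_mask(grid) if config.dirichlet_boundary else None

    def project(v):
        if fixed is not None:
            v = v.copy()
            v[fixed] = 0.0
        return v

    u = phi0.coeffs.copy()
    E = model.total(VectorField(grid, u))
    if not np.isfinite(E):
        raise ValueError("starting deformation has infinite energy")
    g = project(model.gradient(VectorField(grid, u)).coeffs)
    gg = float(np.sum(mass * g * g))
    d = -g
    alpha = config.armijo_alpha0
    records = [IterationRecord(level, 0, 0.0, *model.breakdown(VectorField(grid, u)).as_tuple())]
    stalled = False

    for it in range(1, config.max_iters + 1):
        if np.sqrt(gg) <= config.grad_tol:
            break
        slope = float(np.sum(mass * g * d))
        if slope >= 0:  # not a descent direction: restart
            d = -g
            slope = -gg
        # Armijo backtracking, persistent step with mild growth
        accepted = False
        a = min(alpha * 2.0, config.armijo_alpha0 * 64)
        while a >= config.armijo_min_step:
            E_new = model.total(VectorField(grid, u + a * d))
            if np.isfinite(E_new) and E_new <= E + config.armijo_slope * a * slope:
                accepted = True
                break
            a *= config.armijo_backtrack
        if not accepted:
            stalled = True
            break
        alpha = a
        u = u + a * d
        E_prev, E = E, E_new
        g_new = project(model.gradient(VectorField(grid, u)).coeffs)
        gg_new = float(np.sum(mass * g_new * g_new))
        if it % config.restart_period == 0:
            beta = 0.0
        else:
            beta = gg_new / max(gg, 1e-300)
        d = -g_new + beta * d
        g, gg = g_new, gg_new
        records.append(
            IterationRecord(level, it, a, *model.breakdown(VectorField(grid, u)).as_tuple())
        )
        if E_prev - E <= config.energy_tol * max(abs(E), 1.0):
            break
    return VectorField(grid, u), records, stalled


@dataclass
class CascadicResult:
    phi: VectorField
    grid: AdaptiveGrid
    pair: ShapePair
    params: EnergyParams
    records: list
    level_summaries: list


def _pair_on_grid(grid, shape1, shape2, classifier, fit_r=None) -> ShapePair:
    s1 = signed_distance_field(shape1, grid)
    s2 = signed_distance_field(shape2, grid)
    geo1 = build_geometry_fields(s1.field, r=fit_r, classifier=classifier)
    geo2 = build_geometry_fields(s2.field, r=fit_r, classifier=classifier)
    return ShapePair(grid, s1.field, s2.field, geo1, geo2)


def run_cascadic(
    shape1,
    shape2,
    schedule: MultilevelSchedule,
    params: EnergyParams,
    config: OptimizerConfig | None = None,
    dim: int = 2,
    verbose: bool = False,
) -> CascadicResult:
    """Coarse-to-fine minimization (deterministic; identity start).

    At each level the grid is refined around both surfaces (band width 3h),
    distances and geometry coefficients are recomputed, the schedule updates
    ``sigma``, ``nu`` and ``c_vol``, the previous solution is prolongated
    and used as the initial iterate.  A stalled level proceeds to the next
    level with a warning entry in its summary.
    """
    config = config or OptimizerConfig()
    grid = AdaptiveGrid(dim, level=min(schedule.level_min, 4))
    phi = None
    all_records: list = []
    summaries: list = []
    pair = None
    lvl_params = params
    for level in range(schedule.level_min, schedule.level_max + 1):
        pair0 = _pair_on_grid(grid, shape1, shape2, params.classifier)
        bands = [(pair0.d1, 3.0 * 2.0**-level), (pair0.d2, 3.0 * 2.0**-level)]
        new_grid = refine_around_surfaces(grid, bands, level)
        pair = _pair_on_grid(new_grid, shape1, shape2, params.classifier)
        lvl_params = update_schedule(level, schedule, params)
        model = EnergyModel(pair, lvl_params)
        phi = (
            VectorField.identity(new_grid)
            if phi is None
            else prolongate(phi, new_grid)
        )
        phi, records, stalled = ncg_minimize(phi, model, config, level=level)
        all_records.extend(records)
        summaries.append(
            {
                "level": level,
                "dofs": new_grid.n_dof,
                "iterations": records[-1].iteration,
                "stalled": stalled,
                "energy": records[-1].total,
                "match": records[-1].match,
                "nu": lvl_params.penalty,
                "c_vol": lvl_params.volume_weight,
                "sigma": lvl_params.band_width,
            }
        )
        if verbose:
            s = summaries[-1]
            print(
                f"[level {level}] dofs={s['dofs']} iters={s['iterations']} "
                f"E={s['energy']:.6g} match={s['match']:.3g}"
                + (" (stalled)" if stalled else "")
            )
        grid = new_grid
    return CascadicResult(phi, grid, pair, lvl_params, all_records, summaries)
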