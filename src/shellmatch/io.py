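"""Readers, writers, run configuration and logging.

2D shapes are closed polylines stored as CSV (one ``x,y`` row per vertex,
implicitly closed).  3D shapes are watertight triangle meshes in OBJ, OFF
or PLY, read and written through trimesh.  Grids and deformation fields are
exported as legacy-ASCII VTK unstructured grids (pixel/voxel cells) for
inspection.  Shapes can also be given as fixture specs such as
``circle:0.2``, ``ellipse:0.3,0.18``, ``rect:0.3,0.2,0.05``,
``sphere:0.25`` or ``ellipsoid:0.3,0.22,0.18`` (all centred in the unit
domain), so every demo is reproducible without data files.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from . import shapes as _shapes
from .energies import EnergyParams
from .grid import AdaptiveGrid, ScalarField, VectorField
from .optimize import MultilevelSchedule, OptimizerConfig

__all__ = [
    "read_shape",
    "write_shape",
    "parse_fixture",
    "resolve_shape",
    "normalize_shape",
    "write_vtk_grid",
    "write_energy_log",
    "RunConfig",
    "load_config",
    "save_config",
    "write_outputs",
]

_POLY_FMT = "%.17g"


# ----------------------------------------------------------------------
# shapes
# ----------------------------------------------------------------------
def parse_fixture(spec: str):
    """Analytic fixture from a spec string (see module docstring)."""
    kind, _, rest = spec.partition(":")
    vals = [float(v) for v in rest.split(",")] if rest else []
    if kind == "circle":
        return _shapes.circle(radius=vals[0] if vals else 0.25)
    if kind == "ellipse":
        return _shapes.ellipse(radii=tuple(vals) if vals else (0.3, 0.18))
    if kind in ("rect", "rounded_rectangle"):
        he = tuple(vals[:2]) if len(vals) >= 2 else (0.3, 0.2)
        cr = vals[2] if len(vals) > 2 else 0.05
        return _shapes.rounded_rectangle(half_extents=he, corner_radius=cr)
    if kind == "sphere":
        return _shapes.sphere(radius=vals[0] if vals else 0.25)
    if kind == "ellipsoid":
        return _shapes.ellipsoid(radii=tuple(vals) if vals else (0.3, 0.22, 0.18))
    raise ValueError(f"unknown fixture spec {spec!r}")


def resolve_shape(spec_or_path: str, resolution: int = 1024):
    """Fixture spec -> discretized shape; path -> loaded shape."""
    if ":" in spec_or_path and not Path(spec_or_path).exists():
        fx = parse_fixture(spec_or_path)
        return fx.polygon(resolution) if fx.dim == 2 else fx.mesh(4)
    return read_shape(spec_or_path)


def read_shape(path, fmt: str | None = None, normalize: bool = False):
    """Load and validate a closed shape; optionally fit it into (0,1)^n.

    Returns the shape (polygon array or trimesh.Trimesh); with
    ``normalize=True`` returns ``(shape, affine)`` where the affine dict
    records scale and offset back to the original frame.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = (fmt or path.suffix.lstrip(".")).lower()
    if suffix in ("csv", "txt", "poly"):
        poly = np.loadtxt(path, delimiter=",", ndmin=2)
        if poly.shape[1] != 2 or len(poly) < 3:
            raise ValueError("polyline CSV must have >= 3 rows of x,y")
        from .signed_distance import _validate_shape, _orientation_sign

        _validate_shape(poly)
        if _orientation_sign(poly) < 0:
            poly = poly[::-1].copy()  # outward orientation (CCW)
        shape = poly
    elif suffix in ("obj", "off", "ply"):
        import trimesh

        mesh = trimesh.load(path, force="mesh", process=False)
        from .signed_distance import _validate_shape, _orientation_sign

        _validate_shape(mesh)
        if _orientation_sign(mesh) < 0:
            mesh.invert()
        shape = mesh
    else:
        raise ValueError(f"unsupported shape format {suffix!r}")
    if normalize:
        return normalize_shape(shape)
    return shape


def normalize_shape(shape, margin: float = 0.15):
    """Scale/translate a shape into the unit domain with a margin.

    Returns ``(shape, affine)`` with ``x_original = scale * x + offset``.
    """
    V = shape if isinstance(shape, np.ndarray) else shape.vertices
    lo, hi = V.min(axis=0), V.max(axis=0)
    span = float((hi - lo).max())
    scale = (1.0 - 2.0 * margin) / span
    mid = 0.5 * (lo + hi)
    newV = (V - mid) * scale + 0.5
    affine = {"scale": 1.0 / scale, "offset": (mid - 0.5 / scale).tolist()}
    if isinstance(shape, np.ndarray):
        return newV, affine
    import trimesh

    return trimesh.Trimesh(newV, shape.faces, process=False), affine


def write_shape(path, shape):
    path = Path(path)
    if isinstance(shape, np.ndarray):
        np.savetxt(path, shape, delimiter=",", fmt=_POLY_FMT)
    else:
        shape.export(path)


# ----------------------------------------------------------------------
# VTK legacy export
# ----------------------------------------------------------------------
def write_vtk_grid(path, grid: AdaptiveGrid, point_data: dict | None = None):
    """Legacy-ASCII VTK unstructured grid of the leaves with nodal data."""
    dim = grid.dim
    pts = grid.node_ipos / grid.res
    if dim == 2:
        pts = np.c_[pts, np.zeros(len(pts))]
    cell_type = 8 if dim == 2 else 11  # VTK_PIXEL / VTK_VOXEL match bit order
    nc = 2**dim
    lines = ["# vtk DataFile Version 3.0", "shellmatch grid", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {len(pts)} double"]
    lines += [" ".join(f"{v:.17g}" for v in p) for p in pts]
    cells = grid.corner_nodes
    lines.append(f"CELLS {len(cells)} {len(cells) * (nc + 1)}")
    lines += [f"{nc} " + " ".join(map(str, row)) for row in cells]
    lines.append(f"CELL_TYPES {len(cells)}")
    lines += [str(cell_type)] * len(cells)
    if point_data:
        lines.append(f"POINT_DATA {len(pts)}")
        for name, fld in point_data.items():
            vals = (
                fld.node_values()
                if isinstance(fld, (ScalarField, VectorField))
                else np.asarray(fld)
            )
            if vals.ndim == 1:
                lines += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
                lines += [f"{v:.17g}" for v in vals]
            else:
                v3 = vals if vals.shape[1] == 3 else np.c_[vals, np.zeros(len(vals))]
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{x:.17g}" for x in row) for row in v3]
    Path(path).write_text("\n".join(lines) + "\n")


def write_energy_log(path, records):
    """Per-iteration CSV log: level, iteration, step and the energy terms."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(
            ["level", "iteration", "step", "match", "membrane", "bending",
             "volume", "total"]
        )
        for r in records:
            w.writerow(
                [r.level, r.iteration, f"{r.step:.17g}", f"{r.match:.17g}",
                 f"{r.membrane:.17g}", f"{r.bending:.17g}", f"{r.volume:.17g}",
                 f"{r.total:.17g}"]
            )


# ----------------------------------------------------------------------
# run configuration
# ----------------------------------------------------------------------
@dataclasses.dataclass
class RunConfig:
    source: str = "circle:0.2"
    target: str = "circle:0.3"
    params: EnergyParams = dataclasses.field(default_factory=EnergyParams)
    schedule: MultilevelSchedule = dataclasses.field(default_factory=MultilevelSchedule)
    optimizer: OptimizerConfig = dataclasses.field(default_factory=OptimizerConfig)
    output_dir: str = "out"
    verbose: bool = True

    def to_dict(self):
        d = dataclasses.asdict(self)
        # tuples -> lists for clean YAML round trips
        return json.loads(json.dumps(d, default=list))


def _dataclass_from(cls, d: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    kw = {}
    for k, v in d.items():
        if k not in fields:
            raise ValueError(f"unknown {cls.__name__} key {k!r}")
        kw[k] = tuple(v) if isinstance(v, list) else v
    return cls(**kw)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(
        source=raw.get("source", RunConfig.source),
        target=raw.get("target", RunConfig.target),
        params=_dataclass_from(EnergyParams, raw.get("params", {})),
        schedule=_dataclass_from(MultilevelSchedule, raw.get("schedule", {})),
        optimizer=_dataclass_from(OptimizerConfig, raw.get("optimizer", {})),
        output_dir=raw.get("output_dir", "out"),
        verbose=raw.get("verbose", True),
    )
    for spec in (cfg.source, cfg.target):
        if ":" not in spec and not Path(spec).exists():
            raise FileNotFoundError(f"shape path {spec!r} does not exist")
    return cfg


def save_config(path, cfg: RunConfig):
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def write_outputs(result, outdir, source_shape, config: RunConfig | None = None):
    """Persist a run: deformed input shape, VTK field, CSV log, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(source_shape, np.ndarray):
        deformed = result.phi.evaluate_many(source_shape)
        write_shape(outdir / "deformed_shape.csv", deformed)
    else:
        import trimesh

        dv = result.phi.evaluate_many(np.asarray(source_shape.vertices))
        trimesh.Trimesh(dv, source_shape.faces, process=False).export(
            outdir / "deformed_shape.ply"
        )
    disp = VectorField(
        result.grid, result.phi.coeffs - result.grid.dof_positions
    )
    write_vtk_grid(
        outdir / "deformation.vtk",
        result.grid,
        {"displacement": disp, "d1": result.pair.d1, "d2": result.pair.d2},
    )
    write_energy_log(outdir / "energies.csv", result.records)
    if config is not None:
        save_config(outdir / "config.yaml", config)
    (outdir / "levels.json").write_text(json.dumps(result.level_summaries, indent=2))
    return outdir
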