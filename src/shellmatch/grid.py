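"""Adaptive quadtree/octree grids with multilinear finite elements.

The computational domain is the unit square/cube ``[0, 1]^n`` (n = 2 or 3),
tiled by axis-aligned cells of side ``h = 2**-level``.  A cell is identified
by its :class:`CellKey` -- the refinement level together with the integer
coordinates of its minimal ("lower-left-back") corner in units of ``h``.
Cells are half-open, ``[a*h, a*h + h)``, except along the upper domain
boundary where they are closed; this fixes ownership of points on shared
facets deterministically (the containing cell with the largest anchor wins).

Continuous piecewise-multilinear functions are stored by their coefficients
on the *degrees of freedom* (DOF) nodes.  Vertices of fine cells that lie on
a facet (or, in 3D, an edge) of a coarser neighbour without being one of its
vertices are *hanging nodes*: their values are constrained to the multilinear
interpolation of the coarse facet's vertices, which keeps the represented
function continuous across level jumps.  Refinement is propagated so that
adjacent leaves differ by at most one level, which guarantees that every
hanging node is an edge midpoint or face centre of the coarser neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Callable, NamedTuple, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "CellKey",
    "AdaptiveGrid",
    "ScalarField",
    "VectorField",
    "refine_around_surfaces",
    "enforce_two_to_one_balance",
    "prolongate",
]

#: Hard cap on the refinement level so integer node keys stay well inside
#: exactly-representable float range (positions are multiples of 2**-level).
MAX_LEVEL = 20

_GAUSS_1D = (0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0))


class CellKey(NamedTuple):
    """Identifier of one cell: refinement level and integer anchor."""

    level: int
    anchor: tuple

    @property
    def h(self) -> float:
        return 2.0 ** (-self.level)

    def children(self):
        lvl = self.level + 1
        dim = len(self.anchor)
        base = tuple(2 * a for a in self.anchor)
        for bits in product((0, 1), repeat=dim):
            yield CellKey(lvl, tuple(base[d] + bits[d] for d in range(dim)))

    def parent(self) -> "CellKey":
        if self.level == 0:
            raise ValueError("root cell has no parent")
        return CellKey(self.level - 1, tuple(a // 2 for a in self.anchor))


def _corner_offsets(dim: int) -> np.ndarray:
    # corner c has offset bit d = (c >> d) & 1
    return np.array(
        [[(c >> d) & 1 for d in range(dim)] for c in range(2**dim)], dtype=np.int64
    )


class AdaptiveGrid:
    """2:1-balanced adaptive quad/octree with indexed multilinear FE nodes.

    After construction the grid is immutable; refinement operations return
    new grids.  ``index_nodes`` (called automatically) classifies every leaf
    vertex as DOF or hanging, assigns contiguous DOF indices in sorted key
    order (hence deterministic), and builds the sparse constraint matrix
    mapping DOF coefficients to all nodal values.
    """

    def __init__(self, dim: int, leaves: Sequence[CellKey] | None = None, *, level: int = 0):
        if dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        self.dim = dim
        if leaves is None:
            n = 2**level
            leaves = [
                CellKey(level, tup) for tup in product(range(n), repeat=dim)
            ]
        self.leaf_keys: list[CellKey] = sorted(leaves)
        self.leaf_set = set(self.leaf_keys)
        if not self.leaf_keys:
            raise ValueError("grid needs at least one leaf")
        self.max_level = max(k.level for k in self.leaf_keys)
        if self.max_level > MAX_LEVEL:
            raise ValueError(f"refinement level exceeds key-encoding cap {MAX_LEVEL}")
        self._check_tiling()
        self._build_locate_tables()
        self.balanced = self._check_balanced()
        if self.balanced:
            # unbalanced grids stay un-indexed: hanging-node stencils beyond
            # one level are not supported; rebalance first
            self._index_nodes()
            self._build_corner_matrix()
        self._quad_cache: dict = {}

    def _check_balanced(self) -> bool:
        for key in self.leaf_keys:
            if key.level < 2:
                continue
            for off in _ALL_OFFSETS[self.dim]:
                nb = tuple(a + o for a, o in zip(key.anchor, off))
                if any(c < 0 or c >= (1 << key.level) for c in nb):
                    continue
                for lvl in range(key.level - 2, -1, -1):
                    anc = CellKey(lvl, tuple(c >> (key.level - lvl) for c in nb))
                    if anc in self.leaf_set:
                        return False
        return True

    def require_indexed(self):
        if not self.balanced:
            raise ValueError(
                "grid is not 2:1 balanced; apply enforce_two_to_one_balance first"
            )

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    def _check_tiling(self) -> None:
        total = sum(2.0 ** (-self.dim * k.level) for k in self.leaf_keys)
        if abs(total - 1.0) > 1e-12:
            raise ValueError("leaves do not tile the unit domain")

    @property
    def res(self) -> int:
        """Integer resolution: node coordinates are multiples of 1/res."""
        return 2**self.max_level

    def _encode(self, anchors: np.ndarray) -> np.ndarray:
        code = anchors[..., 0].astype(np.int64)
        for d in range(1, self.dim):
            code = (code << 21) | anchors[..., d].astype(np.int64)
        return code

    def _build_locate_tables(self) -> None:
        by_level: dict[int, list] = {}
        self._leaf_index = {k: i for i, k in enumerate(self.leaf_keys)}
        for k in self.leaf_keys:
            by_level.setdefault(k.level, []).append(k)
        self._level_codes: dict[int, np.ndarray] = {}
        self._level_ids: dict[int, np.ndarray] = {}
        for lvl, keys in by_level.items():
            anchors = np.array([k.anchor for k in keys], dtype=np.int64)
            codes = self._encode(anchors)
            order = np.argsort(codes)
            self._level_codes[lvl] = codes[order]
            self._level_ids[lvl] = np.array(
                [self._leaf_index[keys[i]] for i in order], dtype=np.int64
            )
        self.levels_present = sorted(by_level, reverse=True)

    # node keys are integer coordinate tuples at resolution `res`
    def _index_nodes(self) -> None:
        dim, L = self.dim, self.max_level
        offs = _corner_offsets(dim)
        node_set: dict[tuple, None] = {}
        for k in self.leaf_keys:
            shift = L - k.level
            base = np.array(k.anchor, dtype=np.int64) << shift
            for o in offs:
                node_set[tuple(base + (o << shift))] = None
        node_keys = sorted(node_set)
        self.node_index = {p: i for i, p in enumerate(node_keys)}
        self.node_ipos = np.array(node_keys, dtype=np.int64)
        n_nodes = len(node_keys)

        # classify: a node is hanging iff some containing leaf does not have
        # it as a vertex; with 2:1 balance that leaf is exactly one level
        # coarser and the node sits at a midpoint/face-centre of its boundary.
        hanging_parent: dict[int, list] = {}
        res = self.res
        for idx, pos in enumerate(node_keys):
            worst = None  # coarsest offending leaf
            seen = set()
            for sgn in product((0, -1), repeat=dim):
                key = self._leaf_at_octant(pos, sgn)
                if key is None or key in seen:
                    continue
                seen.add(key)
                shift = L - key.level
                hh = 1 << shift
                is_vertex = all(
                    pos[d] == key.anchor[d] * hh or pos[d] == (key.anchor[d] + 1) * hh
                    for d in range(dim)
                )
                if not is_vertex:
                    if worst is None or key.level < worst.level:
                        worst = key
            if worst is None:
                continue
            shift = L - worst.level
            hh = 1 << shift
            free = [
                d
                for d in range(dim)
                if worst.anchor[d] * hh < pos[d] < (worst.anchor[d] + 1) * hh
            ]
            for d in free:
                if pos[d] % (hh >> 1):
                    raise RuntimeError("grid not 2:1 balanced: bad hanging node")
            parents = []
            w = 0.5 ** len(free)
            for bits in product((0, 1), repeat=len(free)):
                p = list(pos)
                for d, b in zip(free, bits):
                    p[d] = (worst.anchor[d] + b) * hh
                parents.append((tuple(p), w))
            hanging_parent[idx] = parents

        self.is_hanging = np.zeros(n_nodes, dtype=bool)
        self.is_hanging[list(hanging_parent)] = True
        dof_nodes = np.flatnonzero(~self.is_hanging)
        self.n_dof = len(dof_nodes)
        self.dof_node_index = dof_nodes
        dof_of_node = -np.ones(n_nodes, dtype=np.int64)
        dof_of_node[dof_nodes] = np.arange(self.n_dof)
        self.dof_of_node = dof_of_node
        self.dof_positions = self.node_ipos[dof_nodes] / res

        # resolve constraints (parents of a hanging node may themselves hang
        # one more level up; edge stencils resolve before face stencils
        # because recursion bottoms out at true DOFs)
        memo: dict[int, dict] = {}

        def resolve(i: int) -> dict:
            if i in memo:
                return memo[i]
            if not self.is_hanging[i]:
                memo[i] = {dof_of_node[i]: 1.0}
                return memo[i]
            memo[i] = {}  # placeholder; 2:1 balance forbids cycles
            acc: dict = {}
            for p, w in hanging_parent[i]:
                for j, wj in resolve(self.node_index[p]).items():
                    acc[j] = acc.get(j, 0.0) + w * wj
            memo[i] = acc
            return acc

        rows, cols, vals = [], [], []
        for i in range(n_nodes):
            for j, w in resolve(i).items():
                rows.append(i)
                cols.append(j)
                vals.append(w)
        self.constraints = sp.csr_matrix(
            (vals, (rows, cols)), shape=(n_nodes, self.n_dof)
        )

    def _leaf_at_octant(self, pos: tuple, sgn: tuple) -> CellKey | None:
        """Leaf whose closed cell touches ``pos`` from octant direction sgn."""
        L = self.max_level
        for lvl in self.levels_present:
            shift = L - lvl
            hh = 1 << shift
            anchor = []
            ok = True
            for d in range(self.dim):
                a, r = divmod(pos[d], hh)
                if r == 0 and sgn[d] < 0:
                    a -= 1
                if a < 0 or a >= (1 << lvl):
                    ok = False
                    break
                anchor.append(a)
            if not ok:
                continue
            key = CellKey(lvl, tuple(anchor))
            if key in self.leaf_set:
                return key
        return None

    def _build_corner_matrix(self) -> None:
        dim, L = self.dim, self.max_level
        offs = _corner_offsets(dim)
        nc = 2**dim
        corner_nodes = np.empty((len(self.leaf_keys), nc), dtype=np.int64)
        for i, k in enumerate(self.leaf_keys):
            shift = L - k.level
            base = np.array(k.anchor, dtype=np.int64) << shift
            for c in range(nc):
                corner_nodes[i, c] = self.node_index[tuple(base + (offs[c] << shift))]
        self.corner_nodes = corner_nodes
        self.corner_map = self.constraints[corner_nodes.ravel()].tocsr()
        self.leaf_levels = np.array([k.level for k in self.leaf_keys])
        self.leaf_h = 2.0**-self.leaf_levels
        self.leaf_anchor = np.array([k.anchor for k in self.leaf_keys], dtype=np.int64)
        self.leaf_origin = self.leaf_anchor * self.leaf_h[:, None]

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    def locate_leaf(self, x) -> CellKey:
        idx = self.locate_many(np.asarray(x, dtype=float)[None, :])[0]
        return self.leaf_keys[idx]

    def locate_many(self, X: np.ndarray) -> np.ndarray:
        """Leaf index containing each point (facets go to the larger anchor)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.dim:
            raise ValueError("points must have shape (m, dim)")
        if np.any(X < -1e-12) or np.any(X > 1 + 1e-12):
            raise ValueError("point outside the unit domain; clamp first")
        res = self.res
        xi = np.clip((X * res).astype(np.int64), 0, res - 1)
        out = -np.ones(len(X), dtype=np.int64)
        todo = np.arange(len(X))
        for lvl in self.levels_present:
            if todo.size == 0:
                break
            anchors = xi[todo] >> (self.max_level - lvl)
            codes = self._encode(anchors)
            table = self._level_codes[lvl]
            pos = np.searchsorted(table, codes)
            pos_c = np.clip(pos, 0, len(table) - 1)
            hit = table[pos_c] == codes
            out[todo[hit]] = self._level_ids[lvl][pos_c[hit]]
            todo = todo[~hit]
        if todo.size:
            raise RuntimeError("locate failed: incomplete tiling")
        return out

    def _local_coords(self, X: np.ndarray, li: np.ndarray):
        h = self.leaf_h[li]
        t = (X - self.leaf_origin[li]) / h[:, None]
        return np.clip(t, 0.0, 1.0), h

    def interp_weights(self, X: np.ndarray, li: np.ndarray | None = None):
        """Multilinear weights (m, 2^dim) and leaf indices for points X."""
        if li is None:
            li = self.locate_many(X)
        t, h = self._local_coords(X, li)
        offs = _corner_offsets(self.dim)
        w = np.ones((len(X), len(offs)))
        for d in range(self.dim):
            td = t[:, d : d + 1]
            w *= np.where(offs[:, d][None, :] == 1, td, 1.0 - td)
        return w, li, t, h

    def grad_weights(self, X: np.ndarray, li: np.ndarray | None = None):
        """d(weights)/dx: array (m, dim, 2^dim); one-sided on facets."""
        if li is None:
            li = self.locate_many(X)
        t, h = self._local_coords(X, li)
        offs = _corner_offsets(self.dim)
        m = len(X)
        gw = np.empty((m, self.dim, len(offs)))
        for g in range(self.dim):
            w = np.ones((m, len(offs)))
            for d in range(self.dim):
                td = t[:, d : d + 1]
                if d == g:
                    w *= np.where(offs[:, d][None, :] == 1, 1.0, -1.0)
                else:
                    w *= np.where(offs[:, d][None, :] == 1, td, 1.0 - td)
            gw[:, g, :] = w / h[:, None]
        return gw, li

    # ------------------------------------------------------------------
    # quadrature / assembly
    # ------------------------------------------------------------------
    def quadrature(self, leaf_ids: np.ndarray | None = None):
        """Tensor 2-point Gauss rule: points (m, dim), weights (m,), owner leaf."""
        key = None if leaf_ids is None else hash(leaf_ids.tobytes())
        if key in self._quad_cache:
            return self._quad_cache[key]
        if leaf_ids is None:
            leaf_ids = np.arange(len(self.leaf_keys))
        pts_ref = np.array(list(product(_GAUSS_1D, repeat=self.dim)))
        nq = len(pts_ref)
        h = self.leaf_h[leaf_ids]
        X = (
            self.leaf_origin[leaf_ids][:, None, :]
            + pts_ref[None, :, :] * h[:, None, None]
        ).reshape(-1, self.dim)
        w = np.repeat(h**self.dim / nq, nq)
        owner = np.repeat(leaf_ids, nq)
        out = (X, w, owner)
        self._quad_cache[key] = out
        return out

    def assembly_matrices(self, X: np.ndarray, li: np.ndarray | None = None):
        """Sparse evaluation operators at points X.

        Returns ``(B_val, B_grad)`` with ``B_val @ u`` the point values of the
        field with DOF coefficients ``u`` and ``B_grad[d] @ u`` the d-th
        spatial derivative (list of dim sparse matrices).
        """
        w, li, _, _ = self.interp_weights(X, li)
        gw, _ = self.grad_weights(X, li)
        m = len(X)
        nc = 2**self.dim
        cols = (li[:, None] * nc + np.arange(nc)[None, :]).ravel()
        rows = np.repeat(np.arange(m), nc)
        nrows_corner = self.corner_map.shape[0]
        Wv = sp.csr_matrix((w.ravel(), (rows, cols)), shape=(m, nrows_corner))
        B_val = (Wv @ self.corner_map).tocsr()
        B_grad = []
        for d in range(self.dim):
            Wg = sp.csr_matrix(
                (gw[:, d, :].ravel(), (rows, cols)), shape=(m, nrows_corner)
            )
            B_grad.append((Wg @ self.corner_map).tocsr())
        return B_val, B_grad

    # serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "leaves": [[k.level, list(k.anchor)] for k in self.leaf_keys],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AdaptiveGrid":
        leaves = [CellKey(lvl, tuple(a)) for lvl, a in d["leaves"]]
        return cls(d["dim"], leaves)

    def __eq__(self, other):
        return isinstance(other, AdaptiveGrid) and self.leaf_keys == other.leaf_keys

    def __hash__(self):
        return hash(tuple(self.leaf_keys))


# ----------------------------------------------------------------------
# fields
# ----------------------------------------------------------------------
@dataclass
class ScalarField:
    """Continuous piecewise-multilinear scalar function on an AdaptiveGrid."""

    grid: AdaptiveGrid
    coeffs: np.ndarray  # (n_dof,)

    def __post_init__(self):
        self.grid.require_indexed()
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (self.grid.n_dof,):
            raise ValueError("coefficient shape mismatch")

    @classmethod
    def from_function(cls, grid: AdaptiveGrid, f: Callable) -> "ScalarField":
        return cls(grid, np.asarray(f(grid.dof_positions), dtype=float))

    def node_values(self) -> np.ndarray:
        return self.grid.constraints @ self.coeffs

    def evaluate_many(self, X: np.ndarray, li=None) -> np.ndarray:
        g = self.grid
        w, li, _, _ = g.interp_weights(np.asarray(X, dtype=float), li)
        vals = self.node_values()[g.corner_nodes[li]]
        return np.einsum("mc,mc->m", w, vals)

    def evaluate(self, x) -> float:
        return float(self.evaluate_many(np.asarray(x, dtype=float)[None, :])[0])

    def gradient_many(self, X: np.ndarray, li=None) -> np.ndarray:
        g = self.grid
        gw, li = g.grad_weights(np.asarray(X, dtype=float), li)
        vals = self.node_values()[g.corner_nodes[li]]
        return np.einsum("mdc,mc->md", gw, vals)

    def evaluate_jacobian(self, x):
        x = np.asarray(x, dtype=float)[None, :]
        return float(self.evaluate_many(x)[0]), self.gradient_many(x)[0]


@dataclass
class VectorField:
    """Continuous piecewise-multilinear vector function (e.g. a deformation)."""

    grid: AdaptiveGrid
    coeffs: np.ndarray  # (n_dof, dim)

    def __post_init__(self):
        self.grid.require_indexed()
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (self.grid.n_dof, self.grid.dim):
            raise ValueError("coefficient shape mismatch")

    @classmethod
    def identity(cls, grid: AdaptiveGrid) -> "VectorField":
        return cls(grid, grid.dof_positions.copy())

    def node_values(self) -> np.ndarray:
        return self.grid.constraints @ self.coeffs

    def evaluate_many(self, X: np.ndarray, li=None) -> np.ndarray:
        g = self.grid
        w, li, _, _ = g.interp_weights(np.asarray(X, dtype=float), li)
        vals = self.node_values()[g.corner_nodes[li]]
        return np.einsum("mc,mck->mk", w, vals)

    def evaluate(self, x) -> np.ndarray:
        return self.evaluate_many(np.asarray(x, dtype=float)[None, :])[0]

    def jacobian_many(self, X: np.ndarray, li=None) -> np.ndarray:
        """Spatial Jacobians, shape (m, dim, dim): J[k, d] = d phi_k / d x_d."""
        g = self.grid
        gw, li = g.grad_weights(np.asarray(X, dtype=float), li)
        vals = self.node_values()[g.corner_nodes[li]]
        return np.einsum("mdc,mck->mkd", gw, vals)

    def evaluate_jacobian(self, x):
        x = np.asarray(x, dtype=float)[None, :]
        return self.evaluate_many(x)[0], self.jacobian_many(x)[0]


# ----------------------------------------------------------------------
# grid operations
# ----------------------------------------------------------------------
_FACE_OFFSETS = {
    2: [o for o in product((-1, 0, 1), repeat=2) if sum(map(abs, o)) == 1],
    3: [o for o in product((-1, 0, 1), repeat=3) if sum(map(abs, o)) == 1],
}
_ALL_OFFSETS = {
    2: [o for o in product((-1, 0, 1), repeat=2) if any(o)],
    3: [o for o in product((-1, 0, 1), repeat=3) if any(o)],
}


def _balance_leafset(dim: int, leaves: set) -> set:
    """Split leaves until adjacent levels differ by at most one.

    Balance is enforced over the full vertex adjacency (facets, edges and
    corners), which is slightly stronger than facet-only balance but keeps
    every hanging-node stencil confined to a single coarser level.
    """
    leaves = set(leaves)
    queue = list(leaves)
    while queue:
        key = queue.pop()
        if key not in leaves or key.level < 2:
            continue
        for off in _ALL_OFFSETS[dim]:
            nb = tuple(a + o for a, o in zip(key.anchor, off))
            if any(c < 0 or c >= (1 << key.level) for c in nb):
                continue
            # ancestors more than one level coarser must be split
            for lvl in range(key.level - 2, -1, -1):
                anc = CellKey(lvl, tuple(c >> (key.level - lvl) for c in nb))
                if anc in leaves:
                    leaves.remove(anc)
                    kids = list(anc.children())
                    leaves.update(kids)
                    queue.extend(kids)
                    queue.append(key)
                    break
    return leaves


def enforce_two_to_one_balance(grid: AdaptiveGrid) -> AdaptiveGrid:
    balanced = _balance_leafset(grid.dim, grid.leaf_set)
    if balanced == grid.leaf_set:
        return grid
    return AdaptiveGrid(grid.dim, balanced)


def refine_around_surfaces(
    grid: AdaptiveGrid,
    bands: Sequence[tuple],
    max_level: int,
) -> AdaptiveGrid:
    """Refine every leaf meeting ``{|d| <= width}`` down to ``max_level``.

    ``bands`` is a list of ``(distance, width)`` pairs where ``distance`` is a
    callable ``d(X) -> (m,)`` or a :class:`ScalarField`.  The test is
    conservative for 1-Lipschitz distance functions: a leaf is refined when
    ``|d(centre)| <= width + diam/2``, so no band-intersecting leaf is missed.
    Refinement only ever subdivides (no coarsening) and the result is
    rebalanced.
    """
    if max_level > MAX_LEVEL:
        raise ValueError(f"max_level {max_level} exceeds key-encoding cap {MAX_LEVEL}")
    if max_level < grid.max_level:
        raise ValueError("max_level below current finest level")
    if not bands:
        return grid

    def dist_many(dfun, X):
        if isinstance(dfun, ScalarField):
            return dfun.evaluate_many(X)
        return np.asarray(dfun(X), dtype=float)

    leaves = set(grid.leaf_set)
    changed = True
    while changed:
        changed = False
        cand = [k for k in leaves if k.level < max_level]
        if not cand:
            break
        centers = np.array(
            [[(a + 0.5) * k.h for a in k.anchor] for k in cand]
        )
        half_diag = np.array([k.h for k in cand]) * np.sqrt(grid.dim) / 2
        flag = np.zeros(len(cand), dtype=bool)
        for dfun, width in bands:
            if width <= 0:
                raise ValueError("band width must be positive")
            flag |= np.abs(dist_many(dfun, centers)) <= width + half_diag
        for k, f in zip(cand, flag):
            if f:
                leaves.remove(k)
                leaves.update(k.children())
                changed = True
    leaves = _balance_leafset(grid.dim, leaves)
    if leaves == grid.leaf_set:
        return grid
    return AdaptiveGrid(grid.dim, leaves)


def _is_refinement(coarse: AdaptiveGrid, fine: AdaptiveGrid) -> bool:
    cs = coarse.leaf_set
    for k in fine.leaf_keys:
        kk = k
        while kk not in cs:
            if kk.level == 0:
                return False
            kk = kk.parent()
        if kk.level > k.level:  # cannot happen with valid tilings
            return False
    return True


def prolongate(fld, fine_grid: AdaptiveGrid):
    """Transfer a field to a refined grid by point evaluation at new DOFs."""
    if not _is_refinement(fld.grid, fine_grid):
        raise ValueError("target grid does not refine the field's grid")
    X = fine_grid.dof_positions
    if isinstance(fld, ScalarField):
        return ScalarField(fine_grid, fld.evaluate_many(X))
    return VectorField(fine_grid, fld.evaluate_many(X))
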