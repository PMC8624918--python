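"""Reduced velocity parametrisation on a tetrahedral linear FE mesh.

The velocity field is u(x, t) = sum_j alpha_j(t) phi_j(x), where phi_j are
the standard piecewise-linear hat functions of a tetrahedral mesh (phi_j = 1
at node j, 0 at every other node) and alpha_j are per-node 3-vectors -- the
unknowns of the velocity-recovery subproblem.  The mesh is a structured Kuhn
subdivision: the grid bounding box is partitioned into cubic macro-cells of
side ~h, each split into the 6 tetrahedra given by the orderings of the
local coordinates.  This is reproducible and mesher-free; node spacing is
the resolution knob.

The reconstruction only ever needs u at the finite-volume face centroids, so
the basis is precomputed as sparse matrices Phi (faces x nodes) per face
family; face velocities are then three sparse matvecs, exactly linear in
alpha, with an equally cheap exact adjoint for gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .finite_volume import FaceVelocities
from .ray_geometry import CellField

__all__ = ["TetMesh", "BasisOperator", "build_mesh", "assemble_basis",
           "cfl_clamp"]

# the 6 Kuhn tetrahedra of the unit cube: vertex paths 0 -> e_a -> e_a+e_b
# -> (1,1,1) for each ordering (a, b, c) of the axes
_PERMUTATIONS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0),
                 (2, 0, 1), (2, 1, 0)]


def _kuhn_vertices(perm):
    v = [np.zeros(3)]
    acc = np.zeros(3)
    for a in perm:
        acc = acc.copy()
        acc[a] = 1.0
        v.append(acc)
    return np.array(v)  # (4, 3) local unit-cube coordinates


@dataclass
class TetMesh:
    """Structured tetrahedral mesh with per-element linear shape functions.

    ``shape_coeffs[e]`` is a 4x4 matrix whose row j holds (c0, c1, c2, c3)
    of phi_j(x) = c0 + c1 x + c2 y + c3 z on element e (local node j).
    """

    nodes: np.ndarray           # (M, 3)
    elements: np.ndarray        # (E, 4) node indices
    shape_coeffs: np.ndarray    # (E, 4, 4)
    origin: np.ndarray
    spacing: float              # macro-cell side h
    n_macro: int                # macro-cells per side

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def enclosing_sphere_radii(self) -> np.ndarray:
        """Circumscribing-sphere radius per element (h*sqrt(3)/2 for Kuhn)."""
        out = np.empty(self.n_elements)
        for e in range(self.n_elements):
            v = self.nodes[self.elements[e]]
            # circumcentre from |x - v0|^2 = |x - vi|^2, i = 1..3
            A = 2.0 * (v[1:] - v[0])
            b = np.sum(v[1:] ** 2, axis=1) - np.sum(v[0] ** 2)
            c = np.linalg.solve(A, b)
            out[e] = np.linalg.norm(c - v[0])
        return out

    def dump(self, path) -> None:
        """Plain-text node/element dump (debug aid)."""
        with open(path, "w") as f:
            f.write(f"# nodes {self.n_nodes}\n")
            for x, y, z in self.nodes:
                f.write(f"{x:.12g} {y:.12g} {z:.12g}\n")
            f.write(f"# elements {self.n_elements}\n")
            for el in self.elements:
                f.write(" ".join(str(i) for i in el) + "\n")

    def locate(self, points: np.ndarray):
        """Element index and 4 nodal shape values for each query point.

        Points must lie inside (or on the boundary of) the meshed box;
        coordinates are clamped to the box by a relative 1e-12 tolerance.
        Returns (element_idx (N,), node_idx (N, 4), weights (N, 4)).
        """
        p = np.asarray(points, dtype=float)
        xi = (p - self.origin) / self.spacing
        K = self.n_macro
        tol = 1e-12 * max(K, 1)
        if np.any(xi < -tol) or np.any(xi > K + tol):
            raise ValueError("point outside mesh domain")
        xi = np.clip(xi, 0.0, K)
        cell = np.minimum(xi.astype(int), K - 1)
        loc = xi - cell                                   # in [0, 1]^3

        # ordering of the local coordinates selects the Kuhn tetrahedron
        order = np.argsort(-loc, axis=1, kind="stable")   # descending
        s = np.take_along_axis(loc, order, axis=1)        # sorted desc
        # barycentric weights along the vertex path 0, e_o1, e_o1+e_o2, 1
        w = np.empty((p.shape[0], 4))
        w[:, 0] = 1.0 - s[:, 0]
        w[:, 1] = s[:, 0] - s[:, 1]
        w[:, 2] = s[:, 1] - s[:, 2]
        w[:, 3] = s[:, 2]

        # global node indices of the path vertices
        nper = K + 1
        base = cell.copy()
        idx = np.empty((p.shape[0], 4), dtype=np.int64)

        def node_id(c):
            return (c[:, 0] * nper + c[:, 1]) * nper + c[:, 2]

        idx[:, 0] = node_id(base)
        step = base.copy()
        rows = np.arange(p.shape[0])
        step[rows, order[:, 0]] += 1
        idx[:, 1] = node_id(step)
        step = step.copy()
        step[rows, order[:, 1]] += 1
        idx[:, 2] = node_id(step)
        idx[:, 3] = node_id(base + 1)

        perm_lookup = {perm: i for i, perm in enumerate(_PERMUTATIONS)}
        perm_ids = np.array([perm_lookup[tuple(o)] for o in order])
        flat_cell = (cell[:, 0] * K + cell[:, 1]) * K + cell[:, 2]
        elem = flat_cell * 6 + perm_ids
        return elem, idx, w


def build_mesh(grid_spec: CellField, node_spacing: float) -> TetMesh:
    """Structured Kuhn-subdivision mesh covering the FV grid exactly.

    The number of macro-cells per side is ceil(extent / node_spacing); the
    actual spacing is extent / K so the mesh box coincides with the grid
    bounding box (every face centroid is inside the mesh).
    """
    if node_spacing < grid_spec.dx:
        raise ValueError("node spacing must be >= the cell size")
    extent = grid_spec.extent
    K = max(int(np.ceil(extent / node_spacing - 1e-12)), 1)
    h = extent / K
    nper = K + 1
    g = np.arange(nper) * h
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    nodes = grid_spec.origin + np.column_stack(
        [X.ravel(), Y.ravel(), Z.ravel()])

    elements = []
    for cx in range(K):
        for cy in range(K):
            for cz in range(K):
                base = np.array([cx, cy, cz])
                for perm in _PERMUTATIONS:
                    verts = _kuhn_vertices(perm) + base
                    ids = [(int(v[0]) * nper + int(v[1])) * nper + int(v[2])
                           for v in verts]
                    elements.append(ids)
    elements = np.asarray(elements, dtype=np.int64)

    coeffs = np.empty((elements.shape[0], 4, 4))
    for e, el in enumerate(elements):
        v = nodes[el]
        A = np.column_stack([np.ones(4), v])   # rows: [1, x, y, z]
        if abs(np.linalg.det(A)) < 1e-14 * h ** 3:
            raise ValueError(f"degenerate element {e}")
        # phi_j(v_i) = delta_ij  =>  A @ C.T = I
        coeffs[e] = np.linalg.inv(A).T
    return TetMesh(nodes=nodes, elements=elements, shape_coeffs=coeffs,
                   origin=grid_spec.origin.copy(), spacing=h, n_macro=K)


def _face_centroids(grid: CellField, axis: int) -> np.ndarray:
    n, dx = grid.n, grid.dx
    coords = []
    for a in range(3):
        if a == axis:
            coords.append(grid.origin[a] + np.arange(n + 1) * dx)
        else:
            coords.append(grid.origin[a] + (np.arange(n) + 0.5) * dx)
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def _boundary_mask(n: int, axis: int) -> np.ndarray:
    shape = [n, n, n]
    shape[axis] = n + 1
    mask = np.zeros(shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = [0, shape[axis] - 1]
    mask[tuple(sl)] = True
    return mask.ravel()


class BasisOperator:
    """Sparse map from nodal coefficients to FV face velocities.

    x-faces take the alpha components, y-faces beta, z-faces gamma.  With
    ``zero_boundary`` the domain-boundary faces are forced to zero velocity
    (the closed-system boundary condition used during reconstruction); the
    raw operator reproduces any globally linear field at every face
    centroid.
    """

    def __init__(self, mesh: TetMesh, grid: CellField):
        self.mesh = mesh
        self.grid_n = grid.n
        self.grid_dx = grid.dx
        self.phis = []
        self.face_shapes = []
        self.boundary = []
        for axis in range(3):
            pts = _face_centroids(grid, axis)
            _, idx, w = mesh.locate(pts)
            rows = np.repeat(np.arange(pts.shape[0]), 4)
            phi = sp.coo_matrix(
                (w.ravel(), (rows, idx.ravel())),
                shape=(pts.shape[0], mesh.n_nodes)).tocsr()
            phi.sum_duplicates()
            self.phis.append(phi)
            shape = [grid.n] * 3
            shape[axis] += 1
            self.face_shapes.append(tuple(shape))
            self.boundary.append(_boundary_mask(grid.n, axis))

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_nodes

    def face_velocities(self, alpha: np.ndarray,
                        zero_boundary: bool = True) -> FaceVelocities:
        """Evaluate u = sum_j alpha_j phi_j at all face centroids."""
        alpha = np.asarray(alpha, dtype=float)
        if alpha.shape != (self.n_nodes, 3):
            raise ValueError("alpha must have shape (n_nodes, 3)")
        comps = []
        for axis in range(3):
            vals = self.phis[axis] @ alpha[:, axis]
            if zero_boundary:
                vals = vals.copy()
                vals[self.boundary[axis]] = 0.0
            comps.append(vals.reshape(self.face_shapes[axis]))
        return FaceVelocities(u=comps[0], v=comps[1], w=comps[2])

    def gradient_adjoint(self, face_grads, zero_boundary: bool = True
                         ) -> np.ndarray:
        """Pull gradients w.r.t. face velocities back to alpha (M, 3)."""
        out = np.empty((self.n_nodes, 3))
        for axis in range(3):
            g = np.asarray(face_grads[axis], dtype=float).ravel()
            if zero_boundary:
                g = g.copy()
                g[self.boundary[axis]] = 0.0
            out[:, axis] = self.phis[axis].T @ g
        return out


def assemble_basis(mesh: TetMesh, grid: CellField) -> BasisOperator:
    """Precompute the sparse face-centroid evaluation operator."""
    return BasisOperator(mesh, grid)


def cfl_clamp(alpha_star: np.ndarray, dt: float, dx: float) -> np.ndarray:
    """Scale nodal coefficient vectors back into the CFL-feasible domain.

    Per node j, C_j = (|a_jx| + |a_jy| + |a_jz|) * dt / dx; nodes with
    C_j >= 1 are scaled by 1/C_j so that afterwards max_j C_j <= 1.
    """
    a = np.asarray(alpha_star, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("coefficients must be finite")
    C = np.sum(np.abs(a), axis=1) * dt / dx
    scale = np.ones_like(C)
    over = C >= 1.0
    scale[over] = 1.0 / C[over]
    return a * scale[:, None]


def nodal_cfl(alpha: np.ndarray, dt: float, dx: float) -> np.ndarray:
    """Per-node CFL numbers C_j = (|a_x|+|a_y|+|a_z|) dt/dx."""
    return np.sum(np.abs(np.asarray(alpha, dtype=float)), axis=1) * dt / dx
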