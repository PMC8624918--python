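"""Discrete line-integral projection operator and its adjoint.

The measured quantity is the absorbance A_k = log(I0_k / I1_k) along ray k,
modelled as the line integral of the attenuation field f along the ray.  On a
cubic cell grid with piecewise-constant f the integral is exact:

    A_k = sum_i  fbar_i * l_ki

where l_ki is the geometric intersection length of ray k with cell i (a
Siddon-style exact kernel).  The operator is assembled once per
(geometry, grid) pair as a sparse matrix, so projection is a matvec and the
adjoint (backprojection) is the exact transpose.

Geometry convention: the grid is centred on the rotation axis (z through the
grid centre), angles are in degrees, and theta describes a positive sample
rotation around z -- equivalently the apparatus is rotated by -theta.  The
detector row coordinate equals z; the column coordinate x_d lies in the
rotated detector plane.  Pixel centres sit at half-integer offsets from the
detector centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "DetectorGeometry",
    "Ray",
    "CellField",
    "Sinogram",
    "ProjectionOperator",
    "make_rays",
    "project",
    "backproject",
]

_EPS = 1e-12


@dataclass(frozen=True)
class DetectorGeometry:
    """Fixed multi-angle acquisition geometry.

    Parameters
    ----------
    n_rows, n_cols : int
        Detector pixel counts.  Rows run along z, columns along the rotated
        in-plane detector coordinate x_d.
    pixel_size : float
        Pixel side length (same length unit as the grid).
    angles : tuple of float
        Sample rotation angles theta in degrees.
    beam_model : {"parallel", "point_source"}
    source_distance, detector_distance : float
        Source-to-rotation-axis (S) and detector-to-rotation-axis (D)
        distances; only used for the point-source model.
    """

    n_rows: int
    n_cols: int
    pixel_size: float
    angles: tuple = ()
    beam_model: str = "parallel"
    source_distance: float = 0.0
    detector_distance: float = 0.0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if len(self.angles) == 0:
            raise ValueError("angle list must be non-empty")
        if self.beam_model not in ("parallel", "point_source"):
            raise ValueError(f"unknown beam model {self.beam_model!r}")
        if self.beam_model == "point_source":
            if self.source_distance <= 0 or self.detector_distance < 0:
                raise ValueError("point_source requires S > 0 and D >= 0")
        object.__setattr__(self, "angles", tuple(float(a) for a in self.angles))

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    @property
    def n_pixels(self) -> int:
        return self.n_angles * self.n_rows * self.n_cols

    def pixel_coords(self):
        """Detector-plane coordinates (x_d across columns, y_d across rows)."""
        xd = (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * self.pixel_size
        yd = (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * self.pixel_size
        return xd, yd


@dataclass(frozen=True)
class Ray:
    """A single ray clipped to the grid bounding box."""

    entry_point: np.ndarray
    direction: np.ndarray
    path_length: float

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-12:
            raise ValueError("ray direction must be a unit vector")
        if self.path_length < 0:
            raise ValueError("path length must be non-negative")


@dataclass
class CellField:
    """Cubic voxel/cell grid of per-cell average attenuation.

    The cell (ix, iy, iz) has centroid origin + (ix+1/2, iy+1/2, iz+1/2)*dx.
    """

    n: int
    dx: float
    origin: np.ndarray = None
    values: np.ndarray = None

    def __post_init__(self):
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.origin is None:
            half = self.n * self.dx / 2.0
            self.origin = np.array([-half, -half, -half])
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values is None:
            self.values = np.zeros((self.n, self.n, self.n))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n, self.n, self.n):
            raise ValueError("values must have shape (n, n, n)")

    @classmethod
    def empty(cls, n: int, dx: float, center=(0.0, 0.0, 0.0)) -> "CellField":
        half = n * dx / 2.0
        origin = np.asarray(center, dtype=float) - half
        return cls(n=n, dx=dx, origin=origin)

    def copy(self) -> "CellField":
        return CellField(n=self.n, dx=self.dx, origin=self.origin.copy(),
                         values=self.values.copy())

    def centroids(self):
        """Cell-centre coordinate axes (three 1-d arrays)."""
        ax = self.origin[:, None] + (np.arange(self.n) + 0.5) * self.dx
        return ax[0], ax[1], ax[2]

    @property
    def extent(self) -> float:
        return self.n * self.dx


@dataclass
class Sinogram:
    """Absorbance images, one per angle: values[angle, row, col]."""

    values: np.ndarray
    geometry: DetectorGeometry = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")
        if self.geometry is not None:
            expect = (self.geometry.n_angles, self.geometry.n_rows,
                      self.geometry.n_cols)
            if self.values.shape != expect:
                raise ValueError(
                    f"sinogram shape {self.values.shape} != geometry {expect}")


def _rotation_z(theta_deg: float) -> np.ndarray:
    """Rotation of the apparatus by -theta == positive sample rotation."""
    t = np.deg2rad(theta_deg)
    c, s = np.cos(-t), np.sin(-t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ray_arrays(geometry: DetectorGeometry, grid: CellField):
    """Vectorised ray set for one geometry: points, unit directions.

    Returns (points, dirs) with shape (n_pixels, 3), ordered
    (angle, row, col) row-major, matching the flattened sinogram layout.
    """
    xd, yd = geometry.pixel_coords()
    XD, YD = np.meshgrid(xd, yd)          # (rows, cols)
    xd_f = XD.ravel()
    yd_f = YD.ravel()
    npx = xd_f.size

    points = np.empty((geometry.n_angles * npx, 3))
    dirs = np.empty_like(points)
    S = geometry.source_distance
    D = geometry.detector_distance
    for a, theta in enumerate(geometry.angles):
        R = _rotation_z(theta)
        sl = slice(a * npx, (a + 1) * npx)
        if geometry.beam_model == "parallel":
            # ray through the rotated pixel centre, direction R @ x_hat
            pts = np.column_stack([np.zeros(npx), xd_f, yd_f]) @ R.T
            points[sl] = pts
            dirs[sl] = R @ np.array([1.0, 0.0, 0.0])
        else:
            src = R @ np.array([-S, 0.0, 0.0])
            # detector point - source = R @ (D + S, x_d, y_d)   (Rz keeps z)
            rel = np.column_stack([np.full(npx, D + S), xd_f, yd_f]) @ R.T
            nrm = np.linalg.norm(rel, axis=1, keepdims=True)
            points[sl] = src
            dirs[sl] = rel / nrm
    return points, dirs


def _clip_to_box(points, dirs, lo, hi):
    """Slab clipping of lines p + t*d to the box [lo, hi].

    Returns (t0, t1) per ray; rays that miss get t1 <= t0.
    """
    t0 = np.full(points.shape[0], -np.inf)
    t1 = np.full(points.shape[0], np.inf)
    for a in range(3):
        d = dirs[:, a]
        p = points[:, a]
        par = np.abs(d) < _EPS
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = (lo[a] - p) / d
            tb = (hi[a] - p) / d
        tmin = np.minimum(ta, tb)
        tmax = np.maximum(ta, tb)
        t0 = np.where(par, np.where((p >= lo[a]) & (p <= hi[a]), t0, np.inf), np.maximum(t0, tmin))
        t1 = np.where(par, np.where((p >= lo[a]) & (p <= hi[a]), t1, -np.inf), np.minimum(t1, tmax))
    return t0, t1


def make_rays(geometry: DetectorGeometry, grid: CellField) -> list:
    """One `Ray` per (angle, pixel), clipped to the grid bounding box.

    Rays that miss the box get path_length 0 (entry point at the closest
    approach parameter, by convention the clipped t0).
    """
    points, dirs = _ray_arrays(geometry, grid)
    lo = grid.origin
    hi = grid.origin + grid.extent
    t0, t1 = _clip_to_box(points, dirs, lo, hi)
    if geometry.beam_model == "point_source":
        t0 = np.maximum(t0, 0.0)
    rays = []
    for k in range(points.shape[0]):
        L = max(t1[k] - t0[k], 0.0)
        entry = points[k] + (t0[k] if L > 0 else 0.0) * dirs[k]
        rays.append(Ray(entry_point=entry, direction=dirs[k], path_length=L))
    return rays


class ProjectionOperator:
    """Sparse exact intersection-length projector P[.] and its adjoint.

    Rows index (angle, row, col) pixels; columns index flattened (ix, iy, iz)
    cells.  `matrix` is CSR; `project`/`backproject` are matvecs with it and
    its transpose, so the adjoint identity holds to machine precision.
    """

    def __init__(self, geometry: DetectorGeometry, grid: CellField):
        self.geometry = geometry
        self.grid_n = grid.n
        self.grid_dx = grid.dx
        self.grid_origin = grid.origin.copy()
        self.matrix = self._build(geometry, grid)

    def _build(self, geometry, grid) -> sp.csr_matrix:
        n = grid.n
        dx = grid.dx
        lo = grid.origin
        hi = grid.origin + grid.extent
        points, dirs = _ray_arrays(geometry, grid)
        npx_per_angle = geometry.n_rows * geometry.n_cols

        blocks = []
        planes = lo[:, None] + np.arange(n + 1)[None, :] * dx  # (3, n+1)
        for a in range(geometry.n_angles):
            sl = slice(a * npx_per_angle, (a + 1) * npx_per_angle)
            P = points[sl]
            Dd = dirs[sl]
            t0, t1 = _clip_to_box(P, Dd, lo, hi)
            if geometry.beam_model == "point_source":
                t0 = np.maximum(t0, 0.0)
            hit = t1 > t0 + _EPS
            t0 = np.where(hit, t0, 0.0)
            t1 = np.where(hit, t1, 0.0)

            # crossing parameters with all grid planes in each axis
            tc = []
            for ax in range(3):
                d = Dd[:, ax:ax + 1]
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = (planes[ax][None, :] - P[:, ax:ax + 1]) / d
                t = np.where(np.abs(d) < _EPS, np.nan, t)
                tc.append(t)
            tall = np.concatenate(tc + [t0[:, None], t1[:, None]], axis=1)
            tall = np.clip(tall, t0[:, None], t1[:, None])
            tall = np.where(np.isnan(tall), t0[:, None], tall)
            tall.sort(axis=1)

            seg = np.diff(tall, axis=1)                       # lengths
            tm = 0.5 * (tall[:, :-1] + tall[:, 1:])           # midpoints
            pos = P[:, None, :] + tm[:, :, None] * Dd[:, None, :]
            idx = np.floor((pos - lo[None, None, :]) / dx).astype(np.int64)
            ok = (seg > _EPS) & np.all((idx >= 0) & (idx < n), axis=2)
            flat = (idx[..., 0] * n + idx[..., 1]) * n + idx[..., 2]
            rows = np.broadcast_to(
                np.arange(npx_per_angle)[:, None], seg.shape)
            block = sp.coo_matrix(
                (seg[ok], (rows[ok], flat[ok])),
                shape=(npx_per_angle, n ** 3))
            blocks.append(block.tocsr())
        W = sp.vstack(blocks, format="csr")
        W.sum_duplicates()
        return W

    def project(self, values: np.ndarray) -> np.ndarray:
        """Apply P: cell values (n,n,n) -> sinogram (n_angles, rows, cols)."""
        g = self.geometry
        out = self.matrix @ np.asarray(values, dtype=float).ravel()
        return out.reshape(g.n_angles, g.n_rows, g.n_cols)

    def project_flat(self, values_flat: np.ndarray) -> np.ndarray:
        return self.matrix @ values_flat

    def backproject(self, sino_values: np.ndarray) -> np.ndarray:
        """Apply the exact transpose: sinogram -> cell values (n,n,n)."""
        out = self.matrix.T @ np.asarray(sino_values, dtype=float).ravel()
        return out.reshape(self.grid_n, self.grid_n, self.grid_n)


def project(field: CellField, geometry: DetectorGeometry) -> Sinogram:
    """Discrete line-integral projection of a cell field."""
    if not np.all(np.isfinite(field.values)):
        raise ValueError("field values must be finite")
    op = ProjectionOperator(geometry, field)
    return Sinogram(values=op.project(field.values), geometry=geometry)


def backproject(sino: Sinogram, geometry: DetectorGeometry,
                grid_spec: CellField) -> CellField:
    """Exact adjoint of `project` onto the given grid."""
    op = ProjectionOperator(geometry, grid_spec)
    out = grid_spec.copy()
    out.values = op.backproject(sino.values)
    return out
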