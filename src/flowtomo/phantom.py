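"""Analytic ground-truth simulator: dynamic sphere scenes and sinograms.

A scene is a set of attenuating spheres with time-dependent centres.  The
projected absorbance of a sphere is computed analytically (chord length
through the sphere times its attenuation), independently of the numerical
ray model used for reconstruction -- which is precisely what makes the
simulator usable as a validation oracle.

For a point source at O_s and a unit ray direction n_hat, the contribution
of sphere p (centre c_p, radius r_p, attenuation rho_p) to the absorbance is

    2 * rho_p * Re sqrt(S_p),
    S_p = (n_hat . (O_s - c_p))^2 - |O_s|^2 + c_p . (2 O_s - c_p) + r_p^2
        = r_p^2 - d^2,

with d the perpendicular distance from the centre to the ray; the real part
of the complex square root makes non-intersecting rays contribute zero.  In
the parallel-beam limit the chord is 2*sqrt(r_p^2 - d^2) with d the
perpendicular ray-centre distance.  Overlapping spheres simply add.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .ray_geometry import CellField, DetectorGeometry, Sinogram, _ray_arrays

__all__ = [
    "Sphere",
    "SphereScene",
    "HelicalParams",
    "SinogramSeries",
    "helical_centers",
    "sinusoidal_velocity",
    "analytic_projection",
    "supersampled_projection",
    "voxelize",
    "render_series",
    "load_trajectories",
    "save_trajectories",
    "TABLE_HELICAL_PARAMS",
]


@dataclass(frozen=True)
class Sphere:
    center: tuple
    radius: float
    attenuation: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")
        if self.attenuation < 0:
            raise ValueError("sphere attenuation must be non-negative")


@dataclass(frozen=True)
class HelicalParams:
    """Per-particle helical path parameters.

    The centroid of particle i at time t is

        x = v_x * sin(2 pi t) - t_x
        y = v_y * cos(2 pi t) - t_y
        z = v_z * t - t_z

    where v_x, v_y bound the in-plane velocities, v_z is the axial velocity
    and (t_x, t_y, t_z) set the initial offset.
    """

    v_x: float
    v_y: float
    v_z: float
    t_x: float = 0.0
    t_y: float = 0.0
    t_z: float = 0.0


#: The three-particle helical system: a fixed central sphere surrounded by
#: two spheres revolving in opposite directions (velocities in m/s,
#: offsets in m).
TABLE_HELICAL_PARAMS = (
    HelicalParams(v_x=2 / 7, v_y=2 / 7, v_z=3 / 20, t_z=9 / 64),
    HelicalParams(v_x=2 / 7, v_y=-2 / 7, v_z=-3 / 20, t_z=-9 / 64),
    HelicalParams(v_x=0.0, v_y=0.0, v_z=0.0),
)


def helical_centers(params, t: float) -> np.ndarray:
    """Centroids of a helical-motion particle set at time t, shape (P, 3)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    out = np.empty((len(params), 3))
    for i, p in enumerate(params):
        out[i, 0] = p.v_x * np.sin(2 * np.pi * t) - p.t_x
        out[i, 1] = p.v_y * np.cos(2 * np.pi * t) - p.t_y
        out[i, 2] = p.v_z * t - p.t_z
    return out


def sinusoidal_velocity(z0: float, t_end: float, t: float) -> np.ndarray:
    """Axial velocity (0, 0, -z0 sin(pi t / t_end)).

    The CFL number z0*sin(pi t/t_end)*dt/dx is variable in time, peaking at
    z0*dt/dx at t_end/2.
    """
    if not 0 <= t <= t_end:
        raise ValueError("t must lie in [0, t_end]")
    return np.array([0.0, 0.0, -z0 * np.sin(np.pi * t / t_end)])


class SphereScene:
    """Dynamic ensemble of attenuating spheres.

    Parameters
    ----------
    spheres : list of Sphere
        Sphere properties; `center` is the position at t = 0 for static
        scenes, otherwise the motion model overrides it.
    motion : callable (t) -> (P, 3) centres, or None for a static scene.
    t_span : (t0, t1) over which the motion model is defined.
    """

    def __init__(self, spheres, motion=None, t_span=(0.0, np.inf)):
        if len(spheres) < 1:
            raise ValueError("scene needs at least one sphere")
        self.spheres = list(spheres)
        self.motion = motion
        self.t_span = tuple(t_span)

    def centers_at(self, t: float) -> np.ndarray:
        if not (self.t_span[0] <= t <= self.t_span[1]):
            raise ValueError(
                f"motion model undefined at t={t} (span {self.t_span})")
        if self.motion is None:
            return np.array([s.center for s in self.spheres], dtype=float)
        c = np.asarray(self.motion(t), dtype=float)
        if c.shape != (len(self.spheres), 3):
            raise ValueError("motion model returned wrong shape")
        return c

    @property
    def radii(self) -> np.ndarray:
        return np.array([s.radius for s in self.spheres])

    @property
    def attenuations(self) -> np.ndarray:
        return np.array([s.attenuation for s in self.spheres])

    @classmethod
    def helical(cls, params, radii, attenuations, t_span=(0.0, np.inf)):
        spheres = [Sphere(center=(0, 0, 0), radius=r, attenuation=a)
                   for r, a in zip(radii, attenuations)]
        return cls(spheres, motion=lambda t: helical_centers(params, t),
                   t_span=t_span)


def _chords(points, dirs, centers, radii):
    """Chord lengths of rays (points, dirs) through each sphere: (nray, P)."""
    rel = centers[None, :, :] - points[:, None, :]           # (nray, P, 3)
    proj = np.einsum("kpd,kd->kp", rel, dirs)
    d2 = np.einsum("kpd,kpd->kp", rel, rel) - proj ** 2
    s = radii[None, :] ** 2 - d2
    return 2.0 * np.sqrt(np.maximum(s, 0.0))


def _project_points(scene, t, geometry, xd_f, yd_f):
    """Absorbance at arbitrary detector coordinates, all angles stacked.

    xd_f, yd_f are flattened detector coordinates (one entry per sample);
    returns (n_angles, n_samples).
    """
    centers = scene.centers_at(t)
    radii = scene.radii
    rho = scene.attenuations
    nspl = xd_f.size
    geo = DetectorGeometry(
        n_rows=1, n_cols=1, pixel_size=geometry.pixel_size,
        angles=geometry.angles, beam_model=geometry.beam_model,
        source_distance=geometry.source_distance,
        detector_distance=geometry.detector_distance)
    out = np.empty((geometry.n_angles, nspl))
    # reuse the ray-direction conventions of the numerical geometry, but the
    # integral itself is the analytic chord, never the voxel kernel
    from .ray_geometry import _rotation_z
    S = geometry.source_distance
    D = geometry.detector_distance
    for a, theta in enumerate(geometry.angles):
        R = _rotation_z(theta)
        if geometry.beam_model == "parallel":
            pts = np.column_stack([np.zeros(nspl), xd_f, yd_f]) @ R.T
            dirs = np.broadcast_to(R @ np.array([1.0, 0.0, 0.0]), (nspl, 3))
        else:
            src = R @ np.array([-S, 0.0, 0.0])
            rel = np.column_stack([np.full(nspl, D + S), xd_f, yd_f]) @ R.T
            dirs = rel / np.linalg.norm(rel, axis=1, keepdims=True)
            pts = np.broadcast_to(src, (nspl, 3))
        chords = _chords(np.ascontiguousarray(pts),
                         np.ascontiguousarray(dirs), centers, radii)
        out[a] = chords @ rho
    return out


def analytic_projection(scene: SphereScene, t: float,
                        geometry: DetectorGeometry) -> Sinogram:
    """Exact projected absorbance at pixel centres (no supersampling)."""
    xd, yd = geometry.pixel_coords()
    XD, YD = np.meshgrid(xd, yd)
    vals = _project_points(scene, t, geometry, XD.ravel(), YD.ravel())
    vals = vals.reshape(geometry.n_angles, geometry.n_rows, geometry.n_cols)
    return Sinogram(values=vals, geometry=geometry)


def supersampled_projection(scene: SphereScene, t: float,
                            geometry: DetectorGeometry) -> Sinogram:
    """Pixel values as the mean of 9 analytic samples per pixel.

    Samples sit on the 3x3 equidistant grid of offsets {-dp/3, 0, +dp/3}^2
    about each pixel centre.
    """
    xd, yd = geometry.pixel_coords()
    XD, YD = np.meshgrid(xd, yd)
    dp = geometry.pixel_size
    acc = np.zeros((geometry.n_angles, XD.size))
    offsets = (-dp / 3.0, 0.0, dp / 3.0)
    for ox in offsets:
        for oy in offsets:
            acc += _project_points(scene, t, geometry,
                                   XD.ravel() + ox, YD.ravel() + oy)
    vals = (acc / 9.0).reshape(
        geometry.n_angles, geometry.n_rows, geometry.n_cols)
    return Sinogram(values=vals, geometry=geometry)


def voxelize(scene: SphereScene, t: float, grid_spec: CellField,
             subsamples: int = 3) -> CellField:
    """Per-cell average attenuation by m^3 equidistant sub-samples per cell.

    Overlapping spheres sum (consistent with the additive projection model).
    """
    m = int(subsamples)
    out = grid_spec.copy()
    out.values = np.zeros_like(out.values)
    n, dx = out.n, out.dx
    centers = scene.centers_at(t)
    off = (np.arange(m) + 0.5) / m * dx      # sub-sample offsets in a cell
    w = 1.0 / m ** 3
    for c, r, rho in zip(centers, scene.radii, scene.attenuations):
        lo = np.floor((c - r - out.origin) / dx).astype(int)
        hi = np.ceil((c + r - out.origin) / dx).astype(int)
        lo = np.clip(lo, 0, n)
        hi = np.clip(hi, 0, n)
        if np.any(hi <= lo):
            continue
        ax = [out.origin[a] + np.arange(lo[a], hi[a]) * dx for a in range(3)]
        sub = [ax[a][:, None] + off[None, :] for a in range(3)]
        d2x = (sub[0] - c[0]) ** 2          # (ncx, m)
        d2y = (sub[1] - c[1]) ** 2
        d2z = (sub[2] - c[2]) ** 2
        inside = (d2x[:, None, None, :, None, None]
                  + d2y[None, :, None, None, :, None]
                  + d2z[None, None, :, None, None, :]) <= r ** 2
        frac = inside.reshape(hi[0] - lo[0], hi[1] - lo[1], hi[2] - lo[2],
                              -1).sum(axis=3) * w
        out.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += rho * frac
    return out


@dataclass
class SinogramSeries:
    """Uniformly sampled absorbance time series: values[time, angle, r, c]."""

    times: np.ndarray
    values: np.ndarray
    geometry: DetectorGeometry = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if len(dt) and np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1e-300):
            raise ValueError("times must be uniformly spaced")
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("one sinogram per time required")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def frame(self, l: int) -> np.ndarray:
        return self.values[l]


def render_series(scene: SphereScene, times,
                  geometry: DetectorGeometry) -> SinogramSeries:
    """Supersampled analytic projection at each requested time.

    Each frame is an independent analytic re-evaluation: the simulator never
    interpolates in time.
    """
    times = np.asarray(times, dtype=float)
    frames = np.empty((times.size, geometry.n_angles,
                       geometry.n_rows, geometry.n_cols))
    for l, t in enumerate(times):
        frames[l] = supersampled_projection(scene, t, geometry).values
    return SinogramSeries(times=times, values=frames, geometry=geometry)


_TRAJECTORY_COLUMNS = ["time", "id", "cx", "cy", "cz", "radius", "density"]


def load_trajectories(path) -> SphereScene:
    """Scene from a tabular trajectory file (time,id,cx,cy,cz,radius,density).

    Centres are interpolated piecewise-linearly between listed times; radius
    and density (attenuation) are taken from the first row per id.  A
    single-time file yields a static scene.
    """
    df = pd.read_csv(path)
    missing = set(_TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    ids = sorted(df["id"].unique())
    spheres, knots, paths = [], [], []
    for sid in ids:
        sub = df[df["id"] == sid].sort_index()
        t = sub["time"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0) and len(t) > 1:
            raise ValueError(f"non-monotone times for sphere id {sid}")
        c = sub[["cx", "cy", "cz"]].to_numpy(dtype=float)
        spheres.append(Sphere(center=tuple(c[0]),
                              radius=float(sub["radius"].iloc[0]),
                              attenuation=float(sub["density"].iloc[0])))
        knots.append(t)
        paths.append(c)

    t0 = max(k[0] for k in knots)
    t1 = min(k[-1] for k in knots)

    def motion(t):
        out = np.empty((len(ids), 3))
        for i, (tk, ck) in enumerate(zip(knots, paths)):
            if tk.size == 1:
                out[i] = ck[0]
            else:
                for a in range(3):
                    out[i, a] = np.interp(t, tk, ck[:, a])
        return out

    if all(k.size == 1 for k in knots):
        return SphereScene(spheres, motion=None)
    return SphereScene(spheres, motion=motion,
                       t_span=(t0, t1 if t1 > t0 else np.inf))


def save_trajectories(scene: SphereScene, times, path) -> None:
    """Export a scene sampled at the given times to the tabular format."""
    rows = []
    for t in np.asarray(times, dtype=float):
        centers = scene.centers_at(t)
        for i, s in enumerate(scene.spheres):
            rows.append((t, i, *centers[i], s.radius, s.attenuation))
    pd.DataFrame(rows, columns=_TRAJECTORY_COLUMNS).to_csv(path, index=False)
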