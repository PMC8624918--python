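"""Error metrics, particle tracking and the phantom benchmark drivers.

RMSE and MAE are applied both to volume residuals (reconstruction minus a
reference volume) and to sinogram residuals (numerically projected state
minus the ground-truth projections).

Particle tracking asks whether the artificial velocity fields produced by
the reconstruction sub-iteration approximate the true kinematics: each true
initial sphere centroid is advected through the recovered velocity series by
classical RK4, sampling the field volume-averaged over the sphere at its
current predicted position, with quadratic temporal interpolation of the
per-step velocity samples.  The normalised centroid error

    delta_c = ||c_recon - c_true||_2 / diameter

is < 1 exactly when the predicted and true sphere volumes overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import phantom
from .phantom import SphereScene, render_series, voxelize
from .ray_geometry import CellField, DetectorGeometry, ProjectionOperator, Sinogram
from .reconstructor import (RecoverySettings, dense_angle_geometry,
                            initial_reconstruction, run_algorithm1)
from .velocity_model import assemble_basis, build_mesh

__all__ = [
    "rmse",
    "mae",
    "make_scenario",
    "TrackingResult",
    "track_particles",
    "overlap_fraction",
    "threshold_volume",
    "run_benchmark",
]


def rmse(residuals) -> float:
    """Root mean squared error sqrt(sum r_i^2 / n)."""
    r = np.asarray(residuals, dtype=float).ravel()
    if r.size == 0:
        raise ValueError("need at least one residual")
    return float(np.sqrt(np.mean(r ** 2)))


def mae(residuals) -> float:
    """Mean absolute error sum |r_i| / n."""
    r = np.asarray(residuals, dtype=float).ravel()
    if r.size == 0:
        raise ValueError("need at least one residual")
    return float(np.mean(np.abs(r)))


@dataclass
class TrackingResult:
    """Per-sphere, per-time normalised centroid errors."""

    times: np.ndarray
    delta_c: np.ndarray      # (T+1, P); nan after a sphere leaves the grid
    max_cfl: np.ndarray      # (P,)
    left_grid: np.ndarray    # (P,) bool
    predicted: np.ndarray    # (T+1, P, 3)

    @property
    def overlap(self) -> np.ndarray:
        """delta_c < 1 (nan counts as no overlap)."""
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.delta_c, nan=np.inf) < 1.0


def _cell_center_basis(basis, grid: CellField):
    """Sparse map from nodal coefficients to cell-centre velocities."""
    import scipy.sparse as sp
    cx, cy, cz = grid.centroids()
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    _, idx, w = basis.mesh.locate(pts)
    rows = np.repeat(np.arange(pts.shape[0]), 4)
    phi = sp.coo_matrix((w.ravel(), (rows, idx.ravel())),
                        shape=(pts.shape[0], basis.n_nodes)).tocsr()
    return phi


def track_particles(scene: SphereScene, alphas: np.ndarray, times,
                    basis, grid: CellField) -> TrackingResult:
    """Advect the true initial centroids through the recovered velocities.

    ``alphas`` holds the per-step clamped nodal coefficients (T, M, 3);
    field alpha_l propagates [t_l, t_{l+1}].  The velocity assigned to a
    sphere at step l is the basis field averaged over grid cells whose
    centres fall inside the sphere at its current predicted centroid
    (point evaluation as fallback when no centre is inside); intermediate
    times use quadratic interpolation of the per-step samples (initial rate
    zero), with the final quadratic extended over the step being integrated.
    """
    times = np.asarray(times, dtype=float)
    T = len(times) - 1
    alphas = np.asarray(alphas, dtype=float)
    if alphas.shape[0] != T:
        raise ValueError("need one coefficient set per step")
    phi_c = _cell_center_basis(basis, grid)
    cx, cy, cz = grid.centroids()
    lo = grid.origin
    hi = grid.origin + grid.extent
    n = grid.n

    centers0 = scene.centers_at(times[0])
    radii = scene.radii
    P = len(radii)
    dt = times[1] - times[0]
    dx = grid.dx

    predicted = np.full((T + 1, P, 3), np.nan)
    predicted[0] = centers0
    delta_c = np.full((T + 1, P), np.nan)
    delta_c[0] = 0.0
    max_cfl = np.zeros(P)
    left = np.zeros(P, dtype=bool)

    def sphere_velocity(l, c, r):
        vel = (phi_c @ alphas[l]).reshape(n, n, n, 3)
        inside = ((cx[:, None, None] - c[0]) ** 2
                  + (cy[None, :, None] - c[1]) ** 2
                  + (cz[None, None, :] - c[2]) ** 2) <= r ** 2
        if np.any(inside):
            return vel[inside].mean(axis=0)
        # fallback: point evaluation at the centroid
        _, idx, w = basis.mesh.locate(c[None, :])
        return (w[0][:, None] * alphas[l][idx[0]]).sum(axis=0)

    from .temporal import build_spline

    samples = [[] for _ in range(P)]   # velocity samples at step starts
    for l in range(T):
        for p in range(P):
            if left[p]:
                continue
            c = predicted[l, p]
            v = sphere_velocity(l, c, radii[p])
            samples[p].append(v)
            max_cfl[p] = max(max_cfl[p],
                             float(np.sum(np.abs(v))) * dt / dx)

            if len(samples[p]) == 1:
                def vel_t(t, v0=v):
                    return v0
            else:
                sp_v = build_spline(times[:l + 1], np.asarray(samples[p]))
                k = l - 1                      # final interval, extended
                a0, a1, a2 = sp_v.a0[k], sp_v.a1[k], sp_v.a2[k]
                tk = times[k]

                def vel_t(t, a0=a0, a1=a1, a2=a2, tk=tk):
                    q = t - tk
                    return a0 * q * q + a1 * q + a2

            # classical RK4 over [t_l, t_l + dt]; the field is spatially
            # frozen at the step-start sphere average, so only time matters
            t_l = times[l]
            k1 = vel_t(t_l)
            k2 = vel_t(t_l + dt / 2)
            k3 = vel_t(t_l + dt / 2)
            k4 = vel_t(t_l + dt)
            c_new = c + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            if np.any(c_new < lo) or np.any(c_new > hi):
                left[p] = True
                continue
            predicted[l + 1, p] = c_new

        true_c = scene.centers_at(times[l + 1])
        for p in range(P):
            if not left[p]:
                delta_c[l + 1, p] = (np.linalg.norm(
                    predicted[l + 1, p] - true_c[p]) / (2 * radii[p]))
    return TrackingResult(times=times, delta_c=delta_c, max_cfl=max_cfl,
                          left_grid=left, predicted=predicted)


def overlap_fraction(tracking: TrackingResult, t_index: int = -1) -> float:
    """Percentage of spheres with delta_c < 1 at the given time index."""
    ov = tracking.overlap[t_index]
    return 100.0 * np.count_nonzero(ov) / ov.size


def threshold_volume(values: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Binary mask of cells >= fraction * (series-wide maximum).

    ``values`` may be a single volume or a whole (T, n, n, n) series; the
    maximum is taken over everything passed in.
    """
    v = np.asarray(values, dtype=float)
    vmax = v.max()
    if vmax <= 0:
        raise ValueError("series maximum must be positive")
    return v >= fraction * vmax


# ---------------------------------------------------------------------------
# benchmark drivers

SPARSE_ANGLES = (-75.0, -35.0, 0.0, 35.0, 75.0)


def _single_sphere_scene(n, n_steps, peak_cfl, radius, attenuation, dt):
    """Axially translating sphere with the sinusoidal velocity profile.

    The axial displacement over the run is (2/pi)*peak_cfl*n_steps*dx; the
    sphere starts half that above the grid centre so the motion is symmetric
    about the mid-plane and stays inside the field of view.
    """
    dx = 1.0 / n
    t_end = n_steps * dt
    z0 = peak_cfl * dx / dt
    displacement = z0 * (2.0 / np.pi) * t_end
    z_start = displacement / 2.0
    if z_start + radius > 0.5 - 2 * dx:
        raise ValueError("sphere leaves the field of view; reduce n_steps, "
                         "peak_cfl or radius")

    def motion(t):
        z = z_start - z0 * (t_end / np.pi) * (1.0 - np.cos(np.pi * t / t_end))
        return np.array([[0.0, 0.0, z]])

    sph = phantom.Sphere(center=(0.0, 0.0, z_start), radius=radius,
                         attenuation=attenuation)
    return SphereScene([sph], motion=motion, t_span=(0.0, t_end))


def _helical_scene(radii=(0.1, 0.1, 1.0 / 9.0), attenuation=1.0):
    """The three-body helical system (central fixed sphere + two revolvers)."""
    return SphereScene.helical(
        phantom.TABLE_HELICAL_PARAMS, radii,
        [attenuation] * 3, t_span=(0.0, np.inf))


def make_scenario(name: str, config: dict = None):
    """Scene, grid, geometry and sample times for a named phantom scenario.

    ``name`` is one of {"single_sphere", "helical", "trajectory_scene"}.
    Scenario config keys (all optional): n, n_steps, dt, peak_cfl, radius,
    radii, attenuation, angles, t0, extent, trajectory_path.
    """
    cfg = dict(config or {})
    n = int(cfg.get("n", 32))
    dt = float(cfg.get("dt", 1.0 if name == "single_sphere" else 0.002))
    n_steps = int(cfg.get("n_steps", 48 if name == "single_sphere" else 100))
    angles = tuple(cfg.get("angles", SPARSE_ANGLES))

    if name == "single_sphere":
        scene = _single_sphere_scene(
            n, n_steps, float(cfg.get("peak_cfl", 0.5)),
            float(cfg.get("radius", 0.15)),
            float(cfg.get("attenuation", 1.0)), dt)
        extent = 1.0
    elif name == "helical":
        scene = _helical_scene(
            radii=tuple(cfg.get("radii", (0.1, 0.1, 1.0 / 9.0))),
            attenuation=float(cfg.get("attenuation", 1.0)))
        extent = 1.0
    elif name == "trajectory_scene":
        path = cfg.get("trajectory_path")
        scene = cfg.get("scene") or phantom.load_trajectories(path)
        extent = float(cfg.get("extent", 1.0))
    else:
        raise ValueError(f"unknown benchmark {name!r}")

    dx = extent / n
    grid = CellField.empty(n, dx)
    geometry = DetectorGeometry(n_rows=n, n_cols=n, pixel_size=dx,
                                angles=angles)
    times = np.arange(n_steps + 1) * dt + float(cfg.get("t0", 0.0))
    return scene, grid, geometry, times


def run_benchmark(name: str, config: dict = None) -> dict:
    """Generate a phantom series, reconstruct it and evaluate the errors.

    Scenario config keys are those of `make_scenario` plus: basis_spacing,
    strategies, f0 ("reconstruct" or "truth"), settings, ref_final (bool:
    reference reconstruction at the final time), outdir.

    Returns a report dict with, per strategy: the ReconstructionResult,
    RMSE/MAE time curves for volumes (vs voxelized truth) and sinograms
    (vs ground truth projections), and tracking errors.
    """
    cfg = dict(config or {})
    strategies = tuple(cfg.get("strategies", ("replace_local_bc",)))
    settings = cfg.get("settings") or RecoverySettings()
    scene, grid, geometry, times = make_scenario(name, cfg)
    extent = grid.extent
    n = grid.n
    series = render_series(scene, times, geometry)

    mesh = build_mesh(grid, float(cfg.get("basis_spacing", extent / 4)))
    basis = assemble_basis(mesh, grid)
    op = ProjectionOperator(geometry, grid)

    if cfg.get("f0", "reconstruct") == "truth":
        f0 = voxelize(scene, times[0], grid)
    else:
        dense_geo = dense_angle_geometry(geometry)
        dense_sino = phantom.supersampled_projection(scene, times[0],
                                                     dense_geo)
        f0 = initial_reconstruction(dense_sino, dense_geo, grid, settings)

    truth = np.stack([voxelize(scene, t, grid).values for t in times])

    report = {"scenario": name, "times": times, "grid": grid,
              "geometry": geometry, "series": series, "basis": basis,
              "f0": f0, "truth_volumes": truth, "per_strategy": {}}

    ref_final = None
    if cfg.get("ref_final", False):
        dense_geo = dense_angle_geometry(geometry)
        dense_sino = phantom.supersampled_projection(scene, times[-1],
                                                     dense_geo)
        ref_final = initial_reconstruction(dense_sino, dense_geo, grid,
                                           settings)
        report["reference_final"] = ref_final

    for strat in strategies:
        result = run_algorithm1(f0, series, geometry, basis, settings,
                                strategy=strat, operator=op)
        vol_rmse = np.array([rmse(result.volumes[l] - truth[l])
                             for l in range(len(times))])
        vol_mae = np.array([mae(result.volumes[l] - truth[l])
                            for l in range(len(times))])
        sino_resid = np.array([op.project(result.volumes[l]) -
                               series.values[l] for l in range(len(times))])
        sino_rmse = np.array([rmse(r) for r in sino_resid])
        sino_mae = np.array([mae(r) for r in sino_resid])
        tracking = track_particles(scene, result.alphas, times, basis, grid)
        entry = {"result": result, "volume_rmse": vol_rmse,
                 "volume_mae": vol_mae, "sino_rmse": sino_rmse,
                 "sino_mae": sino_mae, "tracking": tracking,
                 "final_volume_rmse": vol_rmse[-1]}
        if ref_final is not None:
            entry["final_volume_rmse_ref"] = rmse(
                result.volumes[-1] - ref_final.values)
        report["per_strategy"][strat] = entry

    outdir = cfg.get("outdir")
    if outdir:
        _write_report(report, outdir)
    return report


def _write_report(report, outdir):
    import os

    import pandas as pd

    from . import io as ftio
    os.makedirs(outdir, exist_ok=True)
    times = report["times"]
    for strat, entry in report["per_strategy"].items():
        pd.DataFrame({
            "time": times,
            "rmse_vol": entry["volume_rmse"],
            "mae_vol": entry["volume_mae"],
            "rmse_sino": entry["sino_rmse"],
            "mae_sino": entry["sino_mae"],
        }).to_csv(os.path.join(outdir, f"metrics_{strat}.csv"), index=False)
        tr = entry["tracking"]
        rows = []
        for p in range(tr.delta_c.shape[1]):
            for l, t in enumerate(times):
                rows.append((t, p, tr.delta_c[l, p], tr.max_cfl[p]))
        pd.DataFrame(rows, columns=["time", "sphere_id", "delta_c",
                                    "max_cfl"]).to_csv(
            os.path.join(outdir, f"tracking_{strat}.csv"), index=False)
        grid = report["grid"]
        final = grid.copy()
        final.values = entry["result"].volumes[-1]
        ftio.save_volume(os.path.join(outdir, f"final_{strat}.tif"), final)
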