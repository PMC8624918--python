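"""Time-series reconstruction by continuity-flow propagation.

The pipeline recovers a time series of 3D attenuation volumes from a sparse,
angularly static set of projections:

1.  An initial, fully-sampled volume fbar_0 is reconstructed from a dense
    angular scan at t_0 by least squares (L-BFGS-B from a zero start).
2.  For each measurement step, the rate of the interpolated sinogram drives
    a velocity-recovery subproblem

        argmin_alpha  sum_k ( P_k[ FV[fbar, u(alpha)] ] - dA_k/dt )^2,

    solved by bounded-iteration L-BFGS-B with an analytic adjoint gradient
    and warm starts.  The solution is clamped node-wise to the CFL-feasible
    domain and fbar is advanced with SSPRK3 through the finite-volume
    operator.

The recovered velocities are a vehicle to find continuity-respecting updates
of the attenuation volume; under the right conditions they also approximate
the true kinematics (see `evaluation.track_particles`).

Gradient note: for fixed fbar the limiter and the face states are
independent of u, so each face flux F = a*u - c*|u| is piecewise linear in
the face velocity; the objective gradient follows by the chain rule through
the sparse basis operator, the flux (subgradient convention sign(0) = 0) and
the projector adjoint, and is validated against finite differences in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .finite_volume import fv_rhs, total_attenuation
from .ray_geometry import CellField, DetectorGeometry, ProjectionOperator, Sinogram
from .temporal import STRATEGIES, build_spline, reinterpolate
from .velocity_model import BasisOperator, cfl_clamp, nodal_cfl

__all__ = [
    "RecoverySettings",
    "ReconstructionResult",
    "dense_angle_geometry",
    "initial_reconstruction",
    "velocity_recovery",
    "rhs_algorithm2",
    "run_algorithm1",
    "unknowns_to_equations_ratio",
]


@dataclass
class RecoverySettings:
    """Optimiser caps and options for the velocity-recovery subproblem."""

    max_iterations: int = 20
    max_line_searches: int = 25
    warm_start: bool = True
    gradient_mode: str = "analytic"   # or "finite_difference"
    store_stage_alphas: bool = False
    nonnegative_initial: bool = False

    def __post_init__(self):
        if self.max_iterations <= 0 or self.max_line_searches <= 0:
            raise ValueError("iteration limits must be positive")
        if self.gradient_mode not in ("analytic", "finite_difference"):
            raise ValueError(f"unknown gradient mode {self.gradient_mode!r}")


@dataclass
class ReconstructionResult:
    """Volumes, recovered velocity coefficients and per-step diagnostics."""

    times: np.ndarray
    volumes: np.ndarray          # (T+1, n, n, n)
    alphas: np.ndarray           # (T, M, 3) final-stage clamped coefficients
    stage_alphas: list = None    # optional [(a1, a2, a3), ...] per step
    diagnostics: list = field(default_factory=list)
    grid: CellField = None

    def diagnostics_frame(self):
        import pandas as pd
        return pd.DataFrame(self.diagnostics)


def unknowns_to_equations_ratio(n_cells_side: int, n_angles: int,
                                n_rows: int = None, n_cols: int = None) -> float:
    """Ratio of volume unknowns to measured equations per time point."""
    n_rows = n_cells_side if n_rows is None else n_rows
    n_cols = n_cells_side if n_cols is None else n_cols
    return n_cells_side ** 3 / (n_angles * n_rows * n_cols)


def dense_angle_geometry(geometry: DetectorGeometry,
                         n_angles: int = None) -> DetectorGeometry:
    """Full-rotation geometry for the initial scan.

    Defaults to ceil(N*pi) angles equally spaced in [0, 180), N the detector
    side length in pixels.
    """
    if n_angles is None:
        n_angles = int(np.ceil(geometry.n_cols * np.pi))
    angles = np.arange(n_angles) * (180.0 / n_angles)
    return DetectorGeometry(
        n_rows=geometry.n_rows, n_cols=geometry.n_cols,
        pixel_size=geometry.pixel_size, angles=tuple(angles),
        beam_model=geometry.beam_model,
        source_distance=geometry.source_distance,
        detector_distance=geometry.detector_distance)


def initial_reconstruction(full_sinogram: Sinogram,
                           geometry: DetectorGeometry,
                           grid_spec: CellField,
                           settings: RecoverySettings = None,
                           max_iterations: int = None,
                           operator: ProjectionOperator = None) -> CellField:
    """Least-squares volume from a dense-angle scan, zero start.

    Minimises sum_k (P_k[fbar] - A_k)^2 under the iteration/line-search caps
    (the iteration cap defaults to the detector side length N).
    """
    settings = settings or RecoverySettings()
    if max_iterations is None:
        max_iterations = geometry.n_cols
    op = operator or ProjectionOperator(geometry, grid_spec)
    A = np.asarray(full_sinogram.values, dtype=float).ravel()
    W = op.matrix

    def fun(x):
        r = W @ x - A
        return float(r @ r), 2.0 * (W.T @ r)

    bounds = [(0.0, None)] * W.shape[1] if settings.nonnegative_initial else None
    res = minimize(fun, np.zeros(W.shape[1]), jac=True, method="L-BFGS-B",
                   bounds=bounds,
                   options={"maxiter": max_iterations,
                            "maxls": settings.max_line_searches})
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"initial reconstruction failed: {res.message}")
    out = grid_spec.copy()
    out.values = res.x.reshape((grid_spec.n,) * 3)
    out._objective = float(res.fun)
    out._start_objective = float(A @ A)
    return out


class _VelocityObjective:
    """sum_k (P_k[FV[fbar, u(alpha)]] - b_k)^2 and its adjoint gradient.

    Face states depend only on fbar and are precomputed; per evaluation the
    cost is three sparse basis matvecs, the flux arrays, and one projector
    matvec pair.
    """

    def __init__(self, fbar: np.ndarray, rate_targets: np.ndarray,
                 basis: BasisOperator, operator: ProjectionOperator,
                 dx: float):
        from .finite_volume import face_states
        self.basis = basis
        self.op = operator
        self.dx = dx
        self.b = np.asarray(rate_targets, dtype=float).ravel()
        self.a = []
        self.c = []
        for axis in range(3):
            fL, fR = face_states(fbar, axis)
            self.a.append(0.5 * (fR + fL))
            self.c.append(0.5 * (fR - fL))
        self.shape = fbar.shape

    def rhs_from_faces(self, faces) -> np.ndarray:
        rhs = np.zeros(self.shape)
        for axis in range(3):
            u = faces[axis]
            F = u * self.a[axis] - np.abs(u) * self.c[axis]
            rhs -= np.diff(F, axis=axis) / self.dx
        return rhs

    def __call__(self, alpha_flat: np.ndarray):
        alpha = alpha_flat.reshape(-1, 3)
        fv = self.basis.face_velocities(alpha)
        faces = [fv.u, fv.v, fv.w]
        rhs = self.rhs_from_faces(faces)
        r = self.op.project_flat(rhs.ravel()) - self.b
        J = float(r @ r)
        g = (2.0 * (self.op.matrix.T @ r)).reshape(self.shape)
        grads = []
        for axis in range(3):
            pad = [(0, 0)] * 3
            pad[axis] = (1, 1)
            gpad = np.pad(g, pad)
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            # face i enters rhs_i with +1/dx and rhs_{i-1} with -1/dx
            dJdF = (gpad[tuple(hi)] - gpad[tuple(lo)]) / self.dx
            u = faces[axis]
            dJdu = dJdF * (self.a[axis] - self.c[axis] * np.sign(u))
            grads.append(dJdu)
        galpha = self.basis.gradient_adjoint(grads)
        if not (np.isfinite(J) and np.all(np.isfinite(galpha))):
            raise RuntimeError("non-finite objective or gradient")
        return J, galpha.ravel()


def velocity_recovery(fbar: np.ndarray, rate_targets: np.ndarray,
                      basis: BasisOperator, operator: ProjectionOperator,
                      dx: float, settings: RecoverySettings = None,
                      warm_start: np.ndarray = None):
    """Approximate minimiser of the projected-rate least squares in alpha.

    Returns (alpha_star (M, 3), objective_value).  Coefficients are
    unbounded here; CFL feasibility is enforced post hoc by the clamp.
    """
    settings = settings or RecoverySettings()
    obj = _VelocityObjective(fbar, rate_targets, basis, operator, dx)
    x0 = (np.zeros((basis.n_nodes, 3)) if warm_start is None
          else np.asarray(warm_start, dtype=float)).ravel().copy()
    if settings.gradient_mode == "analytic":
        fun, jac = obj, True
    else:
        def fun(x):
            return obj(x)[0]
        jac = None
    res = minimize(fun, x0, jac=jac, method="L-BFGS-B",
                   options={"maxiter": settings.max_iterations,
                            "maxls": settings.max_line_searches})
    alpha = res.x.reshape(-1, 3)
    if not np.all(np.isfinite(alpha)):
        raise RuntimeError(f"velocity recovery failed: {res.message}")
    return alpha, float(res.fun)


def rhs_algorithm2(t: float, fbar: np.ndarray, spline, basis: BasisOperator,
                   operator: ProjectionOperator, dx: float, dt: float,
                   settings: RecoverySettings = None,
                   warm_start: np.ndarray = None):
    """Velocity-recovery step: solve, clamp, evaluate FV[fbar, u].

    Returns (dfbar/dt, clamped alpha, diagnostics dict).
    """
    settings = settings or RecoverySettings()
    rate = spline.rate(t)
    alpha_star, obj = velocity_recovery(
        fbar, rate, basis, operator, dx, settings,
        warm_start if settings.warm_start else None)
    cfl_pre = float(np.max(nodal_cfl(alpha_star, dt, dx))) \
        if alpha_star.size else 0.0
    alpha = cfl_clamp(alpha_star, dt, dx)
    cfl_post = float(np.max(nodal_cfl(alpha, dt, dx))) if alpha.size else 0.0
    faces = basis.face_velocities(alpha)
    rhs = fv_rhs(fbar, faces, dx)
    diag = {"objective": obj, "cfl_pre_clamp": cfl_pre,
            "cfl_post_clamp": cfl_post}
    return rhs, alpha, diag


def run_algorithm1(f0: CellField, series, geometry: DetectorGeometry,
                   basis: BasisOperator, settings: RecoverySettings = None,
                   strategy: str = "replace_local_bc",
                   operator: ProjectionOperator = None) -> ReconstructionResult:
    """Propagate the initial volume over the measurement series.

    Per step: project the current state, re-interpolate the measurement
    spline per strategy, run the three SSPRK3 stage solves (rate targets at
    t_l, t_l + dt, t_l + dt/2), update fbar, and warm-start the next step
    from the third-stage clamped coefficients.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    settings = settings or RecoverySettings()
    op = operator or ProjectionOperator(geometry, f0)
    times = np.asarray(series.times, dtype=float)
    dt = float(times[1] - times[0])
    dx = f0.dx
    n = f0.n
    T = times.size - 1

    base_spline = build_spline(times, series.values)

    volumes = np.empty((T + 1, n, n, n))
    volumes[0] = f0.values
    alphas = np.empty((T, basis.n_nodes, 3))
    stage_alphas = [] if settings.store_stage_alphas else None
    diagnostics = []

    fbar = f0.values.copy()
    alpha_init = np.zeros((basis.n_nodes, 3))
    for l in range(T):
        t_l = times[l]
        projected = op.project(fbar)
        spline = reinterpolate(base_spline, l, projected, strategy)

        def alg2(t, f):
            return rhs_algorithm2(t, f, spline, basis, op, dx, dt,
                                  settings, alpha_init)

        try:
            k1, a1, d1 = alg2(t_l, fbar)
            k2, a2, d2 = alg2(t_l + dt, fbar + dt * k1)
            k3, a3, d3 = alg2(t_l + dt / 2.0, fbar + dt * (k1 + k2) / 4.0)
        except RuntimeError:
            # abort with partial results on stage failure
            return ReconstructionResult(
                times=times[:l + 1], volumes=volumes[:l + 1],
                alphas=alphas[:l], stage_alphas=stage_alphas,
                diagnostics=diagnostics, grid=f0)
        fbar = fbar + dt / 6.0 * (k1 + k2 + 4.0 * k3)
        volumes[l + 1] = fbar
        alphas[l] = a3
        if stage_alphas is not None:
            stage_alphas.append((a1, a2, a3))
        alpha_init = a3

        resid = op.project(fbar) - series.values[l + 1]
        diagnostics.append({
            "time": times[l + 1],
            "objective_k1": d1["objective"],
            "objective_k3": d3["objective"],
            "cfl_pre_clamp": max(d["cfl_pre_clamp"] for d in (d1, d2, d3)),
            "cfl_post_clamp": max(d["cfl_post_clamp"] for d in (d1, d2, d3)),
            "projection_rmse": float(np.sqrt(np.mean(resid ** 2))),
            "total_attenuation": total_attenuation(fbar, dx),
        })
    return ReconstructionResult(times=times, volumes=volumes, alphas=alphas,
                                stage_alphas=stage_alphas,
                                diagnostics=diagnostics, grid=f0)
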