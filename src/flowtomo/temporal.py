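"""Temporal machinery: measurement interpolation and SSPRK3 stepping.

Projected rates dA_k/dt drive the velocity recovery, but only the sampled
absorbances A_k(t_0), ..., A_k(t_T) are measured.  They are interpolated by
a piecewise-quadratic spline, the lowest-order polynomial interpolation with
a continuous first derivative.  On interval l, in local time q = t - t_l,

    A(q) = a0 q^2 + a1 q + a2,

with a2 fixed by the value at t_l, a1 by derivative continuity with the
previous interval (the sample is assumed to start from rest: dA/dt = 0 at
t_0), and a0 by the value at t_{l+1}.

During reconstruction the propagated state drifts off the data path, so
before each step the spline may be *re-interpolated* with the projection of
the current state substituted at the current knot.  Three strategies:

- ``original_static_bc``: ignore the current state, keep the original spline.
- ``replace_static_bc``: substitute at t_l, rebuild the whole spline from
  t_0 with the static (zero initial rate) boundary condition.
- ``replace_local_bc``: redefine only interval [t_l, t_{l+1}]: value equals
  the substituted state at t_l, the original datum at t_{l+1}, and the end
  rate equals the original spline's rate there, so from t_{l+1} onwards the
  re-interpolation rejoins the original path.

Time stepping is third-order strong-stability-preserving Runge-Kutta
(SSPRK3) with stage times t, t + dt, t + dt/2; it preserves the TVD property
of the spatial operator for CFL <= 0.5 and its quadrature (weights 1/6, 1/6,
4/6 at nodes 0, 1, 1/2) is Simpson's rule, exact for the quadratic data
model over a single step.
"""

from __future__ import annotations

import numpy as np

from .finite_volume import FaceVelocities

__all__ = ["QuadraticSpline", "STRATEGIES", "build_spline", "reinterpolate",
           "ssprk3_step", "cfl_number"]

STRATEGIES = ("original_static_bc", "replace_static_bc", "replace_local_bc")


class QuadraticSpline:
    """Piecewise-quadratic, derivative-continuous interpolation.

    ``values`` may be an array of any shape per knot (e.g. a flattened
    sinogram); coefficients are stored per interval in local time q = t-t_l.
    """

    def __init__(self, knots, a0, a1, a2, values):
        self.knots = np.asarray(knots, dtype=float)
        self.a0 = a0
        self.a1 = a1
        self.a2 = a2
        self.values = values    # the data the spline was built from

    @property
    def n_intervals(self) -> int:
        return len(self.knots) - 1

    def _interval(self, t: float) -> int:
        k = self.knots
        if t < k[0] - 1e-12 or t > k[-1] + 1e-12:
            raise ValueError(f"t={t} outside spline domain [{k[0]}, {k[-1]}]")
        l = int(np.searchsorted(k, t, side="right") - 1)
        return min(max(l, 0), self.n_intervals - 1)

    def evaluate(self, t: float) -> np.ndarray:
        l = self._interval(t)
        q = t - self.knots[l]
        return self.a0[l] * q * q + self.a1[l] * q + self.a2[l]

    def rate(self, t: float) -> np.ndarray:
        """dA/dt at time t (continuous at interior knots)."""
        l = self._interval(t)
        q = t - self.knots[l]
        return 2.0 * self.a0[l] * q + self.a1[l]

    def copy(self) -> "QuadraticSpline":
        return QuadraticSpline(self.knots.copy(), self.a0.copy(),
                               self.a1.copy(), self.a2.copy(),
                               self.values.copy())


def build_spline(times, values, initial_rate=0.0) -> QuadraticSpline:
    """Left-to-right construction chaining derivative continuity from t_0.

    Interval l matches the data at t_l and t_{l+1} and starts with the end
    rate of interval l-1 (interval 0 starts with ``initial_rate``, the
    static-start boundary condition by default).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("need at least two knots")
    if np.any(np.diff(times) <= 0):
        raise ValueError("knots must be strictly increasing")
    values = np.asarray(values, dtype=float)
    if values.shape[0] != times.size:
        raise ValueError("one value (array) per knot required")
    T = times.size - 1
    a0 = np.empty((T,) + values.shape[1:])
    a1 = np.empty_like(a0)
    a2 = np.empty_like(a0)
    slope = np.broadcast_to(np.asarray(initial_rate, dtype=float),
                            values.shape[1:]).copy()
    for l in range(T):
        dt = times[l + 1] - times[l]
        a2[l] = values[l]
        a1[l] = slope
        a0[l] = (values[l + 1] - values[l] - slope * dt) / dt ** 2
        slope = 2.0 * a0[l] * dt + a1[l]
    return QuadraticSpline(times, a0, a1, a2, values.copy())


def reinterpolate(spline: QuadraticSpline, l: int, replaced_value,
                  strategy: str) -> QuadraticSpline:
    """Substitute the current projected state at knot l per strategy."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if not 0 <= l < spline.n_intervals:
        raise ValueError("knot index out of range")
    if strategy == "original_static_bc":
        return spline
    if strategy == "replace_static_bc":
        vals = spline.values.copy()
        vals[l] = replaced_value
        return build_spline(spline.knots, vals)
    # replace_local_bc: redefine only interval [t_l, t_{l+1}]
    out = spline.copy()
    dt = spline.knots[l + 1] - spline.knots[l]
    end_rate = 2.0 * spline.a0[l] * dt + spline.a1[l]   # original end rate
    v_next = spline.values[l + 1]
    rv = np.asarray(replaced_value, dtype=float)
    d = v_next - rv
    out.a2[l] = rv
    out.a0[l] = (end_rate * dt - d) / dt ** 2
    out.a1[l] = end_rate - 2.0 * out.a0[l] * dt
    return out


def ssprk3_step(t: float, state, dt: float, rhs_operator):
    """One SSPRK3 step: stages at t, t + dt, t + dt/2.

        k1 = D(t, f)
        k2 = D(t + dt, f + dt k1)
        k3 = D(t + dt/2, f + dt (k1 + k2)/4)
        f+ = f + dt/6 (k1 + k2 + 4 k3)
    """
    k1 = rhs_operator(t, state)
    k2 = rhs_operator(t + dt, state + dt * k1)
    k3 = rhs_operator(t + dt / 2.0, state + dt * (k1 + k2) / 4.0)
    return state + dt / 6.0 * (k1 + k2 + 4.0 * k3)


def cfl_number(faces: FaceVelocities, dt: float, dx: float) -> float:
    """Grid CFL number max_i (|u_x| + |u_y| + |u_z|)_i * dt / dx.

    Each cell's component magnitude is the larger of its two face values in
    that axis.
    """
    total = None
    for axis in range(3):
        u = np.abs(faces.component(axis))
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        cell = np.maximum(u[tuple(lo)], u[tuple(hi)])
        total = cell if total is None else total + cell
    return float(np.max(total) * dt / dx) if total.size else 0.0
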