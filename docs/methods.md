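# Methods

## Model and assumptions

The reconstruction target is a scalar attenuation field f(x, t) on a cubic
cell grid, observed through absorbances A_k = log(I0_k/I1_k) modelled as line
integrals along fixed rays (Beer's law). The method assumes:

- **Closed system.** No mass enters or leaves the field of view, so f obeys
  the continuity equation ∂f/∂t + ∇·(f u) = 0 for some velocity field u.
  This is enforced discretely: zero ghost cells and zero velocity on
  domain-boundary faces make the finite-volume update exactly conservative
  (total attenuation Σ f̄·Δx³ is constant to round-off).
- **Static start.** The sample is at rest before the dynamics are triggered,
  so a full-rotation scan at t₀ provides the initial volume, and the
  temporal spline starts with ∂A/∂t = 0 at t₀.
- **Sub-cell motion per frame.** The explicit scheme requires the CFL number
  (|u_x|+|u_y|+|u_z|)·Δt/Δx ≤ 1; the acquisition rate must resolve the
  motion to sub-pixel displacements per frame.
- **Representable kinematics.** The velocity is parametrised on a coarse
  tetrahedral linear FE basis; flows with spatial variation finer than the
  node spacing cannot be represented exactly, although the attenuation field
  itself is unrestricted (sharp interfaces are handled by the TVD limiter).

The recovered velocities are a vehicle for continuity-respecting updates of
the attenuation volume, not a measurement of the flow — although on the
benchmark systems they track the true kinematics well (tracking errors of a
few percent of a sphere diameter).

## Discretisation

**Spatial operator.** Kurganov–Tadmor central flux
F = u/2·(fR+fL) − |u|/2·(fR−fL) on MUSCL-extrapolated face states limited by
superbee, φ(r) = max(0, min(2r, 1), min(r, 2)), with φ = 2 in the degenerate
branch where the slope-ratio denominator vanishes (the limited increment is
then exactly zero, so the branch value is only a convention — kept explicit
so the branch is not "optimised" away inconsistently). Each axis is treated
independently with the same one-dimensional stencil.

**Time integrator.** SSPRK3 with stage times t, t+Δt, t+Δt/2 and final
weights (1/6, 1/6, 4/6). The quadrature is Simpson's rule, exact for the
quadratic-in-time data model over one step; combined with the limiter the
scheme is empirically TVD and positivity-preserving at CFL ≤ 0.5 (asserted
over 200 steps in the tests). Δt is locked to the measurement spacing;
sub-stepping is out of scope.

**Projector.** Exact intersection-length (Siddon-style) kernel assembled
once per (geometry, grid) pair as a sparse CSR matrix; projection and
backprojection are matvecs with the matrix and its transpose, so the adjoint
identity holds to machine precision. Parallel beam is the default; the
point-source geometry is retained and converges to the parallel projector as
the source and detector distances grow (with the detector pixel scaled by
the magnification). The same operator is applied to rate fields ∂f̄/∂t — no
separate code path.

**Velocity basis.** Structured Kuhn subdivision: the grid bounding box is
split into K³ cubic macro-cells (K = ⌈extent/node_spacing⌉), each into 6
tetrahedra. This is reproducible without an external mesher; the published
element counts of the reference experiments came from an unspecified mesher
and are treated as configuration, not targets. Every element's circumsphere
has the macro-cell main diagonal as diameter (radius h·√3/2), reported per
element for comparison with quoted ranges. The basis is evaluated only at
face centroids (and cell centres for tracking), precomputed as sparse
matrices, exactly linear in the nodal coefficients.

**CFL clamp.** Nodal: C_j = (|α_jx|+|α_jy|+|α_jz|)·Δt/Δx, scaled by 1/C_j
when C_j ≥ 1 (the ≥ trigger of the pseudo-code variant; the difference from
a strict > affects only the measure-zero C = 1 case). Clamping coefficient
magnitudes rather than pointwise field values is conservative: interior
field values are convex combinations of nodal values.

## Velocity recovery

Per SSPRK3 stage, argmin_α Σ_k (P_k[FV[f̄, u(α)]] − ∂A_k/∂t)², a plain sum
of squares with no ½ factor, minimised by L-BFGS-B capped at 20 iterations
and 25 line searches (optimizer defaults otherwise; tolerances logged, not
tuned). Coefficients are unbounded in the optimizer — feasibility is
restored post hoc by the clamp. All three stage solves of a step warm-start
from the previous step's third-stage (clamped) solution, and the next step
warm-starts from this step's third stage.

**Gradient.** For fixed f̄ the limiter and face states are independent of u,
so each face flux F = a·u − c·|u| (a, c precomputed from the face states) is
piecewise linear in the face velocity. The objective gradient is assembled
by the chain rule: projector adjoint → flux-divergence adjoint →
(a − c·sign(u)) with the subgradient convention sign(0) = 0 → sparse basis
transpose. It is validated against central finite differences (< 1e-4
relative at states bounded away from the |u| kinks); a finite-difference
fallback mode exists for debugging.

**Initial volume.** Least squares over a dense scan of ⌈Nπ⌉ equally spaced
angles in [0°, 180°) (N the detector side), L-BFGS-B from a zero start with
the iteration cap equal to N. A non-negativity bound is available behind a
flag but off by default. For tests isolating propagation error, f̄₀ can be
injected from the voxelized truth instead.

**Re-interpolation.** The default strategy is the local boundary condition:
only the current interval is rebuilt from the substituted projected state,
with its end rate forced to the original spline's, so the re-interpolation
rejoins the original data path at t_{l+1}. The two alternatives (keeping the
original spline; rebuilding the whole spline from t₀ with the static start)
are selectable for strategy comparisons; the state-replacing strategies
consistently beat the original-data strategy on final volume RMSE in the
benchmarks. The spline is stored in local time q = t − t_l for conditioning.

## Synthetic data

The phantom module is the independent oracle: projected absorbances of
sphere ensembles are evaluated analytically (chord = 2ρ·Re√(r² − d²), summed
over spheres, overlaps adding), never through the reconstruction-side ray
kernel. Pixels are supersampled as the mean of a 3×3 equidistant grid of
offsets {−Δp/3, 0, +Δp/3}² about the pixel centre. Ground-truth volumes are
voxelized with m³ = 27 sub-samples per cell.

It emulates: ideal line-integral absorbance of monodisperse-density
spherical particles with prescribed motion (helical three-body system,
sinusoidal axial translation, imported piecewise-linear trajectory tables).
It does **not** emulate detector noise, photon statistics, beam hardening,
phase contrast, polydisperse shapes, or motion blur within a frame — a green
benchmark therefore establishes correctness of the propagation and recovery
machinery on clean data, not robustness to real measurement artefacts.

**Benchmark scaling.** The reference experiments use 64³ grids and 501
frames; the shipped benchmarks run at n = 32 to stay within desk-scale CPU
budgets. Two scaling constraints are fixed a priori by geometry, not by test
outcomes: for the sinusoidal single-sphere benchmark the total axial travel
is (2/π)·peakCFL·n_steps·Δx, so the sphere (radius 0.15 of the 1-unit field
of view) stays inside the grid for 48 steps at peak CFL 0.5 — the
strategy-comparison configuration — while the 100-step conservation run uses
peak CFL 0.25. The helical three-body system keeps the published trajectory
parameters, radii in the published range (the central fixed sphere gets the
top of the range, the two revolvers the bottom), the physical 2 ms frame
spacing and the five angles (−75°, −35°, 0°, 35°, 75°); 100 steps cover the
first 0.2 s of the 1 s path. Velocity-basis node spacing defaults to a
quarter of the field of view.

## Numerical choices and degenerate inputs

- Rays that miss the grid contribute zero (length 0), not an error.
- Sinogram series must be uniformly sampled (1e-9 relative); the RK step
  equals the sampling interval.
- Degenerate tetrahedra abort mesh construction; face centroids outside the
  mesh abort basis assembly (the structured mesh always covers the grid, so
  this guards imported configurations).
- A sphere whose tracked centroid leaves the grid is flagged and its
  tracking stops; it counts as non-overlapping thereafter.
- Tracking velocity per sphere and step is the basis field averaged over
  cell centres inside the sphere (point evaluation at the centroid as
  fallback), temporally interpolated by the same quadratic spline machinery
  with zero initial rate; within the step being integrated the final
  quadratic is extended. RK4 is classical; the sampled field is spatially
  frozen at the step-start sphere average.
- The pipeline is fully deterministic: identical inputs give bit-identical
  outputs.

## Known limitations

- Error build-up: propagation error grows over the first ~100 steps before
  plateauing at a few times the inherent ray-model discrepancy; the initial
  projected residual is close to zero but not zero because the analytic and
  numerical ray models differ.
- The velocity basis limits recoverable kinematics; dense many-particle
  systems with velocity variation below the node spacing degrade gracefully
  (mass distribution preserved, individual kinematics lost).
- No noise model, no regularisation of the initial reconstruction, no
  rotation-during-acquisition geometries, no cone-beam weighting or detector
  tilt, no GPU kernels.
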