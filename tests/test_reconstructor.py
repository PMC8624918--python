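import numpy as np
import pytest

import flowtomo as ft
from flowtomo.phantom import SinogramSeries
from flowtomo.ray_geometry import ProjectionOperator
from flowtomo.reconstructor import (RecoverySettings, _VelocityObjective,
                                    dense_angle_geometry,
                                    initial_reconstruction, rhs_algorithm2,
                                    run_algorithm1,
                                    unknowns_to_equations_ratio,
                                    velocity_recovery)
from flowtomo.temporal import build_spline
from flowtomo.velocity_model import assemble_basis, build_mesh, nodal_cfl


@pytest.fixture
def recovery_setup():
    n = 12
    grid = ft.CellField.empty(n, 1.0 / n)
    geo = ft.DetectorGeometry(n_rows=n, n_cols=n, pixel_size=1.0 / n,
                              angles=(-75.0, -35.0, 0.0, 35.0, 75.0))
    op = ProjectionOperator(geo, grid)
    basis = assemble_basis(build_mesh(grid, 0.5), grid)
    return grid, geo, op, basis


def test_unknowns_to_equations_ratio_reference_configuration():
    # 64^3 cells observed through five 64x64 projections
    assert unknowns_to_equations_ratio(64, 5) == pytest.approx(12.8)
    assert unknowns_to_equations_ratio(64, 5) > 10.0


def test_dense_angle_geometry_defaults():
    geo = ft.DetectorGeometry(n_rows=32, n_cols=32, pixel_size=1.0,
                              angles=(0.0,))
    dense = dense_angle_geometry(geo)
    assert dense.n_angles == int(np.ceil(32 * np.pi))   # 101
    a = np.asarray(dense.angles)
    assert a[0] == 0.0 and a[-1] < 180.0
    assert np.allclose(np.diff(a), 180.0 / dense.n_angles)


class TestInitialReconstruction:
    def test_zero_sinogram_gives_zero_field(self):
        n = 8
        grid = ft.CellField.empty(n, 1.0)
        geo = dense_angle_geometry(ft.DetectorGeometry(
            n_rows=n, n_cols=n, pixel_size=1.0, angles=(0.0,)), 10)
        sino = ft.Sinogram(values=np.zeros((10, n, n)), geometry=geo)
        f = initial_reconstruction(sino, geo, grid)
        assert np.all(f.values == 0.0)

    def test_single_static_sphere_full_scale(self):
        """Dense-angle least squares at n = 64 (202 angles) recovers a
        12-cell-radius sphere to < 10% volume RMSE, with a residual
        reduction factor well above 10."""
        n = 64
        grid = ft.CellField.empty(n, 1.0 / n)
        geo = dense_angle_geometry(ft.DetectorGeometry(
            n_rows=n, n_cols=n, pixel_size=1.0 / n, angles=(0.0,)))
        assert geo.n_angles == 202
        scene = ft.SphereScene([ft.Sphere(center=(0.05, -0.03, 0.08),
                                          radius=12 / 64, attenuation=1.0)])
        sino = ft.supersampled_projection(scene, 0.0, geo)
        f0 = initial_reconstruction(sino, geo, grid)
        truth = ft.voxelize(scene, 0.0, grid)
        assert np.sqrt(np.mean((f0.values - truth.values) ** 2)) < 0.1
        assert f0._start_objective / f0._objective > 10.0


class TestVelocityRecovery:
    def test_zero_targets_zero_start_stays_zero(self, recovery_setup, rng):
        grid, geo, op, basis = recovery_setup
        f = rng.uniform(0, 1, size=(12, 12, 12))
        alpha, obj = velocity_recovery(
            f, np.zeros(geo.n_pixels), basis, op, grid.dx)
        assert np.all(alpha == 0.0)
        assert obj == 0.0

    def test_analytic_gradient_matches_finite_differences(self,
                                                          recovery_setup,
                                                          rng):
        """Adjoint gradient vs central differences at 20 random states with
        all face velocities bounded away from the |u| kinks."""
        grid, geo, op, basis = recovery_setup
        worst = 0.0
        for _ in range(20):
            f = rng.uniform(0, 1, size=(12, 12, 12))
            signs = np.sign(rng.uniform(-1, 1, size=(1, 3)))
            alpha = rng.uniform(0.1, 0.4,
                                size=(basis.n_nodes, 3)) * grid.dx * signs
            b = rng.normal(size=geo.n_pixels)
            obj = _VelocityObjective(f, b, basis, op, grid.dx)
            _, g = obj(alpha.ravel())
            h = 1e-6 * grid.dx
            for c in rng.integers(0, alpha.size, size=6):
                x1 = alpha.ravel().copy()
                x2 = alpha.ravel().copy()
                x1[c] += h
                x2[c] -= h
                fd = (obj(x1)[0] - obj(x2)[0]) / (2 * h)
                worst = max(worst, abs(fd - g[c]) / max(abs(fd), 1e-12))
        assert worst < 1e-4

    def test_warm_start_is_honoured(self, recovery_setup, rng):
        grid, geo, op, basis = recovery_setup
        f = rng.uniform(0, 1, size=(12, 12, 12))
        warm = rng.normal(scale=0.01 * grid.dx, size=(basis.n_nodes, 3))
        # zero targets: objective is minimised over iterates starting at
        # warm, so the result cannot be worse than the warm start itself
        obj = _VelocityObjective(f, np.zeros(geo.n_pixels), basis, op,
                                 grid.dx)
        j_warm = obj(warm.ravel())[0]
        _, j_opt = velocity_recovery(f, np.zeros(geo.n_pixels), basis, op,
                                     grid.dx, warm_start=warm)
        assert j_opt <= j_warm + 1e-15


class TestRhsAlgorithm2:
    def test_static_scene_zero_everything(self, recovery_setup, rng):
        grid, geo, op, basis = recovery_setup
        f = rng.uniform(0, 1, size=(12, 12, 12))
        spline = build_spline([0.0, 1.0, 2.0],
                              np.zeros((3,) + (geo.n_angles, 12, 12)))
        rhs, alpha, diag = rhs_algorithm2(0.5, f, spline, basis, op,
                                          grid.dx, 1.0)
        assert np.all(rhs == 0.0)
        assert np.all(alpha == 0.0)

    def test_clamp_postcondition_and_conservation(self, recovery_setup, rng):
        grid, geo, op, basis = recovery_setup
        f = rng.uniform(0, 1, size=(12, 12, 12))
        vals = rng.normal(size=(3, geo.n_angles, 12, 12))
        spline = build_spline([0.0, 1.0, 2.0], vals)
        rhs, alpha, diag = rhs_algorithm2(0.5, f, spline, basis, op,
                                          grid.dx, 1.0)
        assert np.max(nodal_cfl(alpha, 1.0, grid.dx)) <= 1.0 + 1e-12
        # zero-boundary velocities: the rhs moves no mass in or out
        assert abs(np.sum(rhs)) < 1e-9 * np.sum(np.abs(rhs) + 1e-300)


class TestRunAlgorithm1:
    def test_static_model_consistent_data_is_identity(self, rng):
        """With measurements equal to the numerical projection of the
        initial state, every re-interpolation strategy propagates the
        volume unchanged (zero rates, zero recovered velocities)."""
        n = 12
        grid = ft.CellField.empty(n, 1.0 / n)
        geo = ft.DetectorGeometry(n_rows=n, n_cols=n, pixel_size=1.0 / n,
                                  angles=(-75.0, 0.0, 75.0))
        op = ProjectionOperator(geo, grid)
        scene = ft.SphereScene([ft.Sphere(center=(0, 0, 0), radius=0.25,
                                          attenuation=1.0)])
        f0 = ft.voxelize(scene, 0.0, grid)
        frame = op.project(f0.values)
        T = 50
        series = SinogramSeries(
            times=np.arange(T + 1, dtype=float),
            values=np.tile(frame, (T + 1, 1, 1, 1)), geometry=geo)
        basis = assemble_basis(build_mesh(grid, 0.5), grid)
        for strategy in ("original_static_bc", "replace_local_bc"):
            result = run_algorithm1(f0, series, geo, basis,
                                    strategy=strategy)
            drift = np.max(np.abs(result.volumes[-1] - f0.values))
            assert drift < 1e-6 * f0.values.max()
            assert np.all(result.alphas == 0.0)

    def test_determinism(self, rng):
        n = 10
        grid = ft.CellField.empty(n, 1.0 / n)
        geo = ft.DetectorGeometry(n_rows=n, n_cols=n, pixel_size=1.0 / n,
                                  angles=(-35.0, 0.0, 35.0))
        scene = ft.SphereScene(
            [ft.Sphere(center=(0, 0, 0.15), radius=0.2, attenuation=1.0)],
            motion=lambda t: np.array([[0, 0, 0.15 - 0.02 * t]]))
        times = np.arange(4.0)
        series = ft.render_series(scene, times, geo)
        f0 = ft.voxelize(scene, 0.0, grid)
        basis = assemble_basis(build_mesh(grid, 0.5), grid)
        r1 = run_algorithm1(f0, series, geo, basis)
        r2 = run_algorithm1(f0, series, geo, basis)
        assert np.array_equal(r1.volumes, r2.volumes)
        assert np.array_equal(r1.alphas, r2.alphas)

    def test_partial_result_structure(self, rng):
        # diagnostics exist per step with finite entries
        n = 10
        grid = ft.CellField.empty(n, 1.0 / n)
        geo = ft.DetectorGeometry(n_rows=n, n_cols=n, pixel_size=1.0 / n,
                                  angles=(0.0, 75.0))
        scene = ft.SphereScene([ft.Sphere(center=(0, 0, 0), radius=0.2,
                                          attenuation=1.0)])
        series = ft.render_series(scene, np.arange(3.0), geo)
        f0 = ft.voxelize(scene, 0.0, grid)
        basis = assemble_basis(build_mesh(grid, 0.5), grid)
        settings = RecoverySettings(store_stage_alphas=True)
        result = run_algorithm1(f0, series, geo, basis, settings)
        df = result.diagnostics_frame()
        assert len(df) == 2
        assert np.all(np.isfinite(df["projection_rmse"]))
        assert np.all(df["cfl_post_clamp"] <= 1.0 + 1e-12)
        assert len(result.stage_alphas) == 2
        assert len(result.stage_alphas[0]) == 3


def test_settings_validation():
    with pytest.raises(ValueError):
        RecoverySettings(max_iterations=0)
    with pytest.raises(ValueError):
        RecoverySettings(gradient_mode="magic")
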