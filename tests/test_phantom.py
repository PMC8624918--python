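import numpy as np
import pytest

import flowtomo as ft
from flowtomo import phantom


def _single_sphere_scene(center=(0, 0, 0), radius=0.25, rho=2.0):
    return ft.SphereScene([ft.Sphere(center=center, radius=radius,
                                     attenuation=rho)])


def _odd_geometry(n=9, pixel=0.1, angles=(0.0,)):
    # odd pixel counts put a pixel centre exactly on the optical axis
    return ft.DetectorGeometry(n_rows=n, n_cols=n, pixel_size=pixel,
                               angles=angles)


class TestAnalyticProjection:
    def test_central_ray_gives_diameter_chord(self):
        scene = _single_sphere_scene(radius=0.3, rho=2.0)
        geo = _odd_geometry()
        sino = ft.analytic_projection(scene, 0.0, geo)
        assert sino.values[0, 4, 4] == pytest.approx(2 * 2.0 * 0.3)

    def test_missing_ray_is_zero(self):
        scene = _single_sphere_scene(radius=0.05, rho=2.0)
        geo = _odd_geometry()
        sino = ft.analytic_projection(scene, 0.0, geo)
        assert sino.values[0, 0, 0] == 0.0   # corner pixel misses

    def test_point_source_formula_matches_perpendicular_distance(self):
        scene = _single_sphere_scene(center=(0.1, -0.05, 0.02),
                                     radius=0.2, rho=1.5)
        geo = ft.DetectorGeometry(
            n_rows=9, n_cols=9, pixel_size=0.1, angles=(25.0,),
            beam_model="point_source", source_distance=50.0,
            detector_distance=30.0)
        sino = ft.analytic_projection(scene, 0.0, geo)
        # oracle: perpendicular distance from centre to each source ray
        from flowtomo.ray_geometry import _ray_arrays, CellField
        pts, dirs = _ray_arrays(geo, CellField.empty(8, 0.1))
        c = np.array([0.1, -0.05, 0.02])
        rel = c - pts
        proj = np.einsum("kd,kd->k", rel, dirs)
        d2 = np.einsum("kd,kd->k", rel, rel) - proj ** 2
        chord = 2 * np.sqrt(np.maximum(0.2 ** 2 - d2, 0.0))
        assert np.allclose(sino.values.ravel(), 1.5 * chord, atol=1e-12)

    def test_integrated_absorbance_equals_sphere_mass(self):
        """Sum over pixels times pixel area recovers (4/3) pi r^3 rho
        within 0.5% once the radius covers >= 10 pixels."""
        n, pixel = 64, 1.0 / 64
        scene = _single_sphere_scene(radius=12 * pixel, rho=3.0)
        geo = ft.DetectorGeometry(n_rows=n, n_cols=n, pixel_size=pixel,
                                  angles=(0.0,))
        sino = ft.analytic_projection(scene, 0.0, geo)
        mass = sino.values[0].sum() * pixel ** 2
        expected = 4 / 3 * np.pi * (12 * pixel) ** 3 * 3.0
        assert mass == pytest.approx(expected, rel=5e-3)

    def test_overlapping_spheres_add(self):
        s1 = _single_sphere_scene(radius=0.3, rho=1.0)
        s2 = _single_sphere_scene(center=(0, 0.1, 0), radius=0.2, rho=0.5)
        both = ft.SphereScene(s1.spheres + s2.spheres)
        geo = _odd_geometry()
        a = ft.analytic_projection(s1, 0.0, geo).values
        b = ft.analytic_projection(s2, 0.0, geo).values
        ab = ft.analytic_projection(both, 0.0, geo).values
        assert np.allclose(ab, a + b)


class TestSupersampledProjection:
    def test_enclosing_sphere_equals_center_sampling(self):
        # sphere much larger than the detector: locally constant background
        scene = _single_sphere_scene(radius=50.0, rho=1.0)
        geo = _odd_geometry(n=5)
        ss = ft.supersampled_projection(scene, 0.0, geo).values
        cs = ft.analytic_projection(scene, 0.0, geo).values
        assert np.allclose(ss, cs, rtol=1e-6)

    def test_value_is_nine_point_mean(self):
        scene = _single_sphere_scene(radius=0.23, rho=1.7)
        geo = _odd_geometry()
        ss = ft.supersampled_projection(scene, 0.0, geo).values
        # hand-computed 9-term mean at an edge pixel of the sphere
        row, col = 4, 6
        xd, yd = geo.pixel_coords()
        acc = []
        for ox in (-geo.pixel_size / 3, 0, geo.pixel_size / 3):
            for oy in (-geo.pixel_size / 3, 0, geo.pixel_size / 3):
                shifted = ft.DetectorGeometry(
                    n_rows=1, n_cols=1, pixel_size=geo.pixel_size,
                    angles=geo.angles)
                val = phantom._project_points(
                    scene, 0.0, shifted,
                    np.array([xd[col] + ox]), np.array([yd[row] + oy]))
                acc.append(val[0, 0])
        assert ss[0, row, col] == pytest.approx(np.mean(acc))
        # mean bound: between min and max of the samples
        assert min(acc) <= ss[0, row, col] <= max(acc)


class TestMotionModels:
    def test_fixed_particle_stays_at_origin(self):
        params = phantom.TABLE_HELICAL_PARAMS
        for t in (0.0, 0.31, 0.77, 1.0):
            assert np.allclose(phantom.helical_centers(params, t)[2], 0.0)

    def test_particle_one_initial_position(self):
        c = phantom.helical_centers(phantom.TABLE_HELICAL_PARAMS, 0.0)
        assert np.allclose(c[0], [0.0, 2 / 7, -9 / 64])

    def test_revolvers_are_mirrored(self):
        """Particles 1 and 2 have opposite-sign y, z trajectories and share
        the same x (their in-plane velocity bounds have equal x sign)."""
        for t in (0.0, 0.2, 0.63):
            c = phantom.helical_centers(phantom.TABLE_HELICAL_PARAMS, t)
            assert c[1][0] == pytest.approx(c[0][0])
            assert c[1][1] == pytest.approx(-c[0][1])
            assert c[1][2] == pytest.approx(-c[0][2])

    def test_sinusoidal_velocity(self):
        assert np.allclose(ft.sinusoidal_velocity(2.0, 1.0, 0.0), 0.0)
        assert np.allclose(ft.sinusoidal_velocity(2.0, 1.0, 0.5),
                           [0, 0, -2.0])

    def test_sinusoidal_peak_cfl(self):
        dt, dx = 0.1, 0.4
        z0 = 0.5 * dx / dt
        t = np.linspace(0, 1.0, 201)
        cfl = np.array([abs(ft.sinusoidal_velocity(z0, 1.0, ti)[2]) * dt / dx
                        for ti in t])
        assert cfl.max() == pytest.approx(0.5)


class TestVoxelize:
    def test_sphere_outside_grid_gives_zero_field(self):
        grid = ft.CellField.empty(8, 1.0)
        scene = _single_sphere_scene(center=(100, 0, 0), radius=1.0)
        assert np.all(ft.voxelize(scene, 0.0, grid).values == 0.0)

    def test_enclosing_sphere_fills_grid(self):
        grid = ft.CellField.empty(8, 0.1)
        scene = _single_sphere_scene(radius=10.0, rho=1.3)
        assert np.allclose(ft.voxelize(scene, 0.0, grid).values, 1.3)

    def test_total_mass(self):
        n = 32
        grid = ft.CellField.empty(n, 1.0 / n)
        r = 8.0 / n
        scene = _single_sphere_scene(radius=r, rho=2.0)
        vox = ft.voxelize(scene, 0.0, grid)
        mass = vox.values.sum() * grid.dx ** 3
        assert mass == pytest.approx(4 / 3 * np.pi * r ** 3 * 2.0, rel=0.01)


class TestRenderSeries:
    def test_static_scene_frames_identical(self):
        scene = _single_sphere_scene()
        geo = _odd_geometry(n=5)
        series = ft.render_series(scene, [0.0, 0.1, 0.2], geo)
        assert np.array_equal(series.values[0], series.values[1])
        assert np.array_equal(series.values[0], series.values[2])

    def test_reference_configuration_shape(self):
        """Five angles, 64x64 detector, 501 samples of 2 ms."""
        scene = ft.SphereScene.helical(
            phantom.TABLE_HELICAL_PARAMS, (0.1, 0.1, 1 / 9.0), (1, 1, 1))
        geo = ft.DetectorGeometry(
            n_rows=64, n_cols=64, pixel_size=0.015625,
            angles=(-75, -35, 0, 35, 75))
        times = np.arange(501) * 0.002
        series = ft.render_series(scene, times, geo)
        assert series.values.shape == (501, 5, 64, 64)
        assert series.dt == pytest.approx(0.002)

    def test_frame_equals_analytic_reevaluation(self):
        scene = ft.SphereScene.helical(
            phantom.TABLE_HELICAL_PARAMS, (0.1, 0.1, 1 / 9.0), (1, 1, 1))
        geo = _odd_geometry(n=7, pixel=0.15, angles=(0.0, 35.0))
        series = ft.render_series(scene, [0.0, 0.05, 0.1], geo)
        direct = ft.supersampled_projection(scene, 0.05, geo).values
        assert np.array_equal(series.values[1], direct)

    def test_motion_undefined_raises(self):
        scene = ft.SphereScene(
            [ft.Sphere(center=(0, 0, 0), radius=0.1, attenuation=1.0)],
            motion=lambda t: np.zeros((1, 3)), t_span=(0.0, 1.0))
        geo = _odd_geometry(n=3)
        with pytest.raises(ValueError):
            ft.render_series(scene, [0.0, 1.0, 2.0], geo)


class TestTrajectories:
    def test_linear_interpolation(self, tmp_path):
        path = tmp_path / "traj.csv"
        path.write_text("time,id,cx,cy,cz,radius,density\n"
                        "0.0,0,0,0,0,0.1,1.0\n"
                        "1.0,0,0,0,1.0,0.1,1.0\n")
        scene = ft.load_trajectories(path)
        assert np.allclose(scene.centers_at(0.5), [[0, 0, 0.5]])

    def test_single_row_gives_static_scene(self, tmp_path):
        path = tmp_path / "traj.csv"
        path.write_text("time,id,cx,cy,cz,radius,density\n"
                        "0.0,0,0.2,-0.1,0,0.1,2.0\n")
        scene = ft.load_trajectories(path)
        assert scene.motion is None
        assert np.allclose(scene.centers_at(5.0), [[0.2, -0.1, 0.0]])
        assert scene.spheres[0].attenuation == 2.0

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "traj.csv"
        path.write_text("time,id,cx,cy,cz\n0,0,0,0,0\n")
        with pytest.raises(ValueError, match="missing columns"):
            ft.load_trajectories(path)

    def test_helical_roundtrip(self, tmp_path):
        scene = ft.SphereScene.helical(
            phantom.TABLE_HELICAL_PARAMS, (0.1, 0.1, 1 / 9.0), (1, 1, 1))
        times = np.linspace(0, 0.5, 11)
        path = tmp_path / "helix.csv"
        phantom.save_trajectories(scene, times, path)
        back = ft.load_trajectories(path)
        for t in times:
            assert np.allclose(back.centers_at(t), scene.centers_at(t),
                               atol=1e-12)
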