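import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import flowtomo as ft
from flowtomo.evaluation import run_benchmark

ALL_STRATEGIES = ("original_static_bc", "replace_static_bc",
                  "replace_local_bc")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_geometry():
    return ft.DetectorGeometry(n_rows=8, n_cols=8, pixel_size=1.0,
                               angles=(-30.0, 10.0, 77.0))


@pytest.fixture
def small_grid():
    return ft.CellField.empty(8, 1.0)


# ---------------------------------------------------------------------------
# heavy end-to-end runs shared across tests (session scope)

@pytest.fixture(scope="session")
def sinusoidal_runs():
    """Single-sphere sinusoidal benchmark, peak CFL 0.5, all strategies.

    48 steps keep the sphere inside the n = 32 field of view (axial travel
    is (2/pi) * 0.5 * n_steps cells).
    """
    return run_benchmark("single_sphere", {
        "n": 32, "n_steps": 48, "peak_cfl": 0.5, "radius": 0.15,
        "f0": "reconstruct", "strategies": ALL_STRATEGIES})


@pytest.fixture(scope="session")
def conservation_run():
    """100-step single-sphere run at CFL <= 0.25 for conservation checks."""
    return run_benchmark("single_sphere", {
        "n": 32, "n_steps": 100, "peak_cfl": 0.25, "radius": 0.15,
        "f0": "truth"})


@pytest.fixture(scope="session")
def helical_run():
    """Three-body helical benchmark scaled to n = 32, 100 steps of 2 ms."""
    return run_benchmark("helical", {
        "n": 32, "n_steps": 100, "dt": 0.002, "f0": "reconstruct"})
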