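import numpy as np
import pandas as pd
import pytest

from eggchamber.geometry import make_geometry
from eggchamber.rigid_dynamics import ModelParams, Trajectory, bin_centers


@pytest.fixture(scope="session")
def geom_default():
    """Default study geometry: e = 1.2, 200 cells."""
    return make_geometry(1.2, 200)


@pytest.fixture(scope="session")
def sphere_default():
    return make_geometry(1.0, 200)


@pytest.fixture(scope="session")
def geom_small():
    """Reduced geometry for fast unit tests."""
    return make_geometry(1.2, 64)


@pytest.fixture(scope="session")
def sphere_small():
    return make_geometry(1.0, 64)


@pytest.fixture
def fast_params():
    """Short run for unit tests of the integration loop."""
    return ModelParams(T=60.0, seed=11)


def make_trajectory(times, omega3, fat2_mean=None, M=8, omega=None, d3=None):
    """Hand-built trajectory for observable tests."""
    times = np.asarray(times, dtype=float)
    omega3 = np.asarray(omega3, dtype=float)
    centers = bin_centers(M)
    if fat2_mean is None:
        fat2_mean = np.full((len(times), M), 1.0)
    return Trajectory(
        times=times, omega3=omega3, fat2_mean=np.asarray(fat2_mean),
        beta_centers=centers, final_state=None, params=ModelParams(),
        omega=None if omega is None else np.asarray(omega, dtype=float),
        d3=None if d3 is None else np.asarray(d3, dtype=float),
    )


def tracks_frame(rows):
    """Track table from (cell_id, frame, t_min, x, y, boundary) tuples."""
    return pd.DataFrame(
        rows, columns=["cell_id", "frame", "t_min", "x_um", "y_um", "boundary"]
    )


def straight_track(cell_id, n_frames, x0=0.0, y0=0.0, vx=0.0, vy=0.0,
                   dt_min=1.0, start_frame=0, boundary=False):
    return [
        (cell_id, start_frame + i, (start_frame + i) * dt_min,
         x0 + vx * i * dt_min, y0 + vy * i * dt_min, boundary)
        for i in range(n_frames)
    ]
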