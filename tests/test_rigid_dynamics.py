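import numpy as np
import pytest

from eggchamber.geometry import EggChamberGeometry, drag_coefficient, make_geometry
from eggchamber.rigid_dynamics import (
    ModelParams,
    Trajectory,
    bin_centers,
    cell_velocities,
    cell_velocity,
    compute_omega3,
    forces_to_vectors,
    init_state,
    run_base_model,
    sample_protrusion_angles,
    step_fat2,
    step_forces,
)
from eggchamber.observables import steady_omega3


# ---------------------------------------------------------------------------
# parameters and initial state

@pytest.mark.parametrize(
    "kwargs",
    [dict(tau1=-1), dict(tau2=0), dict(tau3=-0.1), dict(dt=0), dict(T=-5),
     dict(M=7), dict(M=4), dict(resample_every=0), dict(c_floor=0),
     dict(dt=0.5, tau1=2.0)],
)
def test_params_validation(kwargs):
    with pytest.raises(ValueError):
        ModelParams(**kwargs)


def test_initial_state_unpolarized(geom_small):
    p = ModelParams(seed=4)
    s = init_state(p, geom_small)
    assert np.all(s.fat2 == 1.0 / (2 * np.pi))
    assert np.all(s.forces == 0.0)
    assert s.omega3 == 0.0
    s2 = init_state(p, geom_small)
    assert np.array_equal(
        s.rng.random(10), s2.rng.random(10)
    ), "same seed must give identical streams"


def test_bin_centers_exact_mirror_pairs():
    c = bin_centers(64)
    assert np.array_equal(c[::-1], -c)
    assert np.all(np.diff(c) > 0)
    assert abs(c[0] + np.pi - np.pi / 64) < 1e-12


# ---------------------------------------------------------------------------
# protrusion-angle sampling

def test_sampling_degenerate_distribution():
    M = 16
    fat2 = np.full((200, M), 1e-8)
    fat2[:, 5] = 1.0
    beta = sample_protrusion_angles(fat2, np.random.default_rng(0))
    assert np.all(beta == bin_centers(M)[5])


def test_sampling_uniform_matches_uniform_cdf():
    """Empirical CDF of 1e5 draws from a flat field vs the uniform CDF.

    Evaluated at the bin edges, where the discretized distribution agrees
    exactly with the continuous uniform, so only sampling noise remains.
    """
    M, n = 64, 100_000
    fat2 = np.full((n, M), 1.0 / (2 * np.pi))
    beta = sample_protrusion_angles(fat2, np.random.default_rng(123))
    edges = -np.pi + 2 * np.pi * np.arange(1, M + 1) / M
    emp = np.searchsorted(np.sort(beta), edges - 1e-12, side="right") / n
    exact = (edges + np.pi) / (2 * np.pi)
    assert np.max(np.abs(emp - exact)) < 0.01


def test_sampling_reproducible():
    fat2 = np.random.default_rng(5).random((50, 32)) + 0.1
    b1 = sample_protrusion_angles(fat2, np.random.default_rng(9))
    b2 = sample_protrusion_angles(fat2, np.random.default_rng(9))
    assert np.array_equal(b1, b2)


def test_sampling_rejects_nonfinite():
    fat2 = np.ones((4, 8))
    fat2[2, 3] = np.nan
    with pytest.raises(ValueError):
        sample_protrusion_angles(fat2, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# crawling-force relaxation (frozen protrusion direction)

def test_force_relaxation_closed_form():
    """Euler integration of db/dt = -tau1(eta + b) vs -eta(1 - exp(-tau1 t))."""
    tau1, dt = 1.0, 1e-3
    eta = np.array([[1.0, 0.0]])  # along t1
    b = np.zeros((1, 2))
    n = int(round(1.0 / tau1 / dt))
    for _ in range(n):
        b = step_forces(b, eta, tau1, dt)
    expected = -eta * (1.0 - np.exp(-tau1 * 1.0))
    assert np.allclose(b, expected, atol=5 * dt)
    # long-time fixed point b = -eta
    for _ in range(9 * n):
        b = step_forces(b, eta, tau1, dt)
    assert np.allclose(b, -eta, atol=1e-3)


def test_force_fixed_point_is_stationary():
    eta = np.array([[0.3, -0.4]])
    b = -eta.copy()
    assert np.allclose(step_forces(b, eta, 1.0, 0.01), b, atol=1e-15)


def test_step_forces_rejects_unstable_step():
    with pytest.raises(ValueError):
        step_forces(np.zeros((1, 2)), np.zeros((1, 2)), tau1=2.0, dt=0.5)


# ---------------------------------------------------------------------------
# torque balance

def _single_cell_geometry():
    pos = np.array([[1.0, 0.0, 0.0]])
    n = np.array([[1.0, 0.0, 0.0]])
    t1 = np.array([[0.0, 0.0, 1.0]])
    t2 = np.cross(t1, n)
    lever = np.einsum(
        "ij,ij->i", np.cross(np.array([[0.0, 0.0, 1.0]]), pos), t2
    )
    return EggChamberGeometry(e=1.0, N=1, positions=pos, normals=n,
                              t1=t1, t2=t2, lever=lever)


def test_omega3_single_equatorial_cell():
    g = _single_cell_geometry()
    omega3 = compute_omega3(g, np.array([[0.0, 1.0, 0.0]]))
    assert omega3 == pytest.approx(15.0 / (40.0 * np.pi), rel=1e-12)


def test_omega3_zero_for_meridional_forces(geom_small):
    forces = np.column_stack([np.random.default_rng(1).normal(size=geom_small.N),
                              np.zeros(geom_small.N)])
    assert compute_omega3(geom_small, forces) == 0.0
    vecs = forces_to_vectors(geom_small, forces)
    assert abs(compute_omega3(geom_small, vecs)) < 1e-12


def test_omega3_antipodal_pair_cancels():
    pos = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
    normals = pos.copy()
    t1 = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
    t2 = np.cross(t1, normals)
    lever = np.einsum("ij,ij->i", np.cross([[0, 0, 1.0]] * 2, pos), t2)
    g = EggChamberGeometry(e=1.0, N=2, positions=pos, normals=normals,
                           t1=t1, t2=t2, lever=lever)
    # opposite t2-components: the two forces point the same way in space
    # (both +y), so their torques about the AP axis cancel
    forces = np.array([[0.0, 1.0], [0.0, -1.0]])
    brute = sum(np.cross(pos[i], forces_to_vectors(g, forces)[i])[2] for i in range(2))
    assert abs(brute) < 1e-15
    assert abs(compute_omega3(g, forces)) < 1e-15


def test_omega3_matches_brute_force_loop(geom_small):
    rng = np.random.default_rng(7)
    forces = rng.normal(size=(geom_small.N, 2))
    vecs = forces_to_vectors(geom_small, forces)
    Pi = drag_coefficient(geom_small.e, geom_small.N)
    brute = sum(np.cross(geom_small.positions[i], vecs[i])[2]
                for i in range(geom_small.N)) / Pi
    assert compute_omega3(geom_small, forces) == pytest.approx(brute, abs=1e-12)
    assert compute_omega3(geom_small, vecs) == pytest.approx(brute, abs=1e-12)


def test_cell_velocity_kinematics(geom_small):
    g = _single_cell_geometry()
    assert np.allclose(cell_velocity(1.0, g, 0), [0.0, 1.0, 0.0])
    assert np.allclose(cell_velocity(0.0, g, 0), 0.0)
    v = cell_velocities(0.7, geom_small)
    rho = np.linalg.norm(geom_small.positions[:, :2], axis=1)
    assert np.allclose(np.linalg.norm(v, axis=1), 0.7 * rho, atol=1e-12)


# ---------------------------------------------------------------------------
# Fat2 dynamics

def test_fat2_saturation_decay_closed_form():
    """At v = 0 the field follows dc/dt = -tau2 c^2, i.e. c0/(1 + tau2 c0 t)."""
    tau2, c0, dt = 1.0, 0.5, 1e-3
    t_end = 1.0 / (tau2 * c0)
    c = np.full((3, 8), c0)
    vm = np.zeros_like(c)
    for _ in range(int(round(t_end / dt))):
        c = step_fat2(c, vm, tau2, 20.0, dt, 1e-12)
    assert np.allclose(c, c0 / (1 + tau2 * c0 * t_end), atol=5 * dt)


@pytest.mark.parametrize("sign,target", [(-1.0, "saturate"), (+1.0, "floor")])
def test_fat2_fixed_points(sign, target):
    tau2, tau3, dt, floor, s = 1.0, 20.0, 1e-3, 1e-8, 0.05
    c = np.full((1, 4), 1.0 / (2 * np.pi))
    vm = np.full_like(c, sign * s)
    for _ in range(200_000):
        c = step_fat2(c, vm, tau2, tau3, dt, floor)
    if target == "saturate":
        assert np.allclose(c, tau3 * s, rtol=0.01)
    else:
        assert np.all(c == floor)


def test_fat2_rejects_nonfinite():
    c = np.ones((1, 4))
    vm = np.full_like(c, np.inf)
    with pytest.raises(FloatingPointError):
        step_fat2(c, vm, 1.0, 1.0, 0.01, 1e-8)


# ---------------------------------------------------------------------------
# full runs

def test_symmetry_breaks_and_rotation_sustained(geom_small, fast_params):
    traj = run_base_model(fast_params, geom_small)
    n = len(traj.omega3)
    early = np.abs(traj.omega3[: max(2, n // 20)]).mean()
    assert abs(traj.omega3[-1]) > 10 * early
    assert np.all(traj.fat2_mean >= fast_params.c_floor)


def test_no_feedback_no_rotation(geom_small):
    traj = run_base_model(ModelParams(tau3=0.0, T=60.0, seed=2), geom_small)
    assert abs(steady_omega3(traj)) < 2e-3


def test_mirrored_stream_flips_omega3_exactly(geom_small):
    p = ModelParams(T=30.0, seed=8)
    fwd = run_base_model(p, geom_small)
    mir = run_base_model(p, geom_small, mirror=True)
    assert np.array_equal(mir.omega3, -fwd.omega3)
    assert np.array_equal(mir.fat2_mean, fwd.fat2_mean[:, ::-1])


def test_force_tangency_and_floor_over_long_run(geom_small):
    p = ModelParams(T=100.0, seed=3)  # 10^4 Euler steps
    traj = run_base_model(p, geom_small)
    b_vec = forces_to_vectors(geom_small, traj.final_state.forces)
    tangency = np.abs(np.einsum("ij,ij->i", b_vec, geom_small.normals))
    assert np.max(tangency) < 1e-6
    assert np.all(traj.final_state.fat2 >= p.c_floor)
    # steady-state force magnitudes bounded by the fixed point |b| = 1
    assert np.max(np.linalg.norm(traj.final_state.forces, axis=1)) <= 1.0 + 1e-6


def test_dt_halving_changes_steady_speed_by_under_5pct(geom_small):
    base = ModelParams(T=80.0, dt=0.01, resample_every=1, seed=21)
    fine = base.replace(dt=0.005, resample_every=2)
    w1 = abs(steady_omega3(run_base_model(base, geom_small)))
    w2 = abs(steady_omega3(run_base_model(fine, geom_small)))
    assert w1 > 0
    assert abs(w1 - w2) / w1 < 0.05


def test_trajectory_times_strictly_increasing(geom_small, fast_params):
    traj = run_base_model(fast_params, geom_small)
    assert np.all(np.diff(traj.times) > 0)
    with pytest.raises(ValueError):
        Trajectory(times=np.array([0.0, 1.0, 1.0]), omega3=np.zeros(3),
                   fat2_mean=np.zeros((3, 8)), beta_centers=bin_centers(8),
                   final_state=None, params=fast_params)
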