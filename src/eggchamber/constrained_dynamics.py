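"""Full 3-D rotation: free sphere and pre-stalk axis selection.

For a spherical chamber (``e = 1``) nothing restricts the rotation axis: the
overdamped balance ``Pi(1) * omega = sum_i r_i' x b_i'`` (primes denote
lab-frame vectors) lets the spontaneously chosen axis wander, and an ensemble
of runs ends up with axis directions spread over the sphere.

Stage-1 egg chambers, however, press a polar cap of follicle cells against the
stationary pre-stalk cells.  That flattened interface is modeled by two
implementer-chosen couplings that realize the qualitative physics of an
elastic interface normal and a viscous interface tangent:

* an elastic restoring torque ``k_s * (d3 x e3)`` that rotates the co-moving
  AP axis ``d3`` toward the fixed pre-stalk axis ``e3``, and
* a viscous drag ``-mu_s * sum_cap r' x (omega x r')`` summed over the cells
  currently inside the polar cap of half-angle ``theta_s`` around ``e3``,
  representing the cap sliding past the stationary pre-stalk cells.

Because the elastic coupling pins ``d3`` while the crawling pattern co-moves
with the body, the only rotation compatible with a stationary ``d3`` is spin
about ``e3``; the rotational axis therefore converges onto the pre-stalk axis,
faster for stiffer coupling.

Orientation is integrated as a unit quaternion advanced by the exponential
map of ``omega * dt`` and renormalized every step.  Crawling forces and Fat2
fields live in the co-rotating cell tangent frames exactly as in
:mod:`eggchamber.rigid_dynamics`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .geometry import AP_AXIS, EggChamberGeometry, drag_coefficient
from .rigid_dynamics import (
    ModelParams,
    SimState,
    Trajectory,
    _bin_trig,
    init_state,
)

__all__ = [
    "PRESTALK_AXIS",
    "OrientationState",
    "PrestalkParams",
    "total_torque",
    "elastic_alignment_torque",
    "prestalk_drag",
    "step_free_sphere",
    "run_free_sphere",
    "run_prestalk_model",
]

#: Lab-frame direction of the stationary pre-stalk axis, called ``e3``.
PRESTALK_AXIS = np.array([0.0, 0.0, 1.0])

_SPHERE_TOL = 1e-12


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-last convention, body -> lab)

def _quat_identity() -> np.ndarray:
    return np.array([0.0, 0.0, 0.0, 1.0])


def _quat_mult(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    pv, pw = p[:3], p[3]
    qv, qw = q[:3], q[3]
    return np.append(pw * qv + qw * pv + np.cross(pv, qv), pw * qw - pv @ qv)


def _quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(v)
    if angle < 1e-14:
        return np.append(0.5 * v, 1.0)
    half = 0.5 * angle
    return np.append((np.sin(half) / angle) * v, np.cos(half))


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


@dataclass
class OrientationState:
    """Body-to-lab orientation stored as a unit quaternion (scalar last)."""

    q: np.ndarray = field(default_factory=_quat_identity)
    t: float = 0.0

    @property
    def R(self) -> np.ndarray:
        """Body-to-lab rotation matrix."""
        return _quat_to_matrix(self.q)

    @property
    def d3(self) -> np.ndarray:
        """Lab-frame direction of the co-moving AP axis."""
        return self.R @ AP_AXIS

    def advance(self, omega_lab: np.ndarray, dt: float) -> None:
        self.q = _quat_mult(_quat_from_rotvec(omega_lab * dt), self.q)
        self.q = self.q / np.linalg.norm(self.q)


@dataclass(frozen=True)
class PrestalkParams:
    """Pre-stalk interface parameters on top of the base :class:`ModelParams`.

    ``theta_s`` is the polar half-angle of the contact cap around the
    pre-stalk axis; ``k_s`` the elastic stiffness aligning the AP axis with
    the pre-stalk axis (dimensionless torque per radian of misalignment);
    ``mu_s`` the tangential drag coefficient per interface cell.
    """

    model: ModelParams = field(default_factory=ModelParams)
    theta_s: float = np.pi / 6
    k_s: float = 200.0
    mu_s: float = 10.0

    def __post_init__(self) -> None:
        errors = []
        if not 0 < self.theta_s < np.pi / 2:
            errors.append(f"theta_s must be in (0, pi/2), got {self.theta_s!r}")
        if self.k_s < 0:
            errors.append(f"k_s must be >= 0, got {self.k_s!r}")
        if self.mu_s < 0:
            errors.append(f"mu_s must be >= 0, got {self.mu_s!r}")
        if errors:
            raise ValueError("; ".join(errors))

    def replace(self, **kwargs) -> "PrestalkParams":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# torques

def total_torque(
    geometry: EggChamberGeometry, forces: np.ndarray, R: np.ndarray
) -> np.ndarray:
    """Lab-frame crawling torque ``sum_i (R r_i) x (R b_i)``.

    ``forces`` are body-frame 3-vectors of shape ``(N, 3)``.  A proper
    rotation commutes with the cross product, so the sum is taken in the body
    frame and rotated once.
    """
    return R @ np.cross(geometry.positions, forces).sum(axis=0)


def elastic_alignment_torque(
    d3: np.ndarray, k_s: float, e3: np.ndarray = PRESTALK_AXIS
) -> np.ndarray:
    """Restoring torque ``k_s * (d3 x e3)`` pinning the AP axis to ``e3``."""
    return k_s * np.cross(d3, e3)


def _cap_mask(geometry: EggChamberGeometry, R: np.ndarray, theta_s: float,
              e3: np.ndarray = PRESTALK_AXIS) -> np.ndarray:
    # lab polar angle of R r_i from e3 below theta_s  <=>  (R r_i) . e3 > cos
    return geometry.positions @ (R.T @ e3) > np.cos(theta_s)


def prestalk_drag(
    geometry: EggChamberGeometry,
    R: np.ndarray,
    omega: np.ndarray,
    theta_s: float,
    mu_s: float,
) -> np.ndarray:
    """Viscous torque from the polar cap sliding past the pre-stalk cells.

    ``-mu_s * sum_j r_j' x (omega x r_j')`` over interface cells ``j`` whose
    lab-frame position ``r_j' = R r_j`` lies within the cap of half-angle
    ``theta_s`` around the pre-stalk axis.  Always dissipative:
    ``torque . omega <= 0``.
    """
    mask = _cap_mask(geometry, R, theta_s)
    if not mask.any():
        return np.zeros(3)
    rp = geometry.positions[mask] @ R.T
    return -mu_s * np.cross(rp, np.cross(omega[None, :], rp)).sum(axis=0)


def step_free_sphere(
    orientation: OrientationState,
    geometry: EggChamberGeometry,
    forces: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Advance the orientation of a free sphere by one step.

    ``forces`` are body-frame 3-vectors.  Returns the lab-frame angular
    velocity used for the step.  Only valid for a spherical chamber; the
    anisotropic free rotation of an ellipsoid is outside the model.
    """
    if abs(geometry.e - 1.0) > _SPHERE_TOL:
        raise ValueError(f"free rotation requires a sphere (e = 1), got e = {geometry.e}")
    Pi = drag_coefficient(1.0, geometry.N)
    omega = total_torque(geometry, forces, orientation.R) / Pi
    orientation.advance(omega, dt)
    orientation.t += dt
    return omega


# ---------------------------------------------------------------------------
# full runs

def _run_3d(
    params: ModelParams,
    geometry: EggChamberGeometry,
    prestalk: PrestalkParams | None,
) -> Trajectory:
    if abs(geometry.e - 1.0) > _SPHERE_TOL:
        raise ValueError(f"3-D rotation model requires a sphere (e = 1), got e = {geometry.e}")
    N, M = geometry.N, params.M
    centers, cos_c, sin_c = _bin_trig(M)
    Pi = drag_coefficient(1.0, geometry.N)
    # Torque of b = b1 t1 + b2 t2 at r is b1 (r x t1) + b2 (r x t2).
    C1 = np.cross(geometry.positions, geometry.t1)
    C2 = np.cross(geometry.positions, geometry.t2)
    use_interface = prestalk is not None and (prestalk.mu_s > 0 or prestalk.k_s > 0)
    cos_cap = np.cos(prestalk.theta_s) if prestalk is not None else None

    state = init_state(params, geometry)
    fat2, forces, rng = state.fat2, state.forces, state.rng
    orientation = OrientationState()
    dt, n_steps = params.dt, params.n_steps
    tau1, tau2, tau3 = params.tau1, params.tau2, params.tau3

    n_rec = n_steps // params.record_every + 2
    times = np.empty(n_rec)
    omega_rec = np.empty((n_rec, 3))
    d3_rec = np.empty((n_rec, 3))
    omega3_rec = np.empty(n_rec)
    fat2_rec = np.empty((n_rec, M))
    times[0], omega3_rec[0] = 0.0, 0.0
    omega_rec[0] = 0.0
    d3_rec[0] = orientation.d3
    fat2_rec[0] = fat2.mean(axis=0)
    rec = 1

    eta = np.empty((N, 2))
    b_tmp = np.empty((N, 2))
    c_tmp = np.empty((N, M))
    vm = np.empty((N, M))
    cum = np.empty((N, M))
    below = np.empty((N, M), dtype=bool)
    k = None
    eye3 = np.eye(3)
    for step in range(n_steps):
        if step % params.resample_every == 0:
            np.cumsum(fat2, axis=1, out=cum)
            u = rng.random(N) * cum[:, -1]
            np.less(cum, u[:, None], out=below)
            k = below.sum(axis=1)
            np.minimum(k, M - 1, out=k)
            np.take(cos_c, k, out=eta[:, 0])
            np.take(sin_c, k, out=eta[:, 1])
        np.add(eta, forces, out=b_tmp)
        b_tmp *= -tau1 * dt
        forces += b_tmp

        R = _quat_to_matrix(orientation.q)
        torque_body = C1.T @ forces[:, 0] + C2.T @ forces[:, 1]
        torque_lab = R @ torque_body
        if use_interface:
            d3 = R[:, 2]
            torque_lab = torque_lab + prestalk.k_s * np.cross(d3, PRESTALK_AXIS)
            mask = geometry.positions @ R[2] > cos_cap
            n_cap = int(mask.sum())
            if n_cap and prestalk.mu_s > 0:
                rp = geometry.positions[mask] @ R.T
                A = Pi * eye3 + prestalk.mu_s * (n_cap * eye3 - rp.T @ rp)
                omega_lab = np.linalg.solve(A, torque_lab)
            else:
                omega_lab = torque_lab / Pi
        else:
            omega_lab = torque_lab / Pi
        speed = np.linalg.norm(omega_lab)
        if speed > params.omega_max:
            raise FloatingPointError(
                f"|omega| = {speed:.3g} exceeded omega_max at t = {step * dt:.3g}"
            )
        orientation.advance(omega_lab, dt)
        omega_body = R.T @ omega_lab

        # v_i . m(beta_k) = omega_body . (cos_k (r_i x t1_i) + sin_k (r_i x t2_i))
        a1 = C1 @ omega_body
        a2 = C2 @ omega_body
        np.multiply(a1[:, None], cos_c[None, :], out=vm)
        np.multiply(a2[:, None], sin_c[None, :], out=c_tmp)
        vm += c_tmp
        np.multiply(vm, tau3, out=c_tmp)
        c_tmp += fat2
        c_tmp *= fat2
        c_tmp *= -tau2 * dt
        fat2 += c_tmp
        np.maximum(fat2, params.c_floor, out=fat2)

        if (step + 1) % params.record_every == 0 or step == n_steps - 1:
            d3 = orientation.d3
            times[rec] = (step + 1) * dt
            omega_rec[rec] = omega_lab
            d3_rec[rec] = d3
            omega3_rec[rec] = omega_lab @ d3
            fat2_rec[rec] = fat2.mean(axis=0)
            rec += 1
    if not np.all(np.isfinite(fat2)):
        raise FloatingPointError("Fat2 field became non-finite")

    final = SimState(
        t=n_steps * dt, fat2=fat2, forces=forces,
        omega3=float(omega3_rec[rec - 1]), rng=rng, beta_idx=k,
    )
    return Trajectory(
        times=times[:rec], omega3=omega3_rec[:rec], fat2_mean=fat2_rec[:rec],
        beta_centers=centers, final_state=final, params=params,
        omega=omega_rec[:rec], d3=d3_rec[:rec],
    )


def run_free_sphere(params: ModelParams, geometry: EggChamberGeometry) -> Trajectory:
    """Unconstrained spherical chamber: symmetry breaks about a random axis."""
    return _run_3d(params, geometry, None)


def run_prestalk_model(
    params: PrestalkParams, geometry: EggChamberGeometry
) -> Trajectory:
    """Stage-1 chamber against the pre-stalk interface.

    The run starts with the AP axis aligned with the pre-stalk axis (the
    flattened interface defines the AP axis) and an unpolarized epithelium;
    the spontaneous rotation axis then converges onto the pre-stalk axis.
    """
    return _run_3d(params.model, geometry, params)
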