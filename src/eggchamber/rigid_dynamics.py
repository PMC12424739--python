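"""Symmetry-breaking rotation about the AP axis (base model).

The epithelium is a rigid ellipsoid whose rotation about its long (AP) axis
is overdamped, so the angular speed follows instantaneously from the torque
balance::

    Pi(e) * omega3 = sum_i (r_i x b_i) . z_hat

where ``b_i`` is the crawling force of cell ``i`` and ``Pi(e)`` the rotational
drag against the basement membrane (:func:`eggchamber.geometry.drag_coefficient`).

Each cell carries a Fat2 concentration field ``c_i(beta)`` on the circle of
tangent directions, discretized into ``M`` bins.  The mechanochemical loop per
time step is:

1. each cell draws a protrusion direction ``beta_i`` from the distribution
   proportional to ``c_i(beta)`` (inverse-CDF over the bins), giving the unit
   vector ``eta_i = (cos beta_i, sin beta_i)`` in its tangent frame;
2. the crawling force relaxes toward the direction opposite the Fat2-enriched
   edge, ``db_i/dt = -tau1 * (eta_i + b_i)`` (fixed point ``b_i = -eta_i``);
3. the torque balance yields ``omega3`` and the rigid-body velocities
   ``v_i = omega3 * z_hat x r_i``;
4. Fat2 grows on the trailing side of each cell and saturates,
   ``dc_i(beta)/dt = -tau2 * (tau3 * v_i . m(beta) + c_i(beta)) * c_i(beta)``.

Forces and Fat2 fields are stored in each cell's co-rotating tangent frame
(components along ``t1``/``t2``), so the advection of the force field by the
rigid rotation is carried by the frame itself and no explicit ``omega x b``
term appears in the update.

Starting from the unpolarized state (uniform Fat2 ``c = 1/(2*pi)``, zero
forces) the feedback loop amplifies stochastic torque fluctuations and the
chamber settles into sustained clockwise (``omega3 < 0``) or counterclockwise
(``omega3 > 0``) rotation with equal probability, with Fat2 polarized to the
trailing edge (``beta = -pi/2`` for counterclockwise runs).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import AP_AXIS, EggChamberGeometry, drag_coefficient

__all__ = [
    "ModelParams",
    "SimState",
    "Trajectory",
    "bin_centers",
    "init_state",
    "sample_protrusion_angles",
    "step_forces",
    "compute_omega3",
    "cell_velocity",
    "cell_velocities",
    "step_fat2",
    "run_base_model",
    "run_base_ensemble",
]


@dataclass(frozen=True)
class ModelParams:
    """Non-dimensional parameters of the mechanochemical model.

    ``tau1`` is the relaxation rate of the crawling force toward the sampled
    protrusion direction; ``tau2`` sets the overall rate of Fat2 turnover and
    ``tau3`` the gain of the mechanosensitive recruitment relative to the
    saturation dynamics.  Time is in units of the characteristic rotation
    time, lengths in units of the equatorial radius.
    """

    tau1: float = 1.0
    tau2: float = 1.0
    tau3: float = 20.0
    dt: float = 0.01
    T: float = 200.0
    M: int = 64
    resample_every: int = 1
    c_floor: float = 1e-8
    seed: int = 0
    record_every: int = 20
    omega_max: float = 1e3

    def __post_init__(self) -> None:
        errors = []
        for name in ("tau1", "tau2", "dt", "T", "c_floor"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                errors.append(f"{name} must be finite and > 0, got {v!r}")
        # tau3 = 0 switches the mechanosensitive feedback off entirely, a
        # meaningful control condition.
        if not np.isfinite(self.tau3) or self.tau3 < 0:
            errors.append(f"tau3 must be finite and >= 0, got {self.tau3!r}")
        if self.M < 8 or self.M % 2:
            errors.append(f"M must be an even integer >= 8, got {self.M!r}")
        if self.resample_every < 1:
            errors.append(f"resample_every must be >= 1, got {self.resample_every!r}")
        if self.record_every < 1:
            errors.append(f"record_every must be >= 1, got {self.record_every!r}")
        if np.isfinite(self.dt) and np.isfinite(self.tau1) and self.dt * self.tau1 >= 1:
            errors.append(
                f"dt * tau1 = {self.dt * self.tau1!r} >= 1: explicit Euler unstable"
            )
        if errors:
            raise ValueError("; ".join(errors))

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimState:
    """Instantaneous state of a simulation.

    ``fat2`` has shape ``(N, M)`` (concentration per bin in units of the
    characteristic concentration); ``forces`` has shape ``(N, 2)`` and holds
    the tangent-frame components ``(b . t1, b . t2)`` of each crawling force.
    """

    t: float
    fat2: np.ndarray
    forces: np.ndarray
    omega3: float
    rng: np.random.Generator
    beta_idx: np.ndarray | None = None


@dataclass
class Trajectory:
    """Recorded time series of one run."""

    times: np.ndarray
    omega3: np.ndarray
    fat2_mean: np.ndarray  # (S, M) cell-averaged Fat2 distribution
    beta_centers: np.ndarray
    final_state: SimState
    params: ModelParams
    # Populated by the 3-D variants only:
    omega: np.ndarray | None = None  # (S, 3) lab-frame angular velocity
    d3: np.ndarray | None = None  # (S, 3) lab-frame AP axis

    def __post_init__(self) -> None:
        if len(self.times) == 0:
            raise ValueError("empty trajectory")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")


# ---------------------------------------------------------------------------
# bin discretization

def bin_centers(M: int) -> np.ndarray:
    """Centers of ``M`` equal bins covering (-pi, pi), symmetric about 0.

    The centers are built as an exact mirror pair of the positive half so
    that ``centers[M - 1 - k] == -centers[k]`` bitwise, which makes the
    reflection ``beta -> -beta`` an exact symmetry of the discretization.
    """
    if M < 2 or M % 2:
        raise ValueError(f"M must be an even integer >= 2, got {M!r}")
    half = (np.arange(M // 2) + 0.5) * (2.0 * np.pi / M)
    return np.concatenate([-half[::-1], half])


def _bin_trig(M: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    centers = bin_centers(M)
    half = centers[M // 2:]
    cos_c = np.concatenate([np.cos(half)[::-1], np.cos(half)])
    sin_c = np.concatenate([-np.sin(half)[::-1], np.sin(half)])
    return centers, cos_c, sin_c


# ---------------------------------------------------------------------------
# elementary updates

def init_state(params: ModelParams, geometry: EggChamberGeometry) -> SimState:
    """Unpolarized initial condition: uniform Fat2, zero forces, no rotation."""
    fat2 = np.full((geometry.N, params.M), 1.0 / (2.0 * np.pi))
    forces = np.zeros((geometry.N, 2))
    return SimState(
        t=0.0, fat2=fat2, forces=forces, omega3=0.0,
        rng=np.random.default_rng(params.seed),
    )


def _sample_bins(
    fat2: np.ndarray, rng: np.random.Generator, mirror: bool = False
) -> np.ndarray:
    """Draw one bin index per cell from the distribution prop. to ``fat2``."""
    if not np.all(np.isfinite(fat2)):
        raise ValueError("Fat2 field contains non-finite weights")
    w = fat2[:, ::-1] if mirror else fat2
    cum = np.cumsum(w, axis=1)
    total = cum[:, -1]
    if np.any(total <= 0):
        raise ValueError("Fat2 field has non-positive total weight")
    u = rng.random(fat2.shape[0]) * total
    k = np.minimum((cum < u[:, None]).sum(axis=1), fat2.shape[1] - 1)
    if mirror:
        k = fat2.shape[1] - 1 - k
    return k


def sample_protrusion_angles(
    fat2: np.ndarray, rng: np.random.Generator, mirror: bool = False
) -> np.ndarray:
    """Per-cell protrusion angle ``beta_i`` sampled proportionally to Fat2.

    ``mirror=True`` reflects the draws (``beta -> -beta``) while consuming
    the random stream identically; it is used to verify the chiral symmetry
    of the model.
    """
    k = _sample_bins(fat2, rng, mirror=mirror)
    return bin_centers(fat2.shape[1])[k]


def step_forces(
    forces: np.ndarray, eta: np.ndarray, tau1: float, dt: float
) -> np.ndarray:
    """One explicit-Euler step of ``db/dt = -tau1 * (eta + b)``.

    Both arrays hold tangent-frame components, shape ``(N, 2)``; tangency is
    therefore maintained by construction.  The fixed point for frozen ``eta``
    is ``b = -eta`` (protrusion opposite the Fat2-enriched edge).
    """
    if dt * tau1 >= 1:
        raise ValueError(f"dt * tau1 = {dt * tau1!r} >= 1: unstable")
    return forces + dt * (-tau1 * (eta + forces))


def forces_to_vectors(geometry: EggChamberGeometry, forces: np.ndarray) -> np.ndarray:
    """Expand tangent-frame components ``(N, 2)`` to body 3-vectors ``(N, 3)``."""
    return forces[:, 0:1] * geometry.t1 + forces[:, 1:2] * geometry.t2


def compute_omega3(geometry: EggChamberGeometry, forces: np.ndarray) -> float:
    """Angular speed from the torque balance about the AP axis.

    ``forces`` may be given either as body 3-vectors ``(N, 3)`` or as
    tangent-frame components ``(N, 2)``.
    """
    Pi = drag_coefficient(geometry.e, geometry.N)
    forces = np.asarray(forces, dtype=float)
    if forces.shape[1] == 2:
        torque = float(geometry.lever @ forces[:, 1])
    else:
        torque = float(np.cross(geometry.positions, forces)[:, 2].sum())
    return torque / Pi


def cell_velocities(omega3: float, geometry: EggChamberGeometry) -> np.ndarray:
    """Rigid-body velocities ``v_i = omega3 * z_hat x r_i``, shape ``(N, 3)``."""
    return omega3 * np.cross(AP_AXIS[None, :], geometry.positions)


def cell_velocity(omega3: float, geometry: EggChamberGeometry, i: int) -> np.ndarray:
    """Velocity of cell ``i`` under rotation about the AP axis."""
    return omega3 * np.cross(AP_AXIS, geometry.positions[i])


def step_fat2(
    fat2: np.ndarray,
    vm: np.ndarray,
    tau2: float,
    tau3: float,
    dt: float,
    c_floor: float,
) -> np.ndarray:
    """One explicit-Euler step of the mechanosensitive Fat2 dynamics.

    ``vm[i, k] = v_i . m(beta_k, r_i)`` is the component of cell ``i``'s
    velocity along each bin direction.  Fat2 grows where ``vm < 0`` (trailing
    side), saturating at ``c* = -tau3 * vm``, and decays elsewhere; the field
    is floored at ``c_floor`` to keep the sampling distribution well defined.
    """
    out = fat2 + dt * (-tau2 * (tau3 * vm + fat2) * fat2)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("Fat2 field became non-finite")
    return np.maximum(out, c_floor)


# ---------------------------------------------------------------------------
# full run

def run_base_model(
    params: ModelParams,
    geometry: EggChamberGeometry,
    mirror: bool = False,
) -> Trajectory:
    """Integrate the axis-constrained model from the unpolarized state.

    Per step: (resample protrusion angles on schedule) -> force relaxation ->
    torque balance -> rigid-body velocities -> Fat2 update -> record.

    ``mirror=True`` reflects every sampled protrusion angle (``beta ->
    -beta``) while consuming the random stream identically; the resulting
    trajectory is the exact chiral image of the unmirrored run (``omega3``
    flips sign bitwise).
    """
    N, M = geometry.N, params.M
    centers, cos_c, sin_c = _bin_trig(M)
    Pi = drag_coefficient(geometry.e, geometry.N)
    # v_i . m(beta_k) = omega3 * lever_i * sin(beta_k)
    P = geometry.lever[:, None] * sin_c[None, :]

    state = init_state(params, geometry)
    fat2, forces, rng = state.fat2, state.forces, state.rng
    dt, n_steps = params.dt, params.n_steps

    n_rec = n_steps // params.record_every + 1
    times = np.empty(n_rec + 1)
    omega3_rec = np.empty(n_rec + 1)
    fat2_rec = np.empty((n_rec + 1, M))
    times[0], omega3_rec[0] = 0.0, 0.0
    fat2_rec[0] = fat2.mean(axis=0)
    rec = 1

    k = None
    eta = np.empty((N, 2))
    b_tmp = np.empty((N, 2))
    c_tmp = np.empty((N, M))
    cum = np.empty((N, M))
    below = np.empty((N, M), dtype=bool)
    tau1, tau2, tau3 = params.tau1, params.tau2, params.tau3
    omega3 = 0.0
    for step in range(n_steps):
        if step % params.resample_every == 0:
            if mirror:
                np.cumsum(fat2[:, ::-1], axis=1, out=cum)
            else:
                np.cumsum(fat2, axis=1, out=cum)
            u = rng.random(N) * cum[:, -1]
            np.less(cum, u[:, None], out=below)
            k = below.sum(axis=1)
            np.minimum(k, M - 1, out=k)
            if mirror:
                np.subtract(M - 1, k, out=k)
            np.take(cos_c, k, out=eta[:, 0])
            np.take(sin_c, k, out=eta[:, 1])
        # b += dt * (-tau1 * (eta + b))
        np.add(eta, forces, out=b_tmp)
        b_tmp *= -tau1 * dt
        forces += b_tmp
        omega3 = (geometry.lever @ forces[:, 1]) / Pi
        if abs(omega3) > params.omega_max:
            raise FloatingPointError(
                f"|omega3| = {abs(omega3):.3g} exceeded omega_max at t = {step * dt:.3g}"
            )
        # c += dt * (-tau2 * (tau3 * omega3 * P + c) * c); floor
        np.multiply(P, tau3 * omega3, out=c_tmp)
        c_tmp += fat2
        c_tmp *= fat2
        c_tmp *= -tau2 * dt
        fat2 += c_tmp
        np.maximum(fat2, params.c_floor, out=fat2)
        if (step + 1) % params.record_every == 0 or step == n_steps - 1:
            times[rec] = (step + 1) * dt
            omega3_rec[rec] = omega3
            fat2_rec[rec] = fat2.mean(axis=0)
            rec += 1
    if not np.all(np.isfinite(fat2)):
        raise FloatingPointError("Fat2 field became non-finite")

    final = SimState(
        t=n_steps * dt, fat2=fat2, forces=forces, omega3=float(omega3),
        rng=rng, beta_idx=k,
    )
    return Trajectory(
        times=times[:rec], omega3=omega3_rec[:rec], fat2_mean=fat2_rec[:rec],
        beta_centers=centers, final_state=final, params=params,
    )


def run_base_ensemble(
    params: ModelParams,
    geometry: EggChamberGeometry,
    seeds: Sequence[int],
) -> list[Trajectory]:
    """Run the base model once per seed with otherwise identical parameters."""
    return [run_base_model(params.replace(seed=int(s)), geometry) for s in seeds]
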