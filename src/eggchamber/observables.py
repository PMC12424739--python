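"""Readouts of single runs and ensembles.

Reduces simulated trajectories to the quantities used to characterize
symmetry breaking: rotation direction (clockwise / counterclockwise / none),
onset time, steady rotation speed, the circular mean of the cell-averaged
Fat2 distribution, and axis-alignment statistics for the 3-D variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rigid_dynamics import Trajectory

__all__ = [
    "EnsembleSummary",
    "steady_omega3",
    "rotation_direction",
    "onset_time",
    "fat2_circular_mean",
    "summarize_ensemble",
    "mean_resultant_length",
    "axis_angles_deg",
    "alignment_time",
]

#: Fraction of the run (counted from the end) over which steady-state
#: statistics are evaluated.
STEADY_WINDOW = 0.2


def _tail(values: np.ndarray, frac: float = STEADY_WINDOW) -> np.ndarray:
    n = len(values)
    if n == 0:
        raise ValueError("empty trajectory")
    return values[max(n - max(int(round(frac * n)), 1), 0):]


def steady_omega3(traj: Trajectory, frac: float = STEADY_WINDOW) -> float:
    """Time-averaged ``omega3`` over the final ``frac`` of the run."""
    return float(_tail(np.asarray(traj.omega3), frac).mean())


def rotation_direction(traj: Trajectory, min_magnitude: float = 0.0) -> str:
    """Classify a run as ``"CCW"`` (omega3 > 0), ``"CW"`` or ``"none"``.

    The sign of the time-averaged ``omega3`` over the final steady window
    decides the direction; runs whose steady magnitude does not exceed
    ``min_magnitude`` (typically 10% of the ensemble-typical steady speed)
    are classified as ``"none"``.
    """
    mean = steady_omega3(traj)
    if abs(mean) <= min_magnitude or mean == 0.0:
        return "none"
    return "CCW" if mean > 0 else "CW"


def onset_time(traj: Trajectory, frac: float = 0.5) -> float:
    """First time ``|omega3|`` reaches ``frac`` of its steady magnitude and
    remains at or above it for the rest of the run."""
    omega3 = np.asarray(traj.omega3)
    steady = abs(steady_omega3(traj))
    if steady == 0.0:
        raise ValueError("run did not settle into rotation; onset undefined")
    above = np.abs(omega3) >= frac * steady
    # last index at which the threshold is not yet sustainedly exceeded
    below_idx = np.nonzero(~above)[0]
    if len(below_idx) == 0:
        return float(traj.times[0])
    first = below_idx[-1] + 1
    if first >= len(omega3):
        raise ValueError("run never sustains the onset threshold")
    return float(traj.times[first])


def fat2_circular_mean(snapshot: np.ndarray, beta_centers: np.ndarray) -> float:
    """Circular mean angle of a Fat2 distribution over the tangent circle.

    Returns the argument of ``sum_k c(beta_k) * exp(i beta_k)`` in
    ``(-pi, pi]``.  Raises if the distribution carries no angular signal
    (all-floor / uniform within numerical noise).
    """
    snapshot = np.asarray(snapshot, dtype=float)
    if np.any(snapshot < 0) or not np.all(np.isfinite(snapshot)):
        raise ValueError("snapshot must be non-negative and finite")
    z = np.sum(snapshot * np.exp(1j * np.asarray(beta_centers)))
    total = snapshot.sum()
    if total <= 0 or abs(z) < 1e-12 * max(total, 1.0):
        raise ValueError("distribution has no resolvable circular mean")
    return float(np.angle(z))


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-ensemble symmetry-breaking statistics."""

    n_runs: int
    fraction_ccw: float
    directions: list[str]
    onset_times: np.ndarray
    steady_speeds: np.ndarray
    fat2_means: np.ndarray


def summarize_ensemble(trajs: list[Trajectory]) -> EnsembleSummary:
    """Aggregate direction, onset and polarization statistics over runs.

    The "none" threshold for each run is 10% of the ensemble median steady
    speed.
    """
    if len(trajs) < 2:
        raise ValueError("ensemble summary requires at least 2 runs")
    steady = np.array([abs(steady_omega3(tr)) for tr in trajs])
    typical = float(np.median(steady))
    directions = [rotation_direction(tr, min_magnitude=0.1 * typical) for tr in trajs]
    n_decided = sum(d != "none" for d in directions)
    fraction_ccw = (
        sum(d == "CCW" for d in directions) / n_decided if n_decided else np.nan
    )
    onsets = np.array([
        onset_time(tr) if d != "none" else np.nan
        for tr, d in zip(trajs, directions)
    ])
    fat2_means = np.array([
        fat2_circular_mean(tr.fat2_mean[-1], tr.beta_centers) for tr in trajs
    ])
    return EnsembleSummary(
        n_runs=len(trajs), fraction_ccw=fraction_ccw, directions=directions,
        onset_times=onsets, steady_speeds=steady, fat2_means=fat2_means,
    )


# ---------------------------------------------------------------------------
# axis statistics for the 3-D variants

def mean_resultant_length(vectors: np.ndarray) -> float:
    """Length of the mean of unit vectors; 1 = identical, ~0 = dispersed."""
    vectors = np.asarray(vectors, dtype=float)
    units = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    return float(np.linalg.norm(units.mean(axis=0)))


def axis_angles_deg(
    traj: Trajectory, axis: np.ndarray = None, undirected: bool = False
) -> np.ndarray:
    """Angle (degrees) between ``omega(t)`` and a fixed lab axis (default z).

    With ``undirected=True`` the reference axis is treated as a line rather
    than a direction (acute angle): rotation about the AP axis is equally
    valid with either handedness, so ``omega`` aligned with ``-axis`` counts
    as aligned.
    """
    if traj.omega is None:
        raise ValueError("trajectory has no 3-D angular velocity record")
    if axis is None:
        axis = np.array([0.0, 0.0, 1.0])
    omega = np.asarray(traj.omega)
    norms = np.linalg.norm(omega, axis=1)
    cosang = np.divide(
        omega @ axis, norms, out=np.ones_like(norms), where=norms > 1e-30
    )
    if undirected:
        cosang = np.abs(cosang)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def alignment_time(traj: Trajectory, threshold_deg: float = 10.0) -> float:
    """First time the (undirected) angle between ``omega`` and the pre-stalk
    axis drops below ``threshold_deg`` and stays below for the rest of the
    run."""
    angles = axis_angles_deg(traj, undirected=True)
    below = angles < threshold_deg
    above_idx = np.nonzero(~below)[0]
    if len(above_idx) == 0:
        return float(traj.times[0])
    first = above_idx[-1] + 1
    if first >= len(angles):
        raise ValueError("rotation axis never aligns within the run")
    return float(traj.times[first])
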