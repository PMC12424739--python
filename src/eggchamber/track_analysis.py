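"""Quantification of centroid tracks and cell-edge intensities.

Operates on two plain tabular inputs:

* **tracks** — one row per cell per frame with columns ``cell_id``, ``frame``,
  ``t_min``, ``x_um``, ``y_um`` and a boolean ``boundary`` flag marking cells
  at the edge of the imaged field;
* **edges** — one row per cell-cell edge with columns ``edge_id``,
  ``angle_deg`` (undirected angle to the AP axis, folded into [0, 90]) and
  ``mean_intensity``.

The statistics mirror standard live-imaging quantifications of rotating
epithelia: tracks are filtered (cells present for fewer than 10 consecutive
frames and boundary cells are discarded) and drift-corrected by centering the
per-frame tissue centroid; the polar order parameter

    alpha = |sum_j sum_i p_ij| / (sum_j sum_i |p_ij|)

is computed from one-minute centroid displacements ``p_ij`` over 30 minutes
(1 for perfectly aligned motion, -> 0 for isotropic motion); migration rates
come from frame-to-frame centroid displacement; and planar polarity of an
edge protein is the ratio of mean intensity on leading/trailing edges
(angle 0-10 degrees) to lateral edges (angle 80-90 degrees).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TRACK_COLUMNS",
    "EDGE_COLUMNS",
    "filter_tracks",
    "center_tracks",
    "polar_order",
    "displacement_stats",
    "migration_rate",
    "fat2_polarity_ratio",
]

TRACK_COLUMNS = ["cell_id", "frame", "t_min", "x_um", "y_um", "boundary"]
EDGE_COLUMNS = ["edge_id", "angle_deg", "mean_intensity"]


def _check_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table is missing columns: {missing}")
    if tracks.duplicated(subset=["cell_id", "frame"]).any():
        raise ValueError("track table has duplicate (cell_id, frame) records")
    if not np.all(np.isfinite(tracks[["x_um", "y_um", "t_min"]].to_numpy(float))):
        raise ValueError("track coordinates must be finite")
    return tracks


def _longest_run(frames: np.ndarray) -> tuple[int, int]:
    """Bounds (first, last) of the longest run of consecutive frame indices."""
    frames = np.sort(frames)
    breaks = np.nonzero(np.diff(frames) != 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(frames) - 1]])
    lengths = ends - starts + 1
    best = int(np.argmax(lengths))  # ties: earliest run
    return int(frames[starts[best]]), int(frames[ends[best]])


def filter_tracks(
    tracks: pd.DataFrame, min_len: int = 10, drop_boundary: bool = True
) -> pd.DataFrame:
    """Apply the track-quality filters.

    Keeps, for each cell, its longest run of consecutive frames; discards
    cells whose longest run is shorter than ``min_len`` frames (default 10)
    and, when ``drop_boundary``, cells flagged as lying at the tissue
    boundary.
    """
    _check_tracks(tracks)
    df = tracks
    if drop_boundary:
        at_boundary = df.groupby("cell_id")["boundary"].transform("any")
        df = df[~at_boundary]
    kept = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        lo, hi = _longest_run(grp["frame"].to_numpy())
        if hi - lo + 1 >= min_len:
            kept.append(grp[(grp["frame"] >= lo) & (grp["frame"] <= hi)])
    if not kept:
        raise ValueError("no tracks remain after filtering")
    return pd.concat(kept, ignore_index=True)


def center_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-frame mean cell position (tissue-centroid proxy)."""
    _check_tracks(tracks)
    out = tracks.copy()
    for col in ("x_um", "y_um"):
        out[col] = out[col] - out.groupby("frame")[col].transform("mean")
    return out


def _displacements(
    tracks: pd.DataFrame, interval_min: float, duration_min: float
) -> np.ndarray:
    """Per-cell displacement vectors at the requested sampling interval.

    Frames are selected (not averaged) at times that are multiples of
    ``interval_min`` up to ``duration_min``; a displacement is recorded for
    each pair of selected times ``interval_min`` apart at which the cell is
    present.
    """
    t = tracks["t_min"].to_numpy(float)
    steps = t / interval_min
    on_grid = np.abs(steps - np.round(steps)) < 1e-6
    within = t <= duration_min + 1e-9
    sel = tracks[on_grid & within].copy()
    sel["slot"] = np.round(sel["t_min"].to_numpy(float) / interval_min).astype(int)
    disp = []
    for _, grp in sel.groupby("cell_id", sort=False):
        grp = grp.sort_values("slot")
        slots = grp["slot"].to_numpy()
        xy = grp[["x_um", "y_um"]].to_numpy(float)
        consecutive = np.diff(slots) == 1
        d = np.diff(xy, axis=0)[consecutive]
        if len(d):
            disp.append(d)
    if not disp:
        return np.empty((0, 2))
    return np.concatenate(disp, axis=0)


def polar_order(
    tracks: pd.DataFrame,
    interval_min: float = 1.0,
    duration_min: float = 30.0,
) -> float:
    """Polar order parameter ``alpha`` of the centroid displacements.

    ``alpha = |sum p| / sum |p|`` over all cells and sampling intervals;
    1 for perfectly aligned movements, -> 0 for isotropic movements.
    Zero-length displacements contribute to neither sum.
    """
    _check_tracks(tracks)
    p = _displacements(tracks, interval_min, duration_min)
    denom = float(np.linalg.norm(p, axis=1).sum())
    if denom == 0.0:
        raise ValueError("all displacements are zero; polar order undefined")
    return float(np.linalg.norm(p.sum(axis=0)) / denom)


def displacement_stats(tracks: pd.DataFrame) -> tuple[pd.Series, float]:
    """Net displacement per cell (first to last position) and the tissue mean."""
    _check_tracks(tracks)
    rows = {}
    for cell_id, grp in tracks.groupby("cell_id", sort=False):
        grp = grp.sort_values("frame")
        xy = grp[["x_um", "y_um"]].to_numpy(float)
        rows[cell_id] = float(np.linalg.norm(xy[-1] - xy[0]))
    per_cell = pd.Series(rows, name="net_displacement_um")
    return per_cell, float(per_cell.mean())


def migration_rate(tracks: pd.DataFrame, method: str = "path") -> float:
    """Mean migration speed over cells, in um/min.

    ``method="path"`` (default) integrates frame-to-frame displacement along
    each track; ``method="net"`` uses the straight-line first-to-last
    displacement.  Either way the per-cell distance is divided by the track's
    elapsed time and averaged over cells.
    """
    _check_tracks(tracks)
    if method not in ("path", "net"):
        raise ValueError(f"method must be 'path' or 'net', got {method!r}")
    rates = []
    for _, grp in tracks.groupby("cell_id", sort=False):
        grp = grp.sort_values("frame")
        xy = grp[["x_um", "y_um"]].to_numpy(float)
        elapsed = float(grp["t_min"].iloc[-1] - grp["t_min"].iloc[0])
        if elapsed <= 0:
            raise ValueError("track has zero elapsed time")
        if method == "path":
            dist = float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())
        else:
            dist = float(np.linalg.norm(xy[-1] - xy[0]))
        rates.append(dist / elapsed)
    return float(np.mean(rates))


def fat2_polarity_ratio(
    edges: pd.DataFrame,
    leading_max_deg: float = 10.0,
    lateral_min_deg: float = 80.0,
) -> float:
    """Leading/trailing-to-lateral edge intensity ratio.

    Mean intensity of edges with angle in [0, ``leading_max_deg``] degrees to
    the AP axis divided by the mean intensity of edges with angle in
    [``lateral_min_deg``, 90].  Both bins are closed; edges in between are
    ignored.
    """
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise ValueError(f"edge table is missing columns: {missing}")
    angle = edges["angle_deg"].to_numpy(float)
    inten = edges["mean_intensity"].to_numpy(float)
    if np.any((angle < 0) | (angle > 90)) or not np.all(np.isfinite(angle)):
        raise ValueError("edge angles must lie in [0, 90] degrees")
    if np.any(inten < 0) or not np.all(np.isfinite(inten)):
        raise ValueError("edge intensities must be finite and >= 0")
    leading = inten[angle <= leading_max_deg]
    lateral = inten[angle >= lateral_min_deg]
    if len(leading) == 0 or len(lateral) == 0:
        raise ValueError(
            "polarity ratio undefined: need at least one edge in each of the "
            f"[0, {leading_max_deg}] and [{lateral_min_deg}, 90] degree bins"
        )
    return float(leading.mean() / lateral.mean())
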