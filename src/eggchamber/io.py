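"""CSV/JSON readers and writers for tracks, edges and trajectories.

All public artifacts are plain UTF-8 CSV with a mandatory header row so that
every intermediate of the pipeline can be inspected with standard tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .rigid_dynamics import Trajectory
from .track_analysis import EDGE_COLUMNS, TRACK_COLUMNS

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_edges",
    "write_edges",
    "write_trajectory",
    "read_trajectory",
]

_TRACK_NUMERIC = ["cell_id", "frame", "t_min", "x_um", "y_um"]
_EDGE_NUMERIC = ["angle_deg", "mean_intensity"]


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def _coerce_numeric(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            rows = (bad[bad].index + 2).tolist()  # 1-based + header line
            raise ValueError(
                f"{path}: non-numeric values in column '{col}' at line(s) {rows}"
            )
        df[col] = converted
    return df


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a centroid-track CSV (cell_id,frame,t_min,x_um,y_um,boundary)."""
    df = pd.read_csv(path)
    _check_columns(df, TRACK_COLUMNS, path)
    df = _coerce_numeric(df, _TRACK_NUMERIC, path)
    df["cell_id"] = df["cell_id"].astype(int)
    df["frame"] = df["frame"].astype(int)
    if df["boundary"].dtype != bool:
        df["boundary"] = (
            df["boundary"].astype(str).str.strip().str.lower()
            .map({"true": True, "false": False, "1": True, "0": False})
        )
        if df["boundary"].isna().any():
            raise ValueError(f"{path}: column 'boundary' must be boolean")
    return df[TRACK_COLUMNS]


def write_tracks(tracks: pd.DataFrame, path: str | Path) -> None:
    tracks[TRACK_COLUMNS].to_csv(path, index=False)


def read_edges(path: str | Path) -> pd.DataFrame:
    """Read a cell-edge CSV (edge_id,angle_deg,mean_intensity)."""
    df = pd.read_csv(path)
    _check_columns(df, EDGE_COLUMNS, path)
    return _coerce_numeric(df, _EDGE_NUMERIC, path)[EDGE_COLUMNS]


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges[EDGE_COLUMNS].to_csv(path, index=False)


def write_trajectory(traj: Trajectory, out_dir: str | Path, meta: dict | None = None):
    """Write a trajectory as CSV plus a JSON metadata sidecar.

    ``trajectory.csv`` holds t and omega3 (and, for the 3-D variants, the
    angular-velocity vector, its norm, and the spherical angles theta/phi of
    omega and of the AP axis d3 in the inertial frame);
    ``fat2.csv`` holds the cell-averaged Fat2 snapshots in long format.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = {"t": traj.times, "omega3": traj.omega3}
    if traj.omega is not None:
        w = traj.omega
        norm = np.linalg.norm(w, axis=1)
        with np.errstate(invalid="ignore"):
            cols.update(
                omega_norm=norm,
                theta_omega=np.degrees(np.arccos(np.clip(
                    np.divide(w[:, 2], norm, out=np.zeros_like(norm), where=norm > 0),
                    -1, 1))),
                phi_omega=np.degrees(np.arctan2(w[:, 1], w[:, 0])),
                theta_d3=np.degrees(np.arccos(np.clip(traj.d3[:, 2], -1, 1))),
                phi_d3=np.degrees(np.arctan2(traj.d3[:, 1], traj.d3[:, 0])),
            )
    pd.DataFrame(cols).to_csv(out / "trajectory.csv", index=False)

    S, M = traj.fat2_mean.shape
    fat2 = pd.DataFrame({
        "t": np.repeat(traj.times, M),
        "beta_bin_center": np.tile(traj.beta_centers, S),
        "c_mean": traj.fat2_mean.ravel(),
    })
    fat2.to_csv(out / "fat2.csv", index=False)

    from dataclasses import asdict
    doc = {"params": asdict(traj.params)}
    if meta:
        doc.update(meta)
    (out / "run.json").write_text(json.dumps(doc, indent=2, default=str))
    return out


def read_trajectory(out_dir: str | Path) -> pd.DataFrame:
    """Read back the scalar time series written by :func:`write_trajectory`."""
    return pd.read_csv(Path(out_dir) / "trajectory.csv")
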