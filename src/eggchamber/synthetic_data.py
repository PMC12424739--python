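"""Synthetic track and edge tables for testing the analysis pipeline.

Emulates the statistical structure of segmented live-imaging data from the
follicular epithelium without any microscopy:

* ``rotating`` — every cell shares a common drift (the in-plane signature of
  rigid rotation, 0.2 um/min by default, the typical speed of early-stage
  rotation) plus small isotropic jitter;
* ``pre_rotation`` — no common drift, large zero-mean jitter (basal centroids
  are dynamic but uncoordinated);
* ``null_like`` — no drift and near-static jitter (motility-dead epithelium).

Cells sit on a jittered hexagonal lattice; cells within one lattice spacing
of the field edge are flagged as boundary cells, and a configurable fraction
of cells appear only for a short consecutive window (shorter than the
10-frame analysis threshold) to exercise the track filters.

Edge tables draw edge angles uniformly over [0, 90] degrees and lognormal
intensities whose mean interpolates between a prescribed leading/trailing
level and a lateral level of 1, giving a known ground-truth polarity ratio.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrackGenConfig",
    "gen_tracks",
    "gen_isotropic_steps_tracks",
    "gen_edges",
]

_MODES = ("rotating", "pre_rotation", "null_like")


@dataclass(frozen=True)
class TrackGenConfig:
    """Parameters of the synthetic track generator.

    Defaults mimic a 30-minute movie at 15-second intervals of ~100 cells
    roughly 8 um across.
    """

    mode: str = "rotating"
    n_cells: int = 100
    n_frames: int = 121
    frame_interval_s: float = 15.0
    drift_um_per_min: float = 0.2
    jitter_um: float = 0.05
    dropout: float = 0.1
    cell_spacing_um: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.mode not in _MODES:
            errors.append(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.n_cells < 1 or self.n_frames < 2:
            errors.append("n_cells must be >= 1 and n_frames >= 2")
        if self.frame_interval_s <= 0 or self.cell_spacing_um <= 0:
            errors.append("frame_interval_s and cell_spacing_um must be > 0")
        if self.jitter_um < 0 or self.drift_um_per_min < 0:
            errors.append("jitter_um and drift_um_per_min must be >= 0")
        if not 0 <= self.dropout < 1:
            errors.append(f"dropout must be in [0, 1), got {self.dropout!r}")
        if errors:
            raise ValueError("; ".join(errors))

    def replace(self, **kwargs) -> "TrackGenConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def rotating(cls, **kwargs) -> "TrackGenConfig":
        return cls(mode="rotating", drift_um_per_min=0.2, jitter_um=0.05, **kwargs)

    @classmethod
    def pre_rotation(cls, **kwargs) -> "TrackGenConfig":
        return cls(mode="pre_rotation", drift_um_per_min=0.0, jitter_um=0.15, **kwargs)

    @classmethod
    def null_like(cls, **kwargs) -> "TrackGenConfig":
        return cls(mode="null_like", drift_um_per_min=0.0, jitter_um=0.02, **kwargs)


def _hex_lattice(n_cells: int, spacing: float, rng: np.random.Generator):
    """Jittered hexagonal lattice of at least ``n_cells`` points (trimmed)."""
    cols = int(np.ceil(np.sqrt(n_cells)))
    rows = int(np.ceil(n_cells / cols))
    ij = np.stack(np.meshgrid(np.arange(cols), np.arange(rows)), axis=-1).reshape(-1, 2)
    xy = ij.astype(float)
    xy[:, 0] += 0.5 * (ij[:, 1] % 2)  # stagger alternate rows
    xy[:, 1] *= np.sqrt(3.0) / 2.0
    xy *= spacing
    xy = xy[:n_cells]
    xy += rng.normal(scale=0.1 * spacing, size=xy.shape)
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    boundary = np.any((xy < lo + spacing) | (xy > hi - spacing), axis=1)
    return xy, boundary


def gen_tracks(cfg: TrackGenConfig) -> pd.DataFrame:
    """Generate a centroid-track table for one synthetic epithelium.

    Per frame each cell moves by the common drift (zero except in
    ``rotating`` mode) plus isotropic Gaussian jitter.  A ``dropout``
    fraction of cells is truncated to a short consecutive window (3-9
    frames), falling below the standard 10-frame filter.
    """
    rng = np.random.default_rng(cfg.seed)
    xy0, boundary = _hex_lattice(cfg.n_cells, cfg.cell_spacing_um, rng)
    dt_min = cfg.frame_interval_s / 60.0

    if cfg.mode == "rotating" and cfg.drift_um_per_min > 0:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        drift = cfg.drift_um_per_min * dt_min * np.array([np.cos(theta), np.sin(theta)])
    else:
        drift = np.zeros(2)

    steps = drift[None, None, :] + cfg.jitter_um * rng.standard_normal(
        (cfg.n_cells, cfg.n_frames - 1, 2)
    )
    pos = np.concatenate(
        [xy0[:, None, :], xy0[:, None, :] + np.cumsum(steps, axis=1)], axis=1
    )

    n_drop = int(round(cfg.dropout * cfg.n_cells))
    drop_cells = rng.choice(cfg.n_cells, size=n_drop, replace=False)
    windows = {}
    for c in drop_cells:
        length = int(rng.integers(3, 10))
        start = int(rng.integers(0, cfg.n_frames - length + 1))
        windows[c] = (start, start + length)

    records = []
    for c in range(cfg.n_cells):
        lo, hi = windows.get(c, (0, cfg.n_frames))
        for f in range(lo, hi):
            records.append((c, f, f * dt_min, pos[c, f, 0], pos[c, f, 1], bool(boundary[c])))
    return pd.DataFrame(
        records, columns=["cell_id", "frame", "t_min", "x_um", "y_um", "boundary"]
    )


def gen_isotropic_steps_tracks(
    n_cells: int = 100,
    n_intervals: int = 30,
    step_um: float = 1.0,
    interval_min: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tracks whose per-interval displacements all have magnitude ``step_um``
    and independent uniformly random directions — the isotropic null of the
    polar order parameter."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(n_cells, n_intervals))
    steps = step_um * np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    start = rng.uniform(0.0, 100.0, size=(n_cells, 1, 2))
    pos = np.concatenate([start, start + np.cumsum(steps, axis=1)], axis=1)
    records = []
    for c in range(n_cells):
        for f in range(n_intervals + 1):
            records.append((c, f, f * interval_min, pos[c, f, 0], pos[c, f, 1], False))
    return pd.DataFrame(
        records, columns=["cell_id", "frame", "t_min", "x_um", "y_um", "boundary"]
    )


def gen_edges(
    n: int, ratio: float, noise_cv: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Generate a cell-edge table with a prescribed polarity ratio.

    Edge angles are uniform on [0, 90] degrees; intensities are lognormal
    with mean ``ratio`` for angles <= 10, mean 1 for angles >= 80 and a
    linear interpolation in between, with coefficient of variation
    ``noise_cv`` (0 gives exact, noise-free intensities).
    """
    if ratio <= 0:
        raise ValueError(f"ratio must be > 0, got {ratio!r}")
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv!r}")
    rng = np.random.default_rng(seed)
    angle = rng.uniform(0.0, 90.0, size=n)
    frac = np.clip((angle - 10.0) / 70.0, 0.0, 1.0)  # 0 at leading, 1 at lateral
    mean = ratio + (1.0 - ratio) * frac
    if noise_cv == 0:
        intensity = mean
    else:
        sigma2 = np.log1p(noise_cv**2)
        mu = np.log(mean) - 0.5 * sigma2
        intensity = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2))
    return pd.DataFrame(
        {"edge_id": np.arange(n), "angle_deg": angle, "mean_intensity": intensity}
    )
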