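"""Validated run configuration (YAML/JSON) for simulation and analysis."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .geometry import EggChamberGeometry, make_geometry
from .rigid_dynamics import ModelParams
from .constrained_dynamics import PrestalkParams

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised with one message line per schema violation."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_default=True)


class GeometrySection(_Section):
    e: float = Field(default=1.2, ge=1.0)
    n_cells: int = Field(default=200, ge=4)
    jitter: float = Field(default=0.0, ge=0.0)


class ModelSection(_Section):
    tau1: float = Field(default=1.0, gt=0)
    tau2: float = Field(default=1.0, gt=0)
    tau3: float = Field(default=20.0, ge=0)
    dt: float = Field(default=0.01, gt=0)
    T: float = Field(default=200.0, gt=0)
    M: int = Field(default=64, ge=8, multiple_of=2)
    resample_every: int = Field(default=1, ge=1)
    c_floor: float = Field(default=1e-8, gt=0)
    record_every: int = Field(default=20, ge=1)


class PrestalkSection(_Section):
    theta_s: float = Field(default=float(np.pi / 6), gt=0, lt=float(np.pi / 2))
    k_s: float = Field(default=200.0, ge=0)
    mu_s: float = Field(default=10.0, ge=0)


class AnalysisSection(_Section):
    min_track_len: int = Field(default=10, ge=1)
    drop_boundary: bool = True
    interval_min: float = Field(default=1.0, gt=0)
    duration_min: float = Field(default=30.0, gt=0)
    rate_method: str = Field(default="path", pattern="^(path|net)$")


class IOSection(_Section):
    out_dir: str = "out"


class RunConfig(_Section):
    """Full configuration; unknown keys are rejected."""

    geometry: GeometrySection = Field(default_factory=GeometrySection)
    model: ModelSection = Field(default_factory=ModelSection)
    prestalk: PrestalkSection = Field(default_factory=PrestalkSection)
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)
    io: IOSection = Field(default_factory=IOSection)
    seed: int = 0

    # -- converters to the runtime parameter objects ------------------------

    def make_geometry(self) -> EggChamberGeometry:
        g = self.geometry
        return make_geometry(g.e, g.n_cells, seed=self.seed, jitter=g.jitter)

    def model_params(self, seed: int | None = None) -> ModelParams:
        m = self.model
        return ModelParams(
            tau1=m.tau1, tau2=m.tau2, tau3=m.tau3, dt=m.dt, T=m.T, M=m.M,
            resample_every=m.resample_every, c_floor=m.c_floor,
            record_every=m.record_every,
            seed=self.seed if seed is None else seed,
        )

    def prestalk_params(self, seed: int | None = None) -> PrestalkParams:
        p = self.prestalk
        return PrestalkParams(
            model=self.model_params(seed=seed),
            theta_s=p.theta_s, k_s=p.k_s, mu_s=p.mu_s,
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML (or JSON) configuration file.

    An absent path or empty file yields the full set of defaults.  On schema
    violations a :class:`ConfigError` is raised listing every violation at
    once with its field path.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as err:
        lines = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines)) from None


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips via load_config)."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
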