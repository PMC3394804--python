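"""Readers/writers and validated run configurations.

Traces travel as 2-column delimited files (time_s, intensity; header
optional), trajectories and scans as tidy CSV, reports as JSON with a
schema version, and network/run configurations as YAML validated by
pydantic models that reject unknown keys.  Every written artifact embeds
the seed and a hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .inverse import FluorescenceTrace
from .network import ReactionNetwork
from .simulate import Trajectory

__all__ = [
    "read_trace",
    "write_trace",
    "write_report",
    "write_trajectory",
    "read_network",
    "write_network",
    "RunConfig",
    "load_config",
    "config_hash",
]

SCHEMA_VERSION = "1"


class SolverSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t_end: float = Field(100.0, gt=0)
    n_points: int = Field(200, ge=2)
    rel_tol: float = Field(1e-8, gt=0)
    abs_tol: float = Field(1e-10, gt=0)
    steady_tol: float = Field(1e-9, gt=0)


class ModelOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    variant: Literal["fundamental", "full", "munc18"] = "fundamental"
    complexin: bool = False
    ca_mode: Literal["off", "clamped", "dynamic"] = "off"
    munc18: bool = False
    self_association: bool = False
    n_max: int = Field(5, ge=2)


class FitSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float | None = Field(None, ge=0)
    penalty_weight: float = Field(1e3, ge=0)
    init_guess: list[float] | None = None
    phase1_iters: int = Field(25, ge=0)
    phase2_iters: int = Field(300, ge=1)
    offset: float = 0.0


class RunConfig(BaseModel):
    """Schema-validated configuration for a CLI run; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")
    model: ModelOptions = ModelOptions()
    rates: dict[str, float] = {}
    initials: dict[str, float] = {}
    solver: SolverSettings = SolverSettings()
    fit: FitSettings = FitSettings()
    seed: int = 0

    def build_variant(self):
        from . import models

        if self.model.variant == "munc18":
            return models.munc18_subsystem(self.initials)
        if self.model.variant == "fundamental":
            return models.fundamental_subsystem(self.initials)
        return models.full_system(
            complexin=self.model.complexin,
            ca_mode=self.model.ca_mode,
            munc18=self.model.munc18,
            self_association=self.model.self_association,
            n_max=self.model.n_max,
            initials=self.initials,
        )

    def simulation_config(self):
        from .simulate import SimulationConfig

        s = self.solver
        return SimulationConfig(
            t_end=s.t_end, n_points=s.n_points, rel_tol=s.rel_tol,
            abs_tol=s.abs_tol, steady_tol=s.steady_tol,
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig | Mapping) -> str:
    if isinstance(config, RunConfig):
        payload = config.model_dump()
    else:
        payload = dict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# -- traces -----------------------------------------------------------------


def read_trace(path: str | Path) -> FluorescenceTrace:
    """Strict parse of a delimited (time_s, intensity) file.

    Header row optional; times must be strictly increasing and all cells
    numeric.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "," if "," in first else None
    try:
        float(first.split(sep or ",")[0])
        header = None
    except ValueError:
        header = 0
    df = pd.read_csv(
        path, sep=sep or ",", header=header, float_precision="round_trip"
    )
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected time and intensity columns")
    if header == 0:
        cols = [c.strip().lower() for c in df.columns]
        tcol = next((i for i, c in enumerate(cols) if c.startswith("time")), 0)
        icol = next(
            (i for i, c in enumerate(cols) if c.startswith("intens")),
            1 if tcol == 0 else 0,
        )
    else:
        tcol, icol = 0, 1
    times = pd.to_numeric(df.iloc[:, tcol], errors="raise").to_numpy(float)
    intensities = pd.to_numeric(df.iloc[:, icol], errors="raise").to_numpy(float)
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: times must be strictly increasing")
    return FluorescenceTrace(times, intensities, meta={"provenance": "file",
                                                       "path": str(path)})


def write_trace(trace: FluorescenceTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "intensity": trace.intensities})
    df.to_csv(path, index=False, float_format="%.17g")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Tidy CSV: time, one column per species, conservation drift columns."""
    df = traj.to_frame()
    for i, (law, drift) in enumerate(traj.conservation_audit.items(), start=1):
        df[f"drift_law_{i}"] = drift
    df.to_csv(path, index=False, float_format="%.17g")


def write_report(result, path: str | Path, seed: int | None = None,
                 config: RunConfig | Mapping | None = None) -> None:
    """JSON report with schema version, seed and config hash embedded."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if hasattr(obj, "__dict__"):
            return {k: v for k, v in vars(obj).items() if not k.startswith("_")}
        return str(obj)

    payload = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "result": result,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)


# -- networks ---------------------------------------------------------------


def write_network(network: ReactionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network.to_dict(), fh, sort_keys=False)


def read_network(path: str | Path) -> ReactionNetwork:
    with open(path) as fh:
        return ReactionNetwork.from_dict(yaml.safe_load(fh))
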