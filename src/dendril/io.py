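"""Experiment configuration parsing and result serialisation.

Configs are YAML documents validated against a strict schema (unknown keys
rejected, units as in :mod:`dendril.constants`); every result file is
written next to a JSON summary embedding the full config and its content
hash so any run can be regenerated from its own outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .experiments import ScanResult
from .metrics import ILProfile
from .morphology import BranchSpec
from .simulator import Recording

__all__ = [
    "ExperimentConfig",
    "ConfigError",
    "parse_config",
    "config_hash",
    "write_results",
    "read_profile",
]


class ConfigError(ValueError):
    """Invalid experiment configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MorphologyConfig(_Strict):
    n_branches: int = Field(default=4, ge=1)
    radius: float = Field(default=0.5, gt=0)  # μm
    length: float | None = Field(default=None, gt=0)  # μm; None -> 1 λ
    rm: float = Field(default=20.0, gt=0)  # kΩ·cm²
    ra: float = Field(default=100.0, gt=0)  # Ω·cm
    cm: float = Field(default=1.0, gt=0)  # μF/cm²
    v_rest: float = -65.0  # mV
    sink_diameter: float | None = Field(default=None, gt=0)  # μm
    sink_length_mode: Literal["fixed", "scaled"] = "fixed"

    def branch_spec(self) -> BranchSpec:
        return BranchSpec(
            radius=self.radius,
            length=self.length,
            rm=self.rm,
            ra=self.ra,
            cm=self.cm,
            v_rest=self.v_rest,
        )


class SynapseConfig(_Strict):
    distribution: Literal["tree", "branch", "focal"] = "tree"
    i: float = Field(default=0.2, ge=0.0, le=1.0)
    count: int | None = Field(default=None, ge=1)
    g_mean: float = Field(default=0.001, ge=0)  # μS
    noise_sd_fraction: float = Field(default=0.1, ge=0)
    noise_tau: float = Field(default=10.0, gt=0)  # ms
    delta_egaba: float | None = 0.0  # mV; None -> track the ion state


class StimulusConfig(_Strict):
    branch: int = 0
    x: float = Field(default=0.0, ge=0.0, le=1.0)
    amplitude: float = 0.001  # nA
    onset: float = Field(default=0.0, ge=0)
    offset: float | None = None  # None -> whole simulation


class SolverConfig(_Strict):
    dt: float = Field(default=0.025, gt=0)  # ms
    duration: float = Field(default=150.0, gt=0)  # ms
    dx: float = Field(default=0.01, gt=0, le=1.0)  # fraction of λ
    record_dt: float = Field(default=0.5, gt=0)  # ms
    seeds: list[int] = Field(default_factory=lambda: [1, 2, 3, 4, 5])
    chloride_mode: Literal["static", "dynamic"] = "static"
    egaba_init: float = -70.0  # mV (dynamic mode initial EGABA)


class MetricsConfig(_Strict):
    t: float | None = None  # evaluation time; None -> solver duration
    window: float = Field(default=5.0, gt=0)  # ms


class ExperimentConfig(_Strict):
    morphology: MorphologyConfig = Field(default_factory=MorphologyConfig)
    synapses: SynapseConfig = Field(default_factory=SynapseConfig)
    stimulus: StimulusConfig = Field(default_factory=StimulusConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    output_dir: str = "results"

    def to_dict(self) -> dict:
        return self.model_dump()


def parse_config(document: str | dict | Path | None) -> ExperimentConfig:
    """Parse and validate a YAML config; all fields have Table-1 defaults.

    Accepts YAML text, an already-loaded mapping, a path, or None (full
    defaults).  Unknown keys, unit violations and type errors raise
    :class:`ConfigError` naming the offending key.
    """
    if document is None:
        data: dict = {}
    elif isinstance(document, dict):
        data = document
    else:
        text = (
            Path(document).read_text()
            if isinstance(document, Path)
            else document
        )
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config document must be a mapping")
    try:
        return ExperimentConfig.model_validate(data)
    except ValidationError as exc:
        first = exc.errors()[0]
        key = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"invalid config at '{key}': {first['msg']}") from None


def config_hash(config: ExperimentConfig | dict) -> str:
    """Stable content hash of a configuration."""
    payload = config.to_dict() if isinstance(config, ExperimentConfig) else config
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def write_results(
    result: ScanResult | ILProfile | Recording,
    path: str | Path,
    config: ExperimentConfig | dict | None = None,
    experiment_id: str = "",
) -> list[Path]:
    """Write a result as tidy CSV plus a JSON summary; returns the paths.

    ``path`` is the CSV target; the summary lands at ``path`` with a
    ``.json`` suffix.  Column order is deterministic; re-reading the CSV
    reproduces the stored values exactly (full float precision).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(result, ScanResult):
        frame = result.frame
        summary = {
            "scanned": result.scanned,
            "argmax": _jsonable(result.argmax),
            "seeds": list(result.seeds),
            "config": _jsonable(result.config),
        }
    elif isinstance(result, ILProfile):
        frame = result.to_frame()
        summary = {"t": result.t, "window": result.window, "chloride_mode": result.chloride_mode}
    elif isinstance(result, Recording):
        frame = result.to_frame()
        summary = {
            "duration": float(result.times[-1]),
            "dt": result.config.dt,
            "seed": result.config.seed,
            "chloride_mode": result.config.chloride_mode,
        }
    else:
        raise TypeError(f"cannot serialise {type(result).__name__}")
    if experiment_id:
        frame = frame.assign(experiment_id=experiment_id)
        summary["experiment_id"] = experiment_id
    if config is not None:
        summary["config"] = _jsonable(
            config.to_dict() if isinstance(config, ExperimentConfig) else config
        )
        summary["config_hash"] = config_hash(config)
    frame.to_csv(path, index=False, float_format="%.17g")
    json_path = path.with_suffix(".json")
    json_path.write_text(json.dumps(summary, indent=2, default=str))
    return [path, json_path]


def read_profile(path: str | Path) -> pd.DataFrame:
    """Load a tidy CSV result back into a DataFrame."""
    return pd.read_csv(path, float_precision="round_trip")
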