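"""Run configuration: a sectioned YAML file validated before any allocation.

Unknown keys are rejected so a typo never silently falls back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError


class RecorderSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    variable: str
    cadence: int = Field(default=1, ge=1)
    format: Literal["csv", "hdf5"] = "csv"


class LIFOverrides(BaseModel):
    model_config = ConfigDict(extra="forbid")
    v_rest: Optional[float] = None
    v_reset: Optional[float] = None
    v_threshold: Optional[float] = None
    leak: Optional[float] = None
    noise_high: Optional[float] = None


class IzhikevichOverrides(BaseModel):
    model_config = ConfigDict(extra="forbid")
    a: Optional[float] = None
    b: Optional[float] = None
    c: Optional[float] = None
    d: Optional[float] = None
    spike_cutoff: Optional[float] = None
    noise_mean: Optional[float] = None
    noise_sd: Optional[float] = None


class PlasticityOverrides(BaseModel):
    model_config = ConfigDict(extra="forbid")
    learning_rate: Optional[float] = None
    w_min: Optional[float] = None
    w_max: Optional[float] = None
    norm_interval: Optional[int] = None


class TraceOverrides(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tau_pre: Optional[float] = None
    tau_post: Optional[float] = None
    a_plus: Optional[float] = None
    a_minus: Optional[float] = None


class RunConfig(BaseModel):
    """Everything a ``run`` or ``benchmark`` invocation needs."""

    model_config = ConfigDict(extra="forbid")

    model: Literal["lif_onestep", "izhikevich_trace"] = "lif_onestep"
    n_neurons: int = Field(default=1000, ge=1)
    implementation: Literal["optimized", "naive"] = "optimized"
    dtype: Literal["f64", "f32", "f16"] = "f64"
    backend: str = "numpy"
    seed: int = 0
    iterations: int = Field(default=300, ge=0)
    normalize: bool = False
    recorders: list[RecorderSpec] = Field(default_factory=list)
    output_dir: str = "out"
    lif: LIFOverrides = Field(default_factory=LIFOverrides)
    izhikevich: IzhikevichOverrides = Field(default_factory=IzhikevichOverrides)
    plasticity: PlasticityOverrides = Field(default_factory=PlasticityOverrides)
    trace: TraceOverrides = Field(default_factory=TraceOverrides)
    # benchmark-only section
    sizes: list[int] = Field(default_factory=lambda: [1000])
    replicates: int = Field(default=10, ge=1)


class FixtureSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["spike_vector", "weight_matrix"]
    size: Optional[int] = None                 # spike_vector
    shape: Optional[list[int]] = None          # weight_matrix
    p: float = Field(default=0.01, ge=0.0, le=1.0)
    distribution: Literal["uniform01", "zeros", "value"] = "uniform01"
    value: float = 0.0
    dtype: Literal["f64", "f32", "f16"] = "f64"
    layout: Literal["dst_major", "src_major"] = "dst_major"
    seed: int = 0


class ConfigError(ValueError):
    """Invalid configuration; message carries the offending location."""


def _validate(model_cls, raw: dict, source: str):
    try:
        return model_cls.model_validate(raw)
    except ValidationError as exc:
        lines = [f"invalid config {source}:"]
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"  at {loc}: {err['msg']}")
        raise ConfigError("\n".join(lines)) from exc


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f"{path}:{mark.line + 1}" if mark else str(path)
        raise ConfigError(f"invalid config {where}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"invalid config {path}: top level must be a mapping")
    return _validate(RunConfig, raw, str(path))


def load_fixture_spec(path: str | Path) -> FixtureSpec:
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    return _validate(FixtureSpec, raw, str(path))


def dump_config(cfg: RunConfig) -> str:
    """Serialize a config; load(dump(cfg)) is semantically idempotent."""
    return yaml.safe_dump(cfg.model_dump(), sort_keys=False)


def build_kwargs(cfg: RunConfig) -> dict:
    """Translate a RunConfig into build_reference_model keyword arguments."""
    from .models import IzhikevichParams, LIFParams, PlasticityParams, TraceParams

    def merged(cls, overrides):
        base = cls()
        vals = {k: v for k, v in overrides.model_dump().items() if v is not None}
        return cls(**{**base.__dict__, **vals}) if vals else base

    return dict(
        seed=cfg.seed,
        implementation=cfg.implementation,
        dtype=cfg.dtype,
        backend=cfg.backend,
        normalize=cfg.normalize,
        lif=merged(LIFParams, cfg.lif),
        izhikevich=merged(IzhikevichParams, cfg.izhikevich),
        plasticity=merged(PlasticityParams, cfg.plasticity),
        trace=merged(TraceParams, cfg.trace),
    )
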