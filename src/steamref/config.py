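"""Run configuration: YAML loading, validation, and hashing.

A single YAML file configures every subcommand; unknown keys are rejected
so that typos fail loudly.  Every stochastic path (phantom noise, Monte
Carlo validation) takes its seed from the config (overridable on the
command line), and all outputs embed the config hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "ConfigError", "load_config", "config_hash"]


class ConfigError(ValueError):
    """Invalid run configuration (maps to CLI exit status 2)."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_StrictModel):
    """Acquisition protocol; defaults reproduce the postmortem experiment."""

    Delta_list_ms: list[float] = [70, 100, 150, 200, 250, 300, 350, 400]
    delta_ms: float = 2.22
    nominal_b: float = 3.5  # ms um^-2
    te_ms: float = 16.0
    n_directions: int = 30
    reference_mode: Literal["fixed_b0", "fixed_q0"] = "fixed_b0"
    b0_at_delta_max: float = 0.631  # ms um^-2
    n_axes: int = 3
    scheme_variant: Literal["conventional", "modified"] = "modified"


class CurvesConfig(_StrictModel):
    b0_fractions: list[float] = [0.0, 0.1, 0.2, 0.3]
    direction: Optional[list[float]] = None


class ContoursConfig(_StrictModel):
    b_grid: list[float] = [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
    Delta_grid_ms: list[float] = [70, 100, 150, 200, 250, 300, 350, 400]
    b0_fraction: float = 0.2


class SeqcheckConfig(_StrictModel):
    q_crusher: float = 0.046  # um^-1
    q_slice: float = 0.046
    b_diffusion: list[float] = [3.5, 0.7, 0.0]


class ValidateConfig(_StrictModel):
    n_walkers: int = 100_000
    q_values: list[float] = [0.02, 0.05, 0.1]
    Delta_values_ms: list[float] = [10, 50, 200, 500]
    r_um: float = 5.0
    D: float = 2.0


class AnalyzeConfig(_StrictModel):
    Delta_short_ms: float = 70.0
    Delta_long_ms: float = 400.0
    denominator: Literal["fixed_b0", "fixed_q0"] = "fixed_b0"


class RunConfig(_StrictModel):
    seed: int = 0
    log_level: str = "INFO"
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    model: dict = Field(
        default_factory=lambda: {"type": "biexp", "f_s": 0.3, "D_s": 0.2, "D_f": 1.0}
    )
    phantom: dict = Field(default_factory=dict)
    curves: CurvesConfig = Field(default_factory=CurvesConfig)
    contours: ContoursConfig = Field(default_factory=ContoursConfig)
    seqcheck: SeqcheckConfig = Field(default_factory=SeqcheckConfig)
    validate_mc: ValidateConfig = Field(default_factory=ValidateConfig)
    analyze: AnalyzeConfig = Field(default_factory=AnalyzeConfig)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; None yields the defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse YAML: {exc}") from exc
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        fields = "; ".join(
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"] for e in exc.errors()
        )
        raise ConfigError(f"invalid config ({fields})") from exc


def config_hash(cfg: RunConfig, seed: int | None = None) -> str:
    """Short deterministic hash of the effective configuration."""
    payload = cfg.model_dump()
    if seed is not None:
        payload["seed"] = seed
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
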