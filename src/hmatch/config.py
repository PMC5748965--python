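"""Schema-validated configuration for a history-matching campaign."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class ConfigError(ValueError):
    pass


class WaveSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_runs: int = Field(ge=1)
    n_diagnostic: int = Field(default=50, ge=1)
    c_max: Optional[float] = Field(default=None, gt=0)
    c_2max: Optional[float] = Field(default=None, gt=0)
    c_3max: Optional[float] = Field(default=None, gt=0)
    outputs: Optional[list[str]] = None
    basis_order: int = Field(default=3, ge=0)
    nugget_proportion: float = Field(default=0.05, ge=0.0, le=1.0)
    theta: float = Field(default=0.35, gt=0)
    n_mc_volume: int = Field(default=20000, ge=1)
    admission_threshold: float = Field(default=0.95, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _at_least_one_cutoff(self):
        if self.c_max is None and self.c_2max is None and self.c_3max is None:
            raise ValueError("each wave needs at least one implausibility cutoff")
        return self

    def policy_dict(self) -> dict:
        out = {}
        if self.c_max is not None:
            out["c_max"] = self.c_max
        if self.c_2max is not None:
            out["c_2max"] = self.c_2max
        if self.c_3max is not None:
            out["c_3max"] = self.c_3max
        return out


class MatchConfig(BaseModel):
    """A full campaign: simulator, ranges, observations, wave schedule."""

    model_config = ConfigDict(extra="forbid")

    simulator: Literal["toy", "crosstalk_full", "crosstalk_k2c0", "external"]
    ranges: Optional[str] = None        # CSV path; None = simulator's bundled ranges
    observations: Optional[str] = None  # CSV path; None = bundled observations
    external_command: Optional[str] = None
    waves: list[WaveSettings]
    seed: int = 0
    solver_rtol: float = 1e-8
    solver_atol: float = 1e-10
    convergence_fraction: float = Field(default=0.1, gt=0)

    @model_validator(mode="after")
    def _external_needs_command(self):
        if self.simulator == "external" and not self.external_command:
            raise ValueError("external simulator requires external_command")
        if not self.waves:
            raise ValueError("at least one wave must be configured")
        return self

    def config_hash(self) -> str:
        doc = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> MatchConfig:
    """Load and validate a YAML/JSON campaign config.

    Raises :class:`ConfigError` listing every schema violation found.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    text = path.read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError(f"config file {path} is empty or not a mapping")
    try:
        cfg = MatchConfig.model_validate(doc)
    except Exception as e:
        raise ConfigError(f"invalid config {path}:\n{e}") from e

    # cross-checks against the observation table
    if cfg.observations is not None:
        from .linkage import observations_from_csv

        obs = observations_from_csv(cfg.observations)
        problems = []
        for i, w in enumerate(cfg.waves):
            for name in w.outputs or []:
                if name not in obs:
                    problems.append(
                        f"wave {i+1} output {name!r} missing from the observation table"
                    )
        if problems:
            raise ConfigError("invalid config:\n" + "\n".join(problems))
    elif cfg.simulator in ("crosstalk_full", "crosstalk_k2c0"):
        from .crosstalk import OUTPUT_NAMES

        problems = []
        for i, w in enumerate(cfg.waves):
            for name in w.outputs or []:
                if name not in OUTPUT_NAMES:
                    problems.append(
                        f"wave {i+1} output {name!r} is not a crosstalk model output"
                    )
        if problems:
            raise ConfigError("invalid config:\n" + "\n".join(problems))
    return cfg


def arabidopsis_reproduction_config() -> MatchConfig:
    """The bundled five-wave reproduction schedule for the crosstalk model.

    2000 runs and 200 diagnostic runs per wave; the wave cutoffs follow the
    reference schedule (wave 1: I_2M <= 3.25 and I_3M <= 3; wave 2: 3.1/2.8;
    wave 3: 5/2.9/2.7; wave 4: 3.2/2.8/2.65; wave 5 is a simulator-certified
    sampling pass at I_M <= 3.2 rather than an emulated wave).
    """
    return MatchConfig(
        simulator="crosstalk_full",
        seed=1,
        waves=[
            WaveSettings(n_runs=2000, n_diagnostic=200, c_2max=3.25, c_3max=3.0),
            WaveSettings(n_runs=2000, n_diagnostic=200, c_2max=3.1, c_3max=2.8),
            WaveSettings(n_runs=2000, n_diagnostic=200, c_max=5.0, c_2max=2.9, c_3max=2.7),
            WaveSettings(n_runs=2000, n_diagnostic=200, c_max=3.2, c_2max=2.8, c_3max=2.65),
        ],
    )
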