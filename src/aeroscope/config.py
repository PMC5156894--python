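"""Run configuration: one documented place for every pipeline default.

The ``RunConfig`` model is the single source of truth for thresholds,
trimming windows, statistical settings, and output locations. A YAML file
overrides any subset of fields; unknown keys are an error (no silent
ignore), and out-of-range values fail validation.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field
from pydantic import ValidationError as _PydanticValidationError

from .errors import ConfigError


class RunConfig(BaseModel):
    """Resolved pipeline configuration.

    Field defaults document the protocol: 60 s lead/tail trims on each
    sealed measurement phase, background rejection when the background rate
    exceeds 25% of provisional RMR, an r^2 of 0.90 below which a slope is
    QC-flagged (never auto-rejected), and alpha = 0.05 for the model
    reduction protocol.
    """

    model_config = ConfigDict(extra="forbid")

    dialect: str = "default"
    lenient: bool = False

    # respirometry reduction
    lead_trim_s: float = Field(default=60.0, ge=0)
    tail_trim_s: float = Field(default=60.0, ge=0)
    bg_frac_threshold: float = Field(default=0.25, ge=0, le=1)
    r2_threshold: float = Field(default=0.90, ge=0, le=1)
    background_mode: str = Field(default="auto", pattern="^(auto|constant|linear_in_time)$")
    fish_density_kg_per_l: float = Field(default=1.0, gt=0)

    # statistics
    alpha: float = Field(default=0.05, gt=0, lt=1)
    sum_of_squares: int = Field(default=2, ge=1, le=3)
    tukey_on_log_scale: bool = True

    # run plumbing
    seed: int = Field(default=0, ge=0)
    out_dir: str = "results"


def load_run_config(path: Path | str | None) -> RunConfig:
    """Load a YAML config, filling documented defaults for unset keys.

    Passing ``None`` (or an empty file) returns pure defaults. Resolution is
    a pure function of (file contents, defaults): repeated loads are
    identical.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparseable config {path}: {exc}") from exc
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig(**raw)
    except _PydanticValidationError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
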