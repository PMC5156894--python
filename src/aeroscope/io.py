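"""Trace CSV dialect, trial metadata sidecars, and validation.

A trial is stored as two text files next to each other:

* ``<name>.csv`` — the trace, columns ``time_s,do_mgl,temp_c,pump_on``
  (header mandatory, UTF-8, '.' decimal separator). Extra columns are
  preserved on round-trip but ignored by the pipeline.
* ``<name>.meta.yaml`` — the sidecar with fish/chamber/trial metadata.

Oxygen is always stored in mg l^-1; percent air saturation appears only in
chamber metadata (``basin_do_pct_sat``). The flush-pump state is an explicit
channel: measurement phases are maximal runs of ``pump_on == 0``; phase
boundaries are never inferred from oxygen inflections.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field
from pydantic import ValidationError as _PydanticValidationError

from .errors import FormatError, ValidationError

logger = logging.getLogger("aeroscope")

TRACE_COLUMNS = ["time_s", "do_mgl", "temp_c", "pump_on"]

Habitat = Literal["forest", "miscanthidium"]
TrialType = Literal["acclimation", "rmr", "mmr", "background_pre", "background_post", "ctmax"]

#: Acclimation temperature treatments used throughout (degrees C).
TREATMENTS = (25.5, 27.5, 29.5, 31.5)


class FishMeta(BaseModel):
    """Identity and state of one fish at trial time."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    fish_id: str
    mass_g: float = Field(gt=0)
    tl_cm: float = Field(gt=0)
    habitat: Habitat
    acclim_temp_c: float
    acclim_days: float = Field(ge=0)

    @property
    def mass_kg(self) -> float:
        return self.mass_g / 1000.0


class ChamberMeta(BaseModel):
    """Closed-loop respirometry system: chamber + pump + tubing."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    chamber_id: str
    system_volume_l: float = Field(gt=0)
    basin_do_pct_sat: float = Field(default=100.0, ge=0)


@dataclass
class TrialRecord:
    """One chamber occupancy: a validated trace plus its metadata.

    ``fish`` is ``None`` for background (empty-chamber) trials. ``extras``
    carries any unrecognized sidecar keys (e.g. simulator ground truth) and
    round-trips losslessly.
    """

    trial_type: TrialType
    chamber: ChamberMeta
    trace: pd.DataFrame
    fish: Optional[FishMeta] = None
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_trace(self.trace)
        if self.trial_type in ("background_pre", "background_post") and self.fish is not None:
            raise ValidationError(
                f"background trial on chamber {self.chamber.chamber_id!r} "
                "must not have a fish attached"
            )

    @property
    def duration_s(self) -> float:
        t = self.trace["time_s"].to_numpy()
        return float(t[-1] - t[0])


def validate_trace(trace: pd.DataFrame, lenient: bool = False) -> pd.DataFrame:
    """Check trace invariants; return the (possibly row-dropped) frame.

    Strict mode raises on the first violation. Lenient mode downgrades
    time-monotonicity violations to warnings and drops the offending rows
    (each dropped row is logged); range violations always raise.
    """
    for col in TRACE_COLUMNS:
        if col not in trace.columns:
            raise FormatError(f"trace is missing required column {col!r}")
    if len(trace) == 0:
        raise ValidationError("trace is empty")

    t = trace["time_s"].to_numpy()
    bad = (t[1:] <= t[:-1]).nonzero()[0]
    if bad.size:
        first = int(bad[0]) + 1
        if not lenient:
            raise ValidationError(
                f"time_s is not strictly increasing: first violation at row {first} "
                f"(time_s={t[first]!r} after {t[first - 1]!r})"
            )
        keep = [0]
        last = t[0]
        for i in range(1, len(t)):
            if t[i] > last:
                keep.append(i)
                last = t[i]
            else:
                logger.warning("lenient mode: dropping row %d (time_s=%r not increasing)", i, t[i])
        trace = trace.iloc[keep].reset_index(drop=True)

    if (trace["do_mgl"].to_numpy() < 0).any():
        idx = int((trace["do_mgl"].to_numpy() < 0).nonzero()[0][0])
        raise ValidationError(f"do_mgl < 0 at row {idx}")
    temp = trace["temp_c"].to_numpy()
    if ((temp <= 0) | (temp >= 45)).any():
        idx = int(((temp <= 0) | (temp >= 45)).nonzero()[0][0])
        raise ValidationError(f"temp_c outside (0, 45) at row {idx}: {temp[idx]!r}")
    pump = trace["pump_on"].to_numpy()
    if not set(pd.unique(pump)) <= {0, 1}:
        raise ValidationError("pump_on must be 0 or 1")
    return trace


_SIDECAR_FISH_KEYS = ("fish_id", "mass_g", "tl_cm", "habitat", "acclim_temp_c", "acclim_days")
_SIDECAR_CHAMBER_KEYS = ("chamber_id", "system_volume_l", "basin_do_pct_sat")


def sidecar_path(path: Path | str) -> Path:
    return Path(path).with_suffix("").with_suffix(".meta.yaml")


def read_trace(path: Path | str, lenient: bool = False) -> TrialRecord:
    """Read a trace CSV plus its ``.meta.yaml`` sidecar into a TrialRecord."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such trace file: {path}")
    meta_path = sidecar_path(path)
    if not meta_path.exists():
        raise FormatError(f"metadata sidecar not found: {meta_path}")

    # round_trip parsing keeps read∘write the identity on canonical files
    trace = pd.read_csv(path, float_precision="round_trip")
    trace = validate_trace(trace, lenient=lenient)

    with open(meta_path, encoding="utf-8") as fh:
        meta = yaml.safe_load(fh) or {}
    if "trial_type" not in meta:
        raise FormatError(f"sidecar {meta_path} is missing 'trial_type'")
    trial_type = meta["trial_type"]
    if trial_type not in ("acclimation", "rmr", "mmr", "background_pre", "background_post", "ctmax"):
        raise ValidationError(f"unknown trial_type token {trial_type!r} in {meta_path}")
    try:
        chamber = ChamberMeta(**{k: meta[k] for k in _SIDECAR_CHAMBER_KEYS if k in meta})
        fish = None
        if meta.get("fish_id") is not None:
            fish = FishMeta(**{k: meta[k] for k in _SIDECAR_FISH_KEYS if k in meta})
    except _PydanticValidationError as exc:
        raise ValidationError(f"invalid sidecar {meta_path}: {exc}") from exc

    known = set(_SIDECAR_FISH_KEYS) | set(_SIDECAR_CHAMBER_KEYS) | {"trial_type"}
    extras = {k: v for k, v in meta.items() if k not in known}
    return TrialRecord(trial_type=trial_type, chamber=chamber, trace=trace, fish=fish, extras=extras)


def write_trace(trial: TrialRecord, path: Path | str) -> None:
    """Write the canonical CSV + sidecar pair; lossless for declared fields."""
    path = Path(path)
    validate_trace(trial.trace)
    path.parent.mkdir(parents=True, exist_ok=True)
    trial.trace.to_csv(path, index=False, lineterminator="\n")

    meta: dict[str, Any] = {"trial_type": trial.trial_type}
    meta.update(trial.chamber.model_dump())
    if trial.fish is not None:
        meta.update(trial.fish.model_dump())
    meta.update(trial.extras)
    with open(sidecar_path(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_trial_dir(directory: Path | str, lenient: bool = False) -> list[TrialRecord]:
    """Read every ``*.csv`` trace (with sidecar) under a directory."""
    directory = Path(directory)
    trials = []
    for csv in sorted(directory.glob("*.csv")):
        if csv.name.endswith(".meta.csv"):
            continue
        trials.append(read_trace(csv, lenient=lenient))
    return trials
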