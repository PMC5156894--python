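"""Critical thermal maximum (CTmax) trial analysis.

A CTmax trial heats the tank at a nominal 1 °C per 3 min after a recovery
hold; the endpoint is loss of equilibrium (LOE), an operator-recorded event
time. CTmax is the water temperature at the LOE instant, linearly
interpolated between the bracketing 90 s log samples. The realized heating
rate is the OLS slope of temperature on time over the ramp window only
(hold excluded), in °C min^-1.

The acclimation response — the slope of CTmax on acclimation temperature —
is the cohort-level summary: a slope of 1 would mean thermal limits shift
one-for-one with acclimation; fishes typically show 0.3–0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import EstimationError, ValidationError
from .io import FishMeta


@dataclass
class CTmaxTrial:
    """A thermal-ramp log with its operator-recorded LOE time."""

    fish: FishMeta
    log: pd.DataFrame  # columns time_s, temp_c, do_mgl
    loe_time_s: float
    ramp_start_s: float = 0.0

    def __post_init__(self) -> None:
        t = self.log["time_s"].to_numpy()
        if len(t) < 2:
            raise ValidationError("CTmax log needs >= 2 samples")
        if not (t[0] <= self.loe_time_s <= t[-1]):
            raise ValidationError(
                f"loe_time_s {self.loe_time_s} outside log span [{t[0]}, {t[-1]}]"
            )
        if self.loe_time_s <= self.ramp_start_s:
            raise ValidationError("loss of equilibrium precedes ramp start")
        ramp = self.log[(self.log["time_s"] >= self.ramp_start_s)]
        if len(ramp) >= 3:
            slope = sps.linregress(ramp["time_s"], ramp["temp_c"]).slope
            if slope < 0:
                raise ValidationError("temperature decreases on average over the ramp")


@dataclass(frozen=True)
class CTmaxResult:
    ctmax_c: float
    heating_rate_c_per_min: float
    fish: FishMeta


@dataclass(frozen=True)
class AcclimationFit:
    """OLS fit of CTmax on acclimation temperature across a cohort."""

    slope: float  # °C CTmax per °C acclimation
    se_slope: float
    intercept: float
    n: int
    ci95: tuple[float, float]
    treatment_means: pd.DataFrame  # acclim_temp_c, mean, sem, n

    def summary(self) -> str:
        lines = [
            f"CTmax acclimation response: slope = {self.slope:.3f} "
            f"± {self.se_slope:.3f} (95% CI {self.ci95[0]:.3f}–{self.ci95[1]:.3f}), "
            f"n = {self.n}",
        ]
        for _, row in self.treatment_means.iterrows():
            lines.append(
                f"  {row['acclim_temp_c']:.1f} °C: CTmax {row['mean']:.2f} "
                f"± {row['sem']:.2f} °C (n={int(row['n'])})"
            )
        return "\n".join(lines)


def heating_rate(trial: CTmaxTrial) -> float:
    """Realized ramp rate, °C min^-1, from ramp start to LOE."""
    window = trial.log[
        (trial.log["time_s"] >= trial.ramp_start_s)
        & (trial.log["time_s"] <= trial.loe_time_s)
    ]
    if len(window) < 3:
        raise EstimationError(
            f"heating rate needs >= 3 log points in the ramp window, got {len(window)}"
        )
    res = sps.linregress(window["time_s"], window["temp_c"])
    return float(res.slope) * 60.0


def extract_ctmax(trial: CTmaxTrial) -> CTmaxResult:
    """Temperature at loss of equilibrium, interpolated between log samples."""
    t = trial.log["time_s"].to_numpy(dtype=float)
    temp = trial.log["temp_c"].to_numpy(dtype=float)
    ctmax = float(np.interp(trial.loe_time_s, t, temp))
    return CTmaxResult(
        ctmax_c=ctmax,
        heating_rate_c_per_min=heating_rate(trial),
        fish=trial.fish,
    )


def acclimation_response(results: Sequence[CTmaxResult]) -> AcclimationFit:
    """Slope (± SE) of CTmax on acclimation temperature, plus treatment means."""
    temps = np.array([r.fish.acclim_temp_c for r in results], dtype=float)
    ct = np.array([r.ctmax_c for r in results], dtype=float)
    if len(np.unique(temps)) < 2:
        raise EstimationError("acclimation response needs >= 2 distinct acclimation temperatures")
    res = sm.OLS(ct, sm.add_constant(temps)).fit()
    lo, hi = res.conf_int(alpha=0.05)[1]
    df = pd.DataFrame({"acclim_temp_c": temps, "ctmax_c": ct})
    means = (
        df.groupby("acclim_temp_c")["ctmax_c"]
        .agg(mean="mean", sem="sem", n="count")
        .reset_index()
    )
    return AcclimationFit(
        slope=float(res.params[1]),
        se_slope=float(res.bse[1]),
        intercept=float(res.params[0]),
        n=len(ct),
        ci95=(float(lo), float(hi)),
        treatment_means=means,
    )


def ctmax_frame(results: Sequence[CTmaxResult]) -> pd.DataFrame:
    """Per-fish CTmax table for the statistics layer."""
    return pd.DataFrame(
        {
            "fish_id": [r.fish.fish_id for r in results],
            "habitat": [r.fish.habitat for r in results],
            "acclim_temp_c": [r.fish.acclim_temp_c for r in results],
            "mass_g": [r.fish.mass_g for r in results],
            "tl_cm": [r.fish.tl_cm for r in results],
            "acclim_days": [r.fish.acclim_days for r in results],
            "ctmax_c": [r.ctmax_c for r in results],
            "heating_rate_c_per_min": [r.heating_rate_c_per_min for r in results],
        }
    )
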