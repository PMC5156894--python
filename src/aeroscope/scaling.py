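"""Allometric scaling, mass adjustment, and the Q10 temperature coefficient.

Metabolic rate scales with body mass as rate = a * mass^b; ``b`` is
estimated as the OLS slope of log10(absolute rate, mg min^-1) on
log10(mass, kg). Mass-specific rates are brought to a common body mass via

    MO2_adj = mean_mass^(b-1) * observed_mass^(1-b) * MO2_observed,

which is exact when the cohort follows the power law with exponent ``b``
(the residual mass dependence of a mass-specific rate is mass^(b-1)).

Q10 — the factor by which a rate changes per 10 °C — uses the van't Hoff
form (rate2/rate1)^(10/(T2-T1)). A "literal product" form
(rate2/rate1) * (10/(T2-T1)) is available for audit only: it is not a
temperature coefficient (it is not 1 for equal rates unless the interval is
exactly 10 °C) and is inconsistent with any published Q10 over a non-10 °C
interval, but mirrors how the expression is sometimes typeset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import EstimationError, ValidationError


@dataclass(frozen=True)
class ScalingFit:
    """Result of a log10(rate) ~ log10(mass) regression."""

    rate_type: str
    b: float
    intercept: float  # log10 rate at 1 kg
    se_b: float
    n: int
    r2: float

    def predict_log10(self, mass_kg: np.ndarray) -> np.ndarray:
        return self.intercept + self.b * np.log10(mass_kg)

    def summary(self) -> str:
        return (
            f"Allometric scaling ({self.rate_type}): b = {self.b:.4f} "
            f"(SE {self.se_b:.4f}), intercept = {self.intercept:.4f}, "
            f"n = {self.n}, r2 = {self.r2:.4f}"
        )


@dataclass(frozen=True)
class Q10Result:
    t1_c: float
    t2_c: float
    rate1: float
    rate2: float
    q10: float
    form: str = "vant_hoff"


def estimate_scaling_exponent(
    mass_kg: Sequence[float],
    rate_abs: Sequence[float],
    rate_type: str = "rmr",
) -> ScalingFit:
    """OLS fit of log10 absolute rate on log10 body mass."""
    mass = np.asarray(mass_kg, dtype=float)
    rate = np.asarray(rate_abs, dtype=float)
    ok = np.isfinite(mass) & np.isfinite(rate)
    mass, rate = mass[ok], rate[ok]
    if len(mass) < 3:
        raise EstimationError(f"scaling fit needs >= 3 fish, got {len(mass)}")
    if (mass <= 0).any() or (rate <= 0).any():
        raise ValidationError("scaling fit requires positive masses and rates")
    x = np.log10(mass)
    if np.ptp(x) == 0:
        raise EstimationError("all fish have identical mass: zero covariate variance")
    res = sm.OLS(np.log10(rate), sm.add_constant(x)).fit()
    return ScalingFit(
        rate_type=rate_type,
        b=float(res.params[1]),
        intercept=float(res.params[0]),
        se_b=float(res.bse[1]),
        n=len(mass),
        r2=float(res.rsquared),
    )


def mass_adjust(
    observed_mass_specific: float | np.ndarray,
    observed_mass_kg: float | np.ndarray,
    mean_mass_kg: float,
    b: float,
) -> float | np.ndarray:
    """Adjust a mass-specific rate to a common body mass.

    Identities: observed_mass == mean_mass gives the observed rate for any
    b, and b == 1 gives the observed rate for any masses.
    """
    m = np.asarray(observed_mass_kg, dtype=float)
    r = np.asarray(observed_mass_specific, dtype=float)
    if mean_mass_kg <= 0 or (m <= 0).any():
        raise ValidationError("masses must be positive")
    if (r < 0).any():
        raise ValidationError("rates must be non-negative")
    out = mean_mass_kg ** (b - 1.0) * m ** (1.0 - b) * r
    return float(out) if np.isscalar(observed_mass_specific) else out


def q10(
    rate1: float,
    rate2: float,
    t1_c: float,
    t2_c: float,
    form: str = "vant_hoff",
) -> Q10Result:
    """Temperature coefficient between mass-adjusted mean rates.

    ``vant_hoff`` (default): (rate2/rate1)^(10/(t2-t1)).
    ``literal_printed``: (rate2/rate1)*(10/(t2-t1)), audit only.
    """
    if rate1 <= 0 or rate2 <= 0:
        raise ValidationError("rates must be positive")
    if t1_c == t2_c:
        raise ValidationError("q10 undefined for t1 == t2")
    ratio = rate2 / rate1
    exponent = 10.0 / (t2_c - t1_c)
    if form == "vant_hoff":
        value = ratio**exponent
    elif form == "literal_printed":
        value = ratio * exponent
    else:
        raise ValidationError(f"unknown q10 form {form!r}")
    return Q10Result(t1_c, t2_c, rate1, rate2, float(value), form=form)


def cohort_mean_mass_kg(mass_kg: Sequence[float]) -> float:
    """Arithmetic mean mass of the analyzed cohort (per rate type)."""
    return float(np.mean(np.asarray(mass_kg, dtype=float)))


def q10_table(
    summaries: pd.DataFrame,
    rate_col: str,
    b: float,
    temp_col: str = "acclim_temp_c",
    mass_col: str = "mass_kg",
    pairs: Optional[Sequence[tuple[float, float]]] = None,
    form: str = "vant_hoff",
) -> pd.DataFrame:
    """Q10 between temperature treatments from mass-adjusted treatment means.

    Rates are first adjusted to the analyzed cohort's mean mass with
    exponent ``b``; means pool habitats within each treatment (one Q10 per
    interval, weighted by fish count through the pooled mean).
    """
    df = summaries.dropna(subset=[rate_col, mass_col]).copy()
    mean_mass = cohort_mean_mass_kg(df[mass_col])
    df["_adj"] = mass_adjust(df[rate_col].to_numpy(), df[mass_col].to_numpy(), mean_mass, b)
    means = df.groupby(temp_col)["_adj"].agg(["mean", "count"])
    temps = sorted(means.index)
    if pairs is None:
        pairs = [(t1, t2) for i, t1 in enumerate(temps) for t2 in temps[i + 1 :]]
    rows = []
    for t1, t2 in pairs:
        res = q10(means.loc[t1, "mean"], means.loc[t2, "mean"], t1, t2, form=form)
        rows.append(
            {
                "rate_type": rate_col,
                "t1_c": t1,
                "t2_c": t2,
                "rate1_adj": res.rate1,
                "rate2_adj": res.rate2,
                "q10": res.q10,
                "form": form,
                "n1": int(means.loc[t1, "count"]),
                "n2": int(means.loc[t2, "count"]),
                "mean_mass_kg": mean_mass,
                "b": b,
            }
        )
    return pd.DataFrame(rows)
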