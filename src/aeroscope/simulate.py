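"""Synthetic trial generators with embedded ground truth.

Every input the pipeline consumes can be generated here with known truth,
so each stage is verifiable by parameter recovery without external data.

``simulate_trace`` integrates a two-circuit chamber: during sealed
(measure) phases the dissolved-oxygen balance is

    dDO/dt = -(MO2_fish + MO2_background(t)) / 60 / V_eff,

with V_eff the system volume minus the fish's displacement; during flush
phases a first-order washout term ``k * (DO_basin - DO)`` is added.
Integration is explicit Euler at an internal step no larger than 1 s
(adequate: the dynamics are first-order and slow), subsampled to the
logging cadence, with Gaussian sensor noise added to the *observed* series.

``simulate_cohort`` draws a juvenile cohort with log-uniform masses,
power-law allometry (exponent ``b_true``), exponential Q10 temperature
dependence, a multiplicative habitat offset, and lognormal individual
variation; ``simulate_ctmax_cohort`` draws thermal-ramp trials whose true
loss-of-equilibrium temperature responds linearly to acclimation
temperature.

All generators are deterministic given (config, seed); the PRNG is numpy's
PCG64, recorded in the output truth tables.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import SimulationError, ValidationError
from .io import ChamberMeta, FishMeta, TrialRecord
from .ctmax import CTmaxTrial


class TraceSimConfig(BaseModel):
    """One chamber occupancy. Defaults emulate the field protocol: 10-min
    sealed measurements alternating with 15-min flushes."""

    model_config = ConfigDict(extra="forbid")

    true_mo2_mg_min: float = Field(ge=0)  # 0 for blank (background) runs
    bg_rate_pre_mg_min: float = Field(default=0.0, ge=0)
    bg_rate_post_mg_min: float = Field(default=0.0, ge=0)
    system_volume_l: float = Field(default=1.0, gt=0)
    basin_do_mgl: float = Field(default=7.0, gt=0)
    flush_exchange_rate_per_s: float = Field(default=0.02, gt=0)
    cycle: list[tuple[float, float]] = Field(
        default_factory=lambda: [(600.0, 900.0)] * 4
    )  # (measure_s, flush_s)
    initial_flush_s: float = Field(default=120.0, ge=0)
    noise_sd_mgl: float = Field(default=0.0, ge=0)
    sample_interval_s: float = Field(default=5.0, gt=0)
    temp_c: float = Field(default=25.5, gt=0, lt=45)
    fish_mass_g: float = Field(default=0.0, ge=0)
    seed: int = 0


def _bg_rate(cfg: TraceSimConfig, t: float, total: float) -> float:
    if total <= 0:
        return cfg.bg_rate_pre_mg_min
    frac = t / total
    return cfg.bg_rate_pre_mg_min + frac * (cfg.bg_rate_post_mg_min - cfg.bg_rate_pre_mg_min)


def simulate_trace(
    cfg: TraceSimConfig,
    fish: Optional[FishMeta] = None,
    trial_type: str = "rmr",
    chamber_id: str = "ch1",
    rng: Optional[np.random.Generator] = None,
) -> TrialRecord:
    """Simulate one intermittent-flow trial; truth goes in the sidecar extras.

    ``fish`` supplies the displacement volume (falls back to
    ``cfg.fish_mass_g``); background trials pass ``fish=None`` and
    ``trial_type='background_pre'/'background_post'``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    mass_g = fish.mass_g if fish is not None else cfg.fish_mass_g
    v_eff = cfg.system_volume_l - mass_g / 1000.0
    if v_eff <= 0:
        raise SimulationError("fish displaces the whole system volume")

    # phase schedule: optional initial flush, then (measure, flush) pairs
    phases: list[tuple[float, int]] = []  # (duration, pump_on)
    if cfg.initial_flush_s > 0:
        phases.append((cfg.initial_flush_s, 1))
    for measure_s, flush_s in cfg.cycle:
        phases.append((measure_s, 0))
        if flush_s > 0:
            phases.append((flush_s, 1))
    total = sum(d for d, _ in phases)

    dt = min(1.0, cfg.sample_interval_s)
    n = int(round(total / dt)) + 1
    t = np.arange(n) * dt
    pump = np.zeros(n, dtype=int)
    edge = 0.0
    for dur, state in phases:
        sel = (t >= edge - 1e-9) & (t < edge + dur - 1e-9)
        pump[sel] = state
        edge += dur
    pump[-1] = phases[-1][1]

    do = np.empty(n)
    do[0] = cfg.basin_do_mgl
    consumption = cfg.true_mo2_mg_min  # fish only; background added per-step
    for i in range(1, n):
        ti = t[i - 1]
        rate = -(consumption + _bg_rate(cfg, ti, total)) / 60.0 / v_eff
        if pump[i - 1] == 1:
            rate += cfg.flush_exchange_rate_per_s * (cfg.basin_do_mgl - do[i - 1])
        do[i] = do[i - 1] + dt * rate
        if do[i] < 0:
            raise SimulationError(
                "simulated DO fell below 0; shorten measure phases or lower true_mo2"
            )

    # subsample to the logging cadence, then add sensor noise to the readings
    step = max(1, int(round(cfg.sample_interval_s / dt)))
    idx = np.arange(0, n, step)
    do_obs = do[idx] + rng.normal(0.0, cfg.noise_sd_mgl, size=len(idx))
    trace = pd.DataFrame(
        {
            "time_s": t[idx],
            "do_mgl": np.clip(do_obs, 0.0, None),
            "temp_c": np.full(len(idx), cfg.temp_c),
            "pump_on": pump[idx],
        }
    )
    chamber = ChamberMeta(chamber_id=chamber_id, system_volume_l=cfg.system_volume_l)
    truth = {
        "truth_mo2_mg_min": cfg.true_mo2_mg_min,
        "truth_bg_pre_mg_min": cfg.bg_rate_pre_mg_min,
        "truth_bg_post_mg_min": cfg.bg_rate_post_mg_min,
        "rng": "numpy PCG64",
    }
    return TrialRecord(
        trial_type=trial_type, chamber=chamber, trace=trace, fish=fish, extras=truth
    )


class CohortSimConfig(BaseModel):
    """A juvenile cohort spread over temperature treatments and habitats.

    Defaults emulate the study conditions: 34 fish, masses log-uniform on
    2.4–53.7 g, RMR scaling exponent 0.85, RMR Q10 1.6 referenced to
    25.5 °C, a 0.9 multiplicative habitat offset (lower rates in the
    low-oxygen wetland habitat), MMR at 2.2x RMR, and 15% lognormal
    individual variation. ``a_rmr_mg_min`` (2.0) is the absolute RMR of a
    1 kg fish at the reference temperature, which puts a 17 g fish near
    3.7 mg min^-1 kg^-1.

    ``q10_mmr`` defaults to None, meaning MMR couples to the fish's
    realized RMR (shared Q10 and individual variation); setting it decouples
    MMR onto its own deterministic kernel with independent noise.
    """

    model_config = ConfigDict(extra="forbid")

    n_fish: int = Field(default=34, ge=1)
    mass_range_g: tuple[float, float] = (2.4, 53.7)
    a_rmr_mg_min: float = Field(default=2.0, gt=0)
    b_true: float = 0.85
    q10_true: float = Field(default=1.6, gt=0)
    q10_mmr: Optional[float] = Field(default=None, gt=0)
    t_ref_c: float = 25.5
    habitat_offset: float = Field(default=0.9, gt=0)  # miscanthidium multiplier
    mmr_multiplier: float = Field(default=2.2, gt=1)
    cv_lognormal: float = Field(default=0.15, ge=0)
    acclim_max_factor: float = Field(default=1.5, gt=0)  # acclimation max / RMR
    trace_noise_sd_mgl: float = Field(default=0.0, ge=0)
    bg_rate_mg_min: float = Field(default=0.0, ge=0)  # blank-chamber rate for traces
    treatments: tuple[float, ...] = (25.5, 27.5, 29.5, 31.5)
    acclim_days_range: tuple[float, float] = (3.0, 12.0)
    seed: int = 0


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-median multiplicative noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def simulate_cohort(cfg: CohortSimConfig, make_traces: bool = False) -> "CohortSim":
    """Draw a cohort; optionally render each fish's trials as traces.

    The truth table carries one row per fish with the generating rates in
    absolute (mg min^-1) and mass-specific (mg min^-1 kg^-1) units.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_fish
    lo, hi = cfg.mass_range_g
    mass_g = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    mass_kg = mass_g / 1000.0
    # habitat x treatment cells filled round-robin so the design stays as
    # balanced as n allows, then the assignment order is permuted jointly
    cells = [
        (h, t)
        for t in cfg.treatments
        for h in ("forest", "miscanthidium")
    ]
    assign = [cells[i % len(cells)] for i in range(n)]
    order = rng.permutation(n)
    habitat = np.array([assign[i][0] for i in order])
    temps = np.array([assign[i][1] for i in order])
    acclim_days = rng.uniform(*cfg.acclim_days_range, size=n).round(0)

    hab_mult = np.where(habitat == "miscanthidium", cfg.habitat_offset, 1.0)
    rmr_det = (
        cfg.a_rmr_mg_min
        * mass_kg**cfg.b_true
        * cfg.q10_true ** ((temps - cfg.t_ref_c) / 10.0)
        * hab_mult
    )
    rmr_abs = rmr_det * _lognormal_factor(rng, cfg.cv_lognormal, n)
    if cfg.q10_mmr is None:
        mmr_abs = cfg.mmr_multiplier * rmr_abs * _lognormal_factor(rng, cfg.cv_lognormal, n)
    else:
        mmr_det = (
            cfg.mmr_multiplier
            * cfg.a_rmr_mg_min
            * mass_kg**cfg.b_true
            * cfg.q10_mmr ** ((temps - cfg.t_ref_c) / 10.0)
            * hab_mult
        )
        mmr_abs = mmr_det * _lognormal_factor(rng, cfg.cv_lognormal, n)

    truth = pd.DataFrame(
        {
            "fish_id": [f"f{i:03d}" for i in range(n)],
            "mass_g": mass_g,
            "mass_kg": mass_kg,
            "tl_cm": (mass_g / 0.01) ** (1 / 3.0),  # crude length-weight shape
            "habitat": habitat,
            "acclim_temp_c": temps,
            "acclim_days": acclim_days,
            "rmr_abs_mg_min": rmr_abs,
            "mmr_abs_mg_min": mmr_abs,
            "rmr_ms": rmr_abs / mass_kg,
            "mmr_ms": mmr_abs / mass_kg,
            "acclim_max_ms": cfg.acclim_max_factor * rmr_abs / mass_kg,
        }
    )
    truth.attrs["rng"] = "numpy PCG64"
    truth.attrs["config"] = cfg.model_dump()

    trials: list[TrialRecord] = []
    if make_traces:
        for i, row in truth.iterrows():
            fish = FishMeta(
                fish_id=row["fish_id"],
                mass_g=row["mass_g"],
                tl_cm=row["tl_cm"],
                habitat=row["habitat"],
                acclim_temp_c=row["acclim_temp_c"],
                acclim_days=row["acclim_days"],
            )
            vol = max(1.0, 2.0 * row["mass_g"] / 1000.0)
            chamber_id = f"ch{i % 4}"
            for trial_type, mo2 in (("rmr", row["rmr_abs_mg_min"]), ("mmr", row["mmr_abs_mg_min"])):
                tc = TraceSimConfig(
                    true_mo2_mg_min=mo2,
                    bg_rate_pre_mg_min=cfg.bg_rate_mg_min,
                    bg_rate_post_mg_min=cfg.bg_rate_mg_min,
                    system_volume_l=vol,
                    temp_c=row["acclim_temp_c"],
                    fish_mass_g=row["mass_g"],
                    noise_sd_mgl=cfg.trace_noise_sd_mgl,
                    seed=int(rng.integers(2**31 - 1)),
                )
                trial = simulate_trace(tc, fish=fish, trial_type=trial_type, chamber_id=chamber_id)
                trial.extras["acclim_max_ms"] = float(row["acclim_max_ms"])
                trials.append(trial)
            if cfg.bg_rate_mg_min > 0:
                for bg_type in ("background_pre", "background_post"):
                    tc = TraceSimConfig(
                        true_mo2_mg_min=0.0,
                        bg_rate_pre_mg_min=cfg.bg_rate_mg_min,
                        bg_rate_post_mg_min=cfg.bg_rate_mg_min,
                        system_volume_l=vol,
                        temp_c=row["acclim_temp_c"],
                        cycle=[(1500.0, 0.0)],
                        initial_flush_s=0.0,
                        noise_sd_mgl=cfg.trace_noise_sd_mgl,
                        seed=int(rng.integers(2**31 - 1)),
                    )
                    bg_trial = simulate_trace(tc, fish=None, trial_type=bg_type, chamber_id=chamber_id)
                    bg_trial.extras["fish_id_link"] = row["fish_id"]
                    trials.append(bg_trial)
    return CohortSim(truth=truth, trials=trials, config=cfg)


class CohortSim:
    def __init__(self, truth: pd.DataFrame, trials: list[TrialRecord], config: CohortSimConfig):
        self.truth = truth
        self.trials = trials
        self.config = config


class CTmaxSimConfig(BaseModel):
    """CTmax ramp trials with a linear acclimation response.

    Defaults emulate the study: slope 0.30 °C CTmax per °C acclimation,
    residual SD 0.8 °C, ramp 0.333 °C min^-1, 90 s logging, treatments
    25.5/27.5/29.5 °C. The intercept (30.3 °C) centres mean CTmax near
    38.6 °C at the middle treatment.
    """

    model_config = ConfigDict(extra="forbid")

    n_per_treatment: int = Field(default=12, ge=1)
    intercept_c: float = 30.3
    slope_per_c: float = 0.30
    sd_c: float = Field(default=0.8, ge=0)
    ramp_rate_c_per_min: float = Field(default=1.0 / 3.0, gt=0)
    log_interval_s: float = Field(default=90.0, gt=0)
    hold_s: float = Field(default=600.0, ge=0)
    treatments: tuple[float, ...] = (25.5, 27.5, 29.5)
    seed: int = 0


def simulate_ctmax_cohort(cfg: CTmaxSimConfig, n_total: Optional[int] = None) -> tuple[list[CTmaxTrial], pd.DataFrame]:
    """Generate ramp trials; returns (trials, truth table).

    ``n_total`` caps the cohort size (treatments filled round-robin);
    default is ``n_per_treatment`` per treatment.
    """
    rng = np.random.default_rng(cfg.seed)
    alloc: list[float] = []
    if n_total is None:
        for tr in cfg.treatments:
            alloc += [tr] * cfg.n_per_treatment
    else:
        alloc = [cfg.treatments[i % len(cfg.treatments)] for i in range(n_total)]

    trials: list[CTmaxTrial] = []
    rows = []
    for i, t_acc in enumerate(alloc):
        true_ct = cfg.intercept_c + cfg.slope_per_c * t_acc + rng.normal(0.0, cfg.sd_c)
        if true_ct <= t_acc:
            true_ct = t_acc + 0.5  # floor: LOE cannot precede heating
        rate_per_s = cfg.ramp_rate_c_per_min / 60.0
        loe = cfg.hold_s + (true_ct - t_acc) / rate_per_s
        t_end = loe + 2 * cfg.log_interval_s
        times = np.arange(0.0, t_end + cfg.log_interval_s, cfg.log_interval_s)
        temps = np.where(
            times <= cfg.hold_s, t_acc, t_acc + (times - cfg.hold_s) * rate_per_s
        )
        mass_g = float(np.exp(rng.uniform(np.log(2.6), np.log(113.2))))
        fish = FishMeta(
            fish_id=f"ct{i:03d}",
            mass_g=mass_g,
            tl_cm=(mass_g / 0.01) ** (1 / 3.0),
            habitat=("forest", "miscanthidium")[i % 2],
            acclim_temp_c=t_acc,
            acclim_days=float(rng.integers(3, 14)),
        )
        log = pd.DataFrame(
            {"time_s": times, "temp_c": temps, "do_mgl": np.full(len(times), 7.0)}
        )
        trials.append(CTmaxTrial(fish=fish, log=log, loe_time_s=loe, ramp_start_s=cfg.hold_s))
        rows.append(
            {
                "fish_id": fish.fish_id,
                "habitat": fish.habitat,
                "acclim_temp_c": t_acc,
                "true_ctmax_c": true_ct,
                "loe_time_s": loe,
            }
        )
    truth = pd.DataFrame(rows)
    truth.attrs["rng"] = "numpy PCG64"
    truth.attrs["config"] = cfg.model_dump()
    return trials, truth
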