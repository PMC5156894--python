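"""Intermittent-flow respirometry reduction.

The chain runs: ``segment_phases`` (pump-state run-length segmentation) →
``trim_segment`` (drop the first and last minute of each sealed phase) →
``fit_slope`` (OLS decline of dissolved oxygen on time) → ``compute_mo2``
(convert to an absolute oxygen-consumption rate, correcting the system
volume for the fish's own volume at 1 kg l^-1) → ``correct_background``
(subtract microbial respiration of the empty system, constant or drifting
linearly between the pre- and post-trial blanks) → ``summarize_rmr`` /
``summarize_mmr`` / ``aerobic_scope``.

Rates are in mg O2 min^-1 (absolute) or mg min^-1 kg^-1 (mass-specific).

The resting rate (RMR) is the mean of the usable sealed-phase measurements
after an iterative 25%-of-RMR background filter: the filter threshold
depends on RMR, and RMR is the mean of the records that survive the filter,
so the definition is a fixed point. We iterate — compute a provisional RMR
from the current usable set, drop records whose background exceeds the
threshold fraction of it, recompute — until the set is stable; the usable
set only ever shrinks, so termination is guaranteed.

The maximal rate (MMR) is the single highest post-chase measurement and is
excluded outright when it fails to exceed the fish's maximal rate during
chamber acclimation (a chase that did not elevate metabolism above routine
activity did not measure a maximum). Ties are broken by the earliest
segment, which is also where the true maximum is expected immediately after
a chase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EstimationError, ValidationError
from .io import ChamberMeta, FishMeta, TrialRecord

# QC flag tokens carried on MO2Record.flags
FLAG_BG_EXCEEDS = "bg_exceeds_25pct"
FLAG_NEGATIVE = "negative_after_correction"
FLAG_LOW_R2 = "low_r2"


@dataclass
class MeasurementSegment:
    """A maximal sealed (pump off) run of trace samples."""

    segment_index: int
    t_start_s: float
    t_end_s: float
    samples: pd.DataFrame
    trimmed: bool = False
    usable: bool = True
    note: str = ""

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s

    @property
    def t_mid_s(self) -> float:
        return 0.5 * (self.t_start_s + self.t_end_s)


@dataclass(frozen=True)
class SlopeFit:
    """OLS slope of dissolved oxygen on time (signed, mg l^-1 s^-1)."""

    slope_mgl_per_s: float
    intercept_mgl: float
    r2: float
    n_points: int


@dataclass(frozen=True)
class BackgroundModel:
    """Background (microbial) respiration of the empty system, mg min^-1.

    ``linear_in_time`` interpolates (and extrapolates) through
    (t_pre, rate_pre) and (t_post, rate_post); ``constant`` ignores time.
    ``rate_at`` clips negative evaluations to zero — callers flag clamped
    records via ``raw_rate_at``.
    """

    mode: Literal["constant", "linear_in_time"]
    rate_pre: float
    rate_post: float
    t_pre_s: float = 0.0
    t_post_s: float = 1.0

    def raw_rate_at(self, t_s: float) -> float:
        if self.mode == "constant":
            return 0.5 * (self.rate_pre + self.rate_post)
        frac = (t_s - self.t_pre_s) / (self.t_post_s - self.t_pre_s)
        return self.rate_pre + frac * (self.rate_post - self.rate_pre)

    def rate_at(self, t_s: float) -> float:
        return max(0.0, self.raw_rate_at(t_s))


@dataclass
class MO2Record:
    """One sealed-phase oxygen-consumption measurement with QC state."""

    segment_index: int
    t_mid_s: float
    mo2_raw_mg_min: float
    mo2_corr_mg_min: float = np.nan
    mo2_mass_specific: float = np.nan
    bg_rate_mg_min: float = 0.0
    bg_fraction_of_rmr: float = np.nan
    r2: float = np.nan
    flags: set[str] = field(default_factory=set)


@dataclass
class RmrSummary:
    rmr: Optional[float]  # mg min^-1 kg^-1
    used: list[MO2Record]
    dropped: list[MO2Record]
    reason: Optional[str] = None
    n_iterations: int = 0


@dataclass
class MmrSummary:
    mmr: Optional[float]  # mg min^-1 kg^-1
    segment_index: Optional[int]
    excluded: bool = False
    reason: Optional[str] = None


@dataclass
class MetabolicSummary:
    """Per-fish endpoint: RMR, MMR, and aerobic scope."""

    fish: FishMeta
    rmr: Optional[float]
    mmr: Optional[float]
    as_abs: Optional[float]
    fas: Optional[float]
    n_rmr_measures_used: int
    rmr_reason: Optional[str] = None
    mmr_reason: Optional[str] = None


def segment_phases(trial: TrialRecord) -> list[MeasurementSegment]:
    """Split a trace into sealed measurement phases (maximal pump_on == 0 runs).

    Flush runs are discarded. An all-flush trace yields an empty list (the
    caller decides whether that is a problem).
    """
    trace = trial.trace
    pump = trace["pump_on"].to_numpy()
    t = trace["time_s"].to_numpy()
    segments: list[MeasurementSegment] = []
    # boundaries of runs: indices where value changes
    change = np.flatnonzero(np.diff(pump)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(pump)]))
    idx = 0
    for s, e in zip(starts, ends):
        if pump[s] != 0:
            continue
        samples = trace.iloc[s:e].reset_index(drop=True)
        segments.append(
            MeasurementSegment(
                segment_index=idx,
                t_start_s=float(t[s]),
                t_end_s=float(t[e - 1]),
                samples=samples,
            )
        )
        idx += 1
    return segments


def trim_segment(
    seg: MeasurementSegment, lead_s: float = 60.0, tail_s: float = 60.0
) -> MeasurementSegment:
    """Drop samples within ``lead_s`` of sealing and ``tail_s`` of reopening.

    The first minute after closing the valve still carries flush-water mixing
    and handling disturbance; the last minute may catch the operator
    re-opening. A segment too short to trim is returned flagged unusable
    rather than raising — downstream stages skip it.
    """
    if seg.duration_s <= lead_s + tail_s:
        return replace(
            seg,
            trimmed=True,
            usable=False,
            note=f"duration {seg.duration_s:.0f}s <= trims {lead_s + tail_s:.0f}s",
        )
    lo = seg.t_start_s + lead_s
    hi = seg.t_end_s - tail_s
    t = seg.samples["time_s"]
    kept = seg.samples[(t >= lo) & (t <= hi)].reset_index(drop=True)
    if len(kept) == 0:
        return replace(seg, trimmed=True, usable=False, note="no samples in trimmed window")
    return MeasurementSegment(
        segment_index=seg.segment_index,
        t_start_s=float(kept["time_s"].iloc[0]),
        t_end_s=float(kept["time_s"].iloc[-1]),
        samples=kept,
        trimmed=True,
        usable=True,
    )


def fit_slope(seg: MeasurementSegment) -> SlopeFit:
    """OLS slope of do_mgl on time_s over a (trimmed) segment.

    The sign is preserved here; the absolute value is taken only in the
    rate conversion, so a physically impossible rising trace remains
    visible to QC.
    """
    t = seg.samples["time_s"].to_numpy(dtype=float)
    y = seg.samples["do_mgl"].to_numpy(dtype=float)
    if len(t) < 3:
        raise EstimationError(f"segment {seg.segment_index}: need >= 3 samples, got {len(t)}")
    if np.ptp(t) == 0:
        raise EstimationError(f"segment {seg.segment_index}: zero time variance")
    res = sps.linregress(t, y)
    r2 = float(res.rvalue**2)
    if np.isnan(r2):  # constant DO: zero slope, define r2 = 0
        r2 = 0.0
    return SlopeFit(
        slope_mgl_per_s=float(res.slope),
        intercept_mgl=float(res.intercept),
        r2=r2,
        n_points=len(t),
    )


def compute_mo2(
    fit: SlopeFit,
    chamber: ChamberMeta,
    fish: Optional[FishMeta] = None,
    fish_density_kg_per_l: float = 1.0,
) -> float:
    """Convert a DO slope to an absolute rate: MO2 = |dDO/dt| * vol * 60.

    ``vol`` is the closed-system water volume minus the fish's displacement
    (mass / density, density 1 kg l^-1 by default). Background (empty
    chamber) reductions pass ``fish=None``.
    """
    vol = chamber.system_volume_l
    if fish is not None:
        vol = vol - fish.mass_kg / fish_density_kg_per_l
    if vol <= 0:
        raise ValidationError(
            f"effective volume {vol:.3g} l <= 0: fish larger than system "
            f"{chamber.chamber_id!r}"
        )
    return abs(fit.slope_mgl_per_s) * vol * 60.0


def reduce_trial(
    trial: TrialRecord,
    lead_trim_s: float = 60.0,
    tail_trim_s: float = 60.0,
    r2_threshold: float = 0.90,
    fish_density_kg_per_l: float = 1.0,
) -> list[MO2Record]:
    """Run segment → trim → slope → rate for every usable sealed phase."""
    records: list[MO2Record] = []
    for seg in segment_phases(trial):
        seg = trim_segment(seg, lead_trim_s, tail_trim_s)
        if not seg.usable or len(seg.samples) < 3:
            continue
        fit = fit_slope(seg)
        mo2 = compute_mo2(fit, trial.chamber, trial.fish, fish_density_kg_per_l)
        rec = MO2Record(
            segment_index=seg.segment_index,
            t_mid_s=seg.t_mid_s,
            mo2_raw_mg_min=mo2,
            r2=fit.r2,
        )
        if fit.r2 < r2_threshold:
            rec.flags.add(FLAG_LOW_R2)
        records.append(rec)
    return records


def _reduce_background_rate(
    trial: TrialRecord,
    lead_trim_s: float = 60.0,
    tail_trim_s: float = 60.0,
) -> float:
    """Reduce a blank trial to a single background rate (mg min^-1)."""
    records = reduce_trial(trial, lead_trim_s, tail_trim_s, r2_threshold=0.0)
    if not records:
        raise EstimationError("background trial has no usable measurement phase")
    # a blank is one long sealed measurement; average defensively if several
    return float(np.mean([r.mo2_raw_mg_min for r in records]))


def fit_background(
    pre: Optional[TrialRecord],
    post: Optional[TrialRecord] = None,
    mode: str = "auto",
    t_pre_s: float = 0.0,
    t_post_s: Optional[float] = None,
    lead_trim_s: float = 60.0,
    tail_trim_s: float = 60.0,
) -> BackgroundModel:
    """Fit the background model from pre- and post-trial blank runs.

    ``auto`` uses a linear-in-time model only when the background *increased*
    over the trial (microbial growth); a decrease is treated as measurement
    scatter and modelled as constant at the mean. A missing post blank falls
    back to constant at the pre rate.

    ``t_pre_s``/``t_post_s`` anchor the blanks on the fish trial's clock
    (pre at the start, post at the end of the trial span).
    """
    if pre is None and post is None:
        raise EstimationError("at least one background trial is required")
    rate_pre = _reduce_background_rate(pre, lead_trim_s, tail_trim_s) if pre else None
    rate_post = _reduce_background_rate(post, lead_trim_s, tail_trim_s) if post else None
    if rate_post is None:
        return BackgroundModel("constant", rate_pre, rate_pre)
    if rate_pre is None:
        return BackgroundModel("constant", rate_post, rate_post)

    if t_post_s is None:
        t_post_s = t_pre_s + 1.0
    if mode == "auto":
        mode = "linear_in_time" if rate_post > rate_pre else "constant"
    if mode == "linear_in_time" and t_post_s == t_pre_s:
        raise EstimationError("linear background needs distinct pre/post anchor times")
    return BackgroundModel(mode, rate_pre, rate_post, t_pre_s=t_pre_s, t_post_s=t_post_s)


def correct_background(rec: MO2Record, bg: Optional[BackgroundModel], t_mid_s: Optional[float] = None) -> MO2Record:
    """Subtract background at the segment's trimmed midpoint; clamp at zero.

    A corrected rate below zero is physically impossible; it is clamped to 0
    and the record flagged so the analyst can see it.
    """
    t = rec.t_mid_s if t_mid_s is None else t_mid_s
    if bg is None:
        rec.bg_rate_mg_min = 0.0
        rec.mo2_corr_mg_min = rec.mo2_raw_mg_min
        return rec
    raw_bg = bg.raw_rate_at(t)
    rate = max(0.0, raw_bg)
    if raw_bg < 0:
        rec.flags.add(FLAG_NEGATIVE + "_background")
    corr = rec.mo2_raw_mg_min - rate
    if corr < 0:
        rec.flags.add(FLAG_NEGATIVE)
        corr = 0.0
    rec.bg_rate_mg_min = rate
    rec.mo2_corr_mg_min = corr
    return rec


def mass_specific(rec: MO2Record, fish: FishMeta) -> MO2Record:
    rec.mo2_mass_specific = rec.mo2_corr_mg_min / fish.mass_kg
    return rec


def summarize_rmr(
    records: Sequence[MO2Record],
    fish: FishMeta,
    bg_frac_threshold: float = 0.25,
) -> RmrSummary:
    """Resting metabolic rate with the iterative 25%-of-RMR background filter.

    Records and background are compared in the same (absolute, mg min^-1)
    units: a record is rejected when its background rate exceeds
    ``bg_frac_threshold`` times the provisional absolute RMR. Records never
    re-enter once dropped, so the iteration terminates.
    """
    usable = [r for r in records if np.isfinite(r.mo2_corr_mg_min)]
    for r in usable:
        mass_specific(r, fish)
    if not usable:
        return RmrSummary(None, [], list(records), reason="no usable RMR measurements")

    dropped: list[MO2Record] = []
    n_iter = 0
    while True:
        n_iter += 1
        rmr_abs = float(np.mean([r.mo2_corr_mg_min for r in usable]))
        for r in usable:
            r.bg_fraction_of_rmr = (r.bg_rate_mg_min / rmr_abs) if rmr_abs > 0 else np.inf
        out = [r for r in usable if r.bg_fraction_of_rmr > bg_frac_threshold]
        if not out:
            break
        for r in out:
            r.flags.add(FLAG_BG_EXCEEDS)
        dropped.extend(out)
        usable = [r for r in usable if r not in out]
        if not usable:
            return RmrSummary(
                None, [], dropped + [r for r in records if r not in dropped],
                reason="all RMR measurements rejected by background filter",
                n_iterations=n_iter,
            )
    rmr = float(np.mean([r.mo2_mass_specific for r in usable]))
    return RmrSummary(rmr, usable, dropped, n_iterations=n_iter)


def summarize_mmr(
    records: Sequence[MO2Record],
    fish: FishMeta,
    acclimation_max: Optional[float] = None,
) -> MmrSummary:
    """Maximal metabolic rate: highest post-chase measurement.

    Excluded when it does not exceed ``acclimation_max`` (the fish's highest
    mass-specific rate during chamber acclimation): such a value cannot be a
    maximum. When no acclimation maximum is available the rule is skipped.
    Ties go to the earliest segment.
    """
    usable = [r for r in records if np.isfinite(r.mo2_corr_mg_min)]
    for r in usable:
        mass_specific(r, fish)
    if not usable:
        return MmrSummary(None, None, excluded=True, reason="no usable MMR measurements")
    best = usable[0]
    for r in usable[1:]:
        if r.mo2_mass_specific > best.mo2_mass_specific:
            best = r
    if acclimation_max is not None and best.mo2_mass_specific <= acclimation_max:
        return MmrSummary(
            None,
            best.segment_index,
            excluded=True,
            reason=(
                f"MMR {best.mo2_mass_specific:.3g} did not exceed acclimation "
                f"maximum {acclimation_max:.3g}"
            ),
        )
    return MmrSummary(float(best.mo2_mass_specific), best.segment_index)


def aerobic_scope(rmr: float, mmr: float) -> tuple[float, float]:
    """Absolute (MMR − RMR) and factorial (MMR / RMR) aerobic scope."""
    if rmr <= 0:
        raise ValidationError(f"rmr must be > 0, got {rmr!r}")
    return mmr - rmr, mmr / rmr


def summarize_fish(
    fish: FishMeta,
    rmr_records: Sequence[MO2Record],
    mmr_records: Sequence[MO2Record],
    acclimation_max: Optional[float] = None,
    bg_frac_threshold: float = 0.25,
) -> MetabolicSummary:
    """Combine RMR, MMR and aerobic scope into the per-fish endpoint."""
    rs = summarize_rmr(rmr_records, fish, bg_frac_threshold)
    ms = summarize_mmr(mmr_records, fish, acclimation_max)
    as_abs = fas = None
    if rs.rmr is not None and ms.mmr is not None:
        as_abs, fas = aerobic_scope(rs.rmr, ms.mmr)
    return MetabolicSummary(
        fish=fish,
        rmr=rs.rmr,
        mmr=ms.mmr,
        as_abs=as_abs,
        fas=fas,
        n_rmr_measures_used=len(rs.used),
        rmr_reason=rs.reason,
        mmr_reason=ms.reason,
    )
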