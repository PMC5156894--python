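"""End-to-end orchestration: reduce trials, summarize, compare, report.

``run_reduce`` executes the respirometry chain per fish and accounts for
every exclusion with exactly one reason code in the :class:`RunManifest`.
``run_report`` turns per-fish summaries (and CTmax results) into the report
tables: habitat x temperature rate means, ANCOVA term tables, Q10 tables,
adjusted means, and the CTmax ANOVA.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import respirometry as resp
from . import scaling, stats
from .config import RunConfig
from .ctmax import CTmaxResult, acclimation_response, ctmax_frame
from .errors import EstimationError, ValidationError
from .io import TrialRecord


@dataclass
class RunManifest:
    """Machine-readable account of a reduction run."""

    seed: int
    config: dict
    n_trials: int = 0
    n_fish: int = 0
    counts: dict = field(default_factory=dict)
    exclusions: list[dict] = field(default_factory=list)  # fish_id/record + one reason code

    def exclude(self, fish_id: str, reason_code: str, detail: str = "") -> None:
        self.exclusions.append({"fish_id": fish_id, "reason": reason_code, "detail": detail})

    def tally(self, key: str, n: int = 1) -> None:
        self.counts[key] = self.counts.get(key, 0) + n

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _group_trials(trials: Sequence[TrialRecord]):
    by_fish: dict[str, dict[str, TrialRecord]] = {}
    backgrounds: dict[str, dict[str, TrialRecord]] = {}
    for tr in trials:
        if tr.trial_type in ("background_pre", "background_post"):
            link = tr.extras.get("fish_id_link") or tr.chamber.chamber_id
            backgrounds.setdefault(str(link), {})[tr.trial_type] = tr
        else:
            by_fish.setdefault(tr.fish.fish_id, {})[tr.trial_type] = tr
    return by_fish, backgrounds


def run_reduce(
    trials: Sequence[TrialRecord],
    config: Optional[RunConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, RunManifest]:
    """Reduce a set of trials to per-segment records and per-fish summaries.

    Background blanks are matched to a fish by the ``fish_id_link`` sidecar
    key when present, otherwise by chamber. The acclimation maximum for the
    MMR exclusion rule comes from a reduced ``acclimation`` trial when one
    exists, else from an ``acclim_max_ms`` sidecar value, else the rule is
    skipped.
    """
    config = config or RunConfig()
    manifest = RunManifest(seed=config.seed, config=config.model_dump())
    manifest.n_trials = len(trials)
    by_fish, backgrounds = _group_trials(trials)
    manifest.n_fish = len(by_fish)

    record_rows = []
    summaries = []
    for fish_id, tset in sorted(by_fish.items()):
        anchor = tset.get("rmr") or tset.get("mmr")
        fish = anchor.fish

        bg_pair = backgrounds.get(fish_id) or backgrounds.get(anchor.chamber.chamber_id) or {}
        bg_model = None
        if bg_pair:
            span = max(t.duration_s for t in tset.values())
            bg_model = resp.fit_background(
                bg_pair.get("background_pre"),
                bg_pair.get("background_post"),
                mode=config.background_mode,
                t_pre_s=0.0,
                t_post_s=span,
                lead_trim_s=config.lead_trim_s,
                tail_trim_s=config.tail_trim_s,
            )

        def _records(trial):
            recs = resp.reduce_trial(
                trial,
                config.lead_trim_s,
                config.tail_trim_s,
                config.r2_threshold,
                config.fish_density_kg_per_l,
            )
            for r in recs:
                resp.correct_background(r, bg_model)
                resp.mass_specific(r, fish)
            return recs

        acclim_max = None
        if "acclimation" in tset:
            acc_recs = _records(tset["acclimation"])
            if acc_recs:
                acclim_max = max(r.mo2_mass_specific for r in acc_recs)
        elif "acclim_max_ms" in anchor.extras:
            acclim_max = float(anchor.extras["acclim_max_ms"])

        rmr_recs = _records(tset["rmr"]) if "rmr" in tset else []
        mmr_recs = _records(tset["mmr"]) if "mmr" in tset else []
        summary = resp.summarize_fish(
            fish, rmr_recs, mmr_recs,
            acclimation_max=acclim_max,
            bg_frac_threshold=config.bg_frac_threshold,
        )

        n_bg_rejected = sum(1 for r in rmr_recs if resp.FLAG_BG_EXCEEDS in r.flags)
        if n_bg_rejected:
            manifest.tally("rmr_records_bg_rejected", n_bg_rejected)
        if summary.rmr is None:
            code = (
                "rmr_all_bg_rejected"
                if summary.rmr_reason and "background" in summary.rmr_reason
                else "rmr_no_usable_measurements"
            )
            manifest.exclude(fish_id, code, summary.rmr_reason or "")
        if summary.mmr is None and "mmr" in tset:
            code = (
                "mmr_not_above_acclimation_max"
                if summary.mmr_reason and "acclimation" in (summary.mmr_reason or "")
                else "mmr_no_usable_measurements"
            )
            manifest.exclude(fish_id, code, summary.mmr_reason or "")

        for trial_type, recs in (("rmr", rmr_recs), ("mmr", mmr_recs)):
            for r in recs:
                record_rows.append(
                    {
                        "fish_id": fish_id,
                        "trial_type": trial_type,
                        "segment_index": r.segment_index,
                        "t_mid_s": r.t_mid_s,
                        "mo2_raw_mg_min": r.mo2_raw_mg_min,
                        "mo2_corr_mg_min": r.mo2_corr_mg_min,
                        "mo2_mass_specific": r.mo2_mass_specific,
                        "bg_rate_mg_min": r.bg_rate_mg_min,
                        "bg_fraction_of_rmr": r.bg_fraction_of_rmr,
                        "r2": r.r2,
                        "flags": "|".join(sorted(r.flags)),
                    }
                )
        summaries.append(
            {
                "fish_id": fish_id,
                "habitat": fish.habitat,
                "acclim_temp_c": fish.acclim_temp_c,
                "acclim_days": fish.acclim_days,
                "mass_g": fish.mass_g,
                "mass_kg": fish.mass_kg,
                "tl_cm": fish.tl_cm,
                "rmr": summary.rmr,
                "mmr": summary.mmr,
                "as_abs": summary.as_abs,
                "fas": summary.fas,
                "n_rmr_measures_used": summary.n_rmr_measures_used,
            }
        )

    records_df = pd.DataFrame(record_rows)
    summaries_df = pd.DataFrame(summaries)
    manifest.tally("fish_summarized", len(summaries_df))
    return records_df, summaries_df, manifest


# --------------------------------------------------------------------- report

RESPONSES = ("rmr", "mmr", "as_abs")


def _prep_stats_frame(summaries: pd.DataFrame, response: str) -> pd.DataFrame:
    df = summaries.dropna(subset=[response, "mass_kg"]).copy()
    df = df[df[response] > 0]
    df["log10_" + response] = np.log10(df[response] * df["mass_kg"])  # absolute rate
    df["log10_mass"] = np.log10(df["mass_kg"])
    return df


def run_report(
    summaries: pd.DataFrame,
    ctmax_results: Optional[Sequence[CTmaxResult]] = None,
    config: Optional[RunConfig] = None,
) -> dict[str, pd.DataFrame]:
    """Build the report tables from per-fish summaries (+ CTmax results).

    Returns a dict of DataFrames: ``rates_by_group`` (habitat x temperature
    means of RMR/MMR/AS), per-response ``ancova_*`` term tables and
    ``adjusted_means_*``, ``scaling``, ``q10``, and — when CTmax results are
    supplied — ``ctmax_summary``, ``ctmax_anova`` and ``ctmax_response``.
    """
    config = config or RunConfig()
    tables: dict[str, pd.DataFrame] = {}

    group = summaries.groupby(["habitat", "acclim_temp_c"])
    tables["rates_by_group"] = group[list(RESPONSES)].mean().round(2).reset_index()

    scaling_rows = []
    q10_frames = []
    for response in RESPONSES:
        df = _prep_stats_frame(summaries, response)
        if df["habitat"].nunique() < 2 or df["acclim_temp_c"].nunique() < 2:
            continue
        def _build(interactions):
            return stats.Ancova.from_columns(
                df,
                response="log10_" + response,
                factors=["habitat", "acclim_temp_c"],
                covariates=["log10_mass"],
                interactions=interactions,
                alpha=config.alpha,
                log10_response=True,
            )

        try:
            fit = _build(None).fit(reduce_interactions=True)
        except EstimationError:
            # too few fish per cell for the interaction: additive fallback
            try:
                fit = _build([]).fit(reduce_interactions=False)
                fit.notes.append("interaction dropped: insufficient residual df")
            except EstimationError:
                continue
        tables[f"ancova_{response}"] = fit.term_table()
        common_mass = float(df["log10_mass"].mean())
        am = fit.adjusted_means(at_covariates={"log10_mass": common_mass}, backtransform=True)
        am["common_mass_g"] = 10**common_mass * 1000.0
        tables[f"adjusted_means_{response}"] = am

        if response in ("rmr", "mmr"):
            sfit = scaling.estimate_scaling_exponent(
                df["mass_kg"], 10 ** df["log10_" + response], rate_type=response
            )
            scaling_rows.append(
                {"rate_type": response, "b": sfit.b, "se_b": sfit.se_b,
                 "intercept": sfit.intercept, "n": sfit.n, "r2": sfit.r2}
            )
            q10_frames.append(
                scaling.q10_table(df, rate_col=response, b=sfit.b)
            )
    if scaling_rows:
        tables["scaling"] = pd.DataFrame(scaling_rows)
    if q10_frames:
        tables["q10"] = pd.concat(q10_frames, ignore_index=True)

    if ctmax_results:
        ct = ctmax_frame(ctmax_results)
        tables["ctmax_summary"] = (
            ct.groupby(["habitat", "acclim_temp_c"])["ctmax_c"]
            .agg(mean="mean", sem="sem", n="count")
            .reset_index()
        )
        if ct["acclim_temp_c"].nunique() >= 2 and ct["habitat"].nunique() >= 2:
            fit = stats.ctmax_anova(ct, alpha=config.alpha)
            tables["ctmax_anova"] = fit.term_table()
        acc = acclimation_response(ctmax_results)
        tables["ctmax_response"] = pd.DataFrame(
            [{"slope": acc.slope, "se_slope": acc.se_slope,
              "ci95_lo": acc.ci95[0], "ci95_hi": acc.ci95[1],
              "intercept": acc.intercept, "n": acc.n}]
        )
        tables["ctmax_treatment_means"] = acc.treatment_means
    return tables


def write_tables(tables: dict[str, pd.DataFrame], out_dir) -> list[str]:
    """Write each table as ``<name>.csv`` under out_dir; returns paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths.append(str(p))
    return paths
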