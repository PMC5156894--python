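import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aeroscope.errors import EstimationError, ValidationError
from aeroscope.io import ChamberMeta, FishMeta, TrialRecord
from aeroscope.respirometry import (
    FLAG_BG_EXCEEDS,
    FLAG_NEGATIVE,
    BackgroundModel,
    MO2Record,
    aerobic_scope,
    compute_mo2,
    correct_background,
    fit_background,
    fit_slope,
    segment_phases,
    summarize_mmr,
    summarize_rmr,
    trim_segment,
)

from conftest import make_blank_trial, make_segment, ols_slope_oracle


def trial_from_pump(pump, chamber=None):
    pump = np.asarray(pump, dtype=int)
    trace = pd.DataFrame(
        {
            "time_s": np.arange(len(pump), dtype=float),
            "do_mgl": np.full(len(pump), 8.0),
            "temp_c": np.full(len(pump), 25.5),
            "pump_on": pump,
        }
    )
    return TrialRecord(
        trial_type="background_pre",
        chamber=chamber or ChamberMeta(chamber_id="c", system_volume_l=1.0),
        trace=trace,
    )


def rle_runs_oracle(pump):
    """Brute-force run-length scan: (start, end_exclusive) of pump==0 runs."""
    runs, start = [], None
    for i, v in enumerate(pump):
        if v == 0 and start is None:
            start = i
        elif v != 0 and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(pump)))
    return runs


class TestSegmentation:
    def test_basic_pattern(self):
        segs = segment_phases(trial_from_pump([1, 1, 0, 0, 0, 1, 0, 0]))
        assert [len(s.samples) for s in segs] == [3, 2]
        assert [s.t_start_s for s in segs] == [2.0, 6.0]

    def test_all_flush_gives_empty(self):
        assert segment_phases(trial_from_pump([1, 1, 1, 1])) == []

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=80))
    @settings(max_examples=200, deadline=None)
    def test_matches_run_length_oracle(self, pump):
        segs = segment_phases(trial_from_pump(pump))
        expected = rle_runs_oracle(pump)
        assert len(segs) == len(expected)
        for seg, (s, e) in zip(segs, expected):
            assert seg.t_start_s == float(s)
            assert seg.t_end_s == float(e - 1)
            assert len(seg.samples) == e - s


class TestTrim:
    @pytest.mark.parametrize("duration,retained", [(600, 480), (300, 180)])
    def test_retained_window(self, duration, retained):
        t = np.arange(0.0, duration + 1)
        seg = make_segment(t, 8.0 - 0.0001 * t)
        out = trim_segment(seg, 60.0, 60.0)
        assert out.usable and out.trimmed
        assert out.t_end_s - out.t_start_s == retained

    def test_too_short_marked_unusable(self):
        t = np.arange(0.0, 101.0)
        out = trim_segment(make_segment(t, np.full(len(t), 8.0)), 60.0, 60.0)
        assert not out.usable and out.trimmed

    def test_trim_drops_lead_and_tail_samples(self):
        t = np.arange(0.0, 601.0, 5.0)
        out = trim_segment(make_segment(t, np.full(len(t), 8.0)))
        assert out.samples["time_s"].min() == 60.0
        assert out.samples["time_s"].max() == 540.0


class TestSlope:
    def test_exact_line(self):
        t = np.arange(0.0, 300.0, 5.0)
        fit = fit_slope(make_segment(t, 8.0 - 0.001 * t))
        assert fit.slope_mgl_per_s == pytest.approx(-0.001, abs=1e-15)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_do_zero_slope(self):
        t = np.arange(0.0, 300.0, 5.0)
        fit = fit_slope(make_segment(t, np.full(len(t), 8.0)))
        assert fit.slope_mgl_per_s == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        t = np.sort(rng.uniform(0, 600, 50))
        y = 8.0 - 0.002 * t + rng.normal(0, 0.05, 50)
        fit = fit_slope(make_segment(t, y))
        slope, _ = ols_slope_oracle(t, y)
        assert fit.slope_mgl_per_s == pytest.approx(slope, abs=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(EstimationError):
            fit_slope(make_segment([0.0, 1.0], [8.0, 7.9]))


class TestMO2:
    def test_no_fish(self, chamber):
        fit = fit_slope(make_segment(np.arange(0, 300, 5.0), 8.0 - 0.001 * np.arange(0, 300, 5.0)))
        assert compute_mo2(fit, chamber) == pytest.approx(0.06, rel=1e-12)

    def test_fish_volume_correction(self, chamber):
        fish = FishMeta(fish_id="f", mass_g=100.0, tl_cm=20, habitat="forest",
                        acclim_temp_c=25.5, acclim_days=4)
        t = np.arange(0, 300, 5.0)
        fit = fit_slope(make_segment(t, 8.0 - 0.001 * t))
        # effective volume 0.9 l
        assert compute_mo2(fit, chamber, fish) == pytest.approx(0.054, rel=1e-12)

    def test_zero_slope_zero_rate(self, chamber):
        t = np.arange(0, 300, 5.0)
        fit = fit_slope(make_segment(t, np.full(len(t), 8.0)))
        assert compute_mo2(fit, chamber) == 0.0

    def test_fish_larger_than_system(self):
        small = ChamberMeta(chamber_id="c", system_volume_l=0.05)
        fish = FishMeta(fish_id="f", mass_g=100.0, tl_cm=20, habitat="forest",
                        acclim_temp_c=25.5, acclim_days=4)
        t = np.arange(0, 300, 5.0)
        fit = fit_slope(make_segment(t, 8.0 - 0.001 * t))
        with pytest.raises(ValidationError):
            compute_mo2(fit, small, fish)


class TestBackground:
    def test_constant_when_equal(self):
        bg = fit_background(make_blank_trial(0.01), make_blank_trial(0.01, trial_type="background_post"))
        assert bg.mode == "constant"
        for t in (0.0, 3600.0, 7200.0):
            assert bg.rate_at(t) == pytest.approx(0.01, rel=1e-9)

    def test_linear_interpolates_midpoint(self):
        bg = fit_background(
            make_blank_trial(0.01),
            make_blank_trial(0.03, trial_type="background_post"),
            t_pre_s=0.0, t_post_s=7200.0,
        )
        assert bg.mode == "linear_in_time"
        assert bg.rate_at(3600.0) == pytest.approx(0.02, rel=1e-9)

    def test_decreasing_background_goes_constant_at_mean(self):
        bg = fit_background(
            make_blank_trial(0.03),
            make_blank_trial(0.01, trial_type="background_post"),
            t_pre_s=0.0, t_post_s=7200.0,
        )
        assert bg.mode == "constant"
        assert bg.rate_at(1234.0) == pytest.approx(0.02, rel=1e-9)

    def test_missing_post_falls_back_to_pre(self):
        bg = fit_background(make_blank_trial(0.015), None)
        assert bg.mode == "constant"
        assert bg.rate_at(99.0) == pytest.approx(0.015, rel=1e-9)


class TestCorrection:
    def test_plain_subtraction(self):
        rec = MO2Record(segment_index=0, t_mid_s=100.0, mo2_raw_mg_min=0.10)
        bg = BackgroundModel("constant", 0.01, 0.01)
        assert correct_background(rec, bg).mo2_corr_mg_min == pytest.approx(0.09)

    def test_clamp_and_flag(self):
        rec = MO2Record(segment_index=0, t_mid_s=100.0, mo2_raw_mg_min=0.005)
        bg = BackgroundModel("constant", 0.01, 0.01)
        out = correct_background(rec, bg)
        assert out.mo2_corr_mg_min == 0.0
        assert FLAG_NEGATIVE in out.flags

    def test_time_varying_background(self):
        rec = MO2Record(segment_index=0, t_mid_s=3600.0, mo2_raw_mg_min=0.10)
        bg = BackgroundModel("linear_in_time", 0.01, 0.03, t_pre_s=0.0, t_post_s=7200.0)
        assert correct_background(rec, bg).mo2_corr_mg_min == pytest.approx(0.08)

    def test_corrected_never_negative(self):
        for raw in (0.0, 0.001, 0.05, 0.2):
            rec = MO2Record(segment_index=0, t_mid_s=0.0, mo2_raw_mg_min=raw)
            out = correct_background(rec, BackgroundModel("constant", 0.05, 0.05))
            assert out.mo2_corr_mg_min >= 0.0


def _rec(corr_abs, bg_abs, i=0):
    r = MO2Record(segment_index=i, t_mid_s=0.0, mo2_raw_mg_min=corr_abs + bg_abs)
    r.mo2_corr_mg_min = corr_abs
    r.bg_rate_mg_min = bg_abs
    return r


def rmr_fixed_point_oracle(corr, bg, threshold):
    """Exhaustive re-implementation of the shrinking-set iteration."""
    idx = list(range(len(corr)))
    while True:
        rmr = np.mean([corr[i] for i in idx])
        out = [i for i in idx if bg[i] > threshold * rmr]
        if not out:
            return rmr, set(idx)
        idx = [i for i in idx if i not in out]
        if not idx:
            return None, set()


class TestRmr:
    def test_four_equal_records_no_background(self, fish):
        recs = [_rec(0.08, 0.0, i) for i in range(4)]
        s = summarize_rmr(recs, fish)
        assert s.rmr == pytest.approx(0.08 / fish.mass_kg)
        assert len(s.used) == 4

    def test_25pct_rule_drops_high_background_record(self, fish):
        # equal corrected rates; one record's background is 30% of RMR
        recs = [_rec(0.08, 0.0, 0), _rec(0.08, 0.0, 1), _rec(0.08, 0.0, 2), _rec(0.08, 0.024, 3)]
        s = summarize_rmr(recs, fish)
        assert len(s.used) == 3
        assert FLAG_BG_EXCEEDS in recs[3].flags
        assert s.rmr == pytest.approx(0.08 / fish.mass_kg)

    def test_fixed_point_matches_exhaustive_oracle(self, fish):
        rng = np.random.default_rng(11)
        for _ in range(50):
            corr = rng.uniform(0.02, 0.12, 6)
            bg = rng.uniform(0.0, 0.04, 6)
            recs = [_rec(c, b, i) for i, (c, b) in enumerate(zip(corr, bg))]
            s = summarize_rmr(recs, fish, 0.25)
            rmr_o, used_o = rmr_fixed_point_oracle(corr, bg, 0.25)
            assert {r.segment_index for r in s.used} == used_o
            if rmr_o is None:
                assert s.rmr is None
            else:
                assert s.rmr == pytest.approx(rmr_o / fish.mass_kg, rel=1e-12)

    def test_idempotent_on_own_usable_set(self, fish):
        rng = np.random.default_rng(3)
        recs = [_rec(c, b, i) for i, (c, b) in enumerate(zip(rng.uniform(0.02, 0.1, 6), rng.uniform(0, 0.03, 6)))]
        s1 = summarize_rmr(recs, fish)
        if s1.rmr is not None:
            s2 = summarize_rmr(s1.used, fish)
            assert s2.rmr == pytest.approx(s1.rmr, rel=1e-12)
            assert {r.segment_index for r in s2.used} == {r.segment_index for r in s1.used}

    def test_all_rejected_gives_exclusion_reason(self, fish):
        recs = [_rec(0.01, 0.05, i) for i in range(4)]
        s = summarize_rmr(recs, fish)
        assert s.rmr is None and s.reason


class TestMmr:
    def _recs(self, values_ms, fish):
        return [_rec(v * fish.mass_kg, 0.0, i) for i, v in enumerate(values_ms)]

    def test_takes_maximum(self, fish):
        s = summarize_mmr(self._recs([7.0, 9.0, 8.0, 7.5], fish), fish, acclimation_max=6.0)
        assert s.mmr == pytest.approx(9.0)
        assert s.segment_index == 1

    def test_excluded_when_not_above_acclimation_max(self, fish):
        s = summarize_mmr(self._recs([5.0, 5.5], fish), fish, acclimation_max=6.0)
        assert s.excluded and s.mmr is None and "acclimation" in s.reason

    def test_tie_broken_by_earliest_segment(self, fish):
        s = summarize_mmr(self._recs([7.0, 9.0, 9.0, 8.0], fish), fish)
        assert s.segment_index == 1

    def test_rule_skipped_without_acclimation_max(self, fish):
        s = summarize_mmr(self._recs([5.0, 5.5], fish), fish, acclimation_max=None)
        assert s.mmr == pytest.approx(5.5)


class TestAerobicScope:
    def test_field_scale_values(self):
        as_abs, fas = aerobic_scope(3.81, 8.39)
        assert as_abs == pytest.approx(8.39 - 3.81)
        assert fas == pytest.approx(8.39 / 3.81)

    @pytest.mark.parametrize("rmr,mmr", [(4.0, 8.0), (4.0, 4.0), (2.5, 9.1)])
    def test_consistency(self, rmr, mmr):
        as_abs, fas = aerobic_scope(rmr, mmr)
        assert as_abs == mmr - rmr
        assert fas == pytest.approx(1.0 + as_abs / rmr, abs=1e-12)

    def test_nonpositive_rmr_rejected(self):
        with pytest.raises(ValidationError):
            aerobic_scope(0.0, 5.0)
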