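import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from aeroscope.io import ChamberMeta, FishMeta, TrialRecord
from aeroscope.respirometry import MeasurementSegment


@pytest.fixture
def fish():
    return FishMeta(
        fish_id="f001",
        mass_g=20.0,
        tl_cm=12.0,
        habitat="forest",
        acclim_temp_c=25.5,
        acclim_days=5,
    )


@pytest.fixture
def chamber():
    return ChamberMeta(chamber_id="ch1", system_volume_l=1.0)


def ols_slope_oracle(x, y):
    """Independent least-squares via the normal equations (closed form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def make_segment(t, do, index=0, temp=25.5):
    t = np.asarray(t, dtype=float)
    samples = pd.DataFrame(
        {
            "time_s": t,
            "do_mgl": np.asarray(do, dtype=float),
            "temp_c": np.full(len(t), temp),
            "pump_on": np.zeros(len(t), dtype=int),
        }
    )
    return MeasurementSegment(
        segment_index=index,
        t_start_s=float(t[0]),
        t_end_s=float(t[-1]),
        samples=samples,
        trimmed=True,
    )


def make_blank_trial(rate_mg_min, volume_l=1.0, duration_s=1500.0, trial_type="background_pre"):
    """A blank (empty-chamber) trial whose exact reduced rate is rate_mg_min."""
    t = np.arange(0.0, duration_s + 1, 5.0)
    slope = rate_mg_min / 60.0 / volume_l
    trace = pd.DataFrame(
        {
            "time_s": t,
            "do_mgl": 8.0 - slope * t,
            "temp_c": np.full(len(t), 25.5),
            "pump_on": np.zeros(len(t), dtype=int),
        }
    )
    return TrialRecord(
        trial_type=trial_type,
        chamber=ChamberMeta(chamber_id="ch1", system_volume_l=volume_l),
        trace=trace,
    )
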