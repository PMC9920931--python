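"""Novel sleep features from per-night sleep variables.

Inputs are per-night variables produced by an external sleep-detection tool
(onset/offset, sleep-period-time duration, daytime sustained-inactivity
duration, number of sleep periods, sleep efficiency).  Three kinds of
feature are derived per wear period:

* weekend-weekday sleep duration difference (social-jetlag proxy),
* percentage of nights with sleep onset before midnight,
* per-variable linear trends over the period, expressed as the Pearson
  correlation between the (available) night index and the variable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "we_wd_difference",
    "pct_onset_before_midnight",
    "trend",
    "sleep_features_for_period",
    "SLEEP_FEATURES",
    "SLEEP_FEATURES_EXTENDED",
    "is_weekend_night",
]

TREND_VARS = {
    "trend_sleep_onset": "onset_rel_h",
    "trend_sleep_offset": "offset_rel_h",
    "trend_spt_dur": "spt_dur_h",
    "trend_sibd_dur": "sibd_dur_h",
    "trend_n_sleep_periods": "n_sleep_periods",
    "trend_sleep_eff": "sleep_efficiency",
}

# Canonical novel sleep features; onset/offset trends are emitted as
# extended summaries (docs/methods.md discusses the inventory).
SLEEP_FEATURES = [
    "we_wd_sleep_diff",
    "pct_onset_before_midnight",
    "trend_spt_dur",
    "trend_sibd_dur",
    "trend_n_sleep_periods",
    "trend_sleep_eff",
]
SLEEP_FEATURES_EXTENDED = ["trend_sleep_onset", "trend_sleep_offset"]


def is_weekend_night(offset: pd.Timestamp) -> bool:
    """A night is a weekend night when its wake-up falls on Saturday or
    Sunday (the 'free day' convention of social-jetlag work)."""
    return offset.dayofweek >= 5


def we_wd_difference(nights: pd.DataFrame) -> float:
    """Mean weekend sleep duration minus mean weekday sleep duration (h);
    missing when either class of nights is absent."""
    dur = nights["spt_dur_h"].astype(float)
    weekend = nights["offset"].map(is_weekend_night)
    we = dur[weekend].dropna()
    wd = dur[~weekend].dropna()
    if we.empty or wd.empty:
        return float("nan")
    return float(we.mean() - wd.mean())


def pct_onset_before_midnight(nights: pd.DataFrame) -> float:
    """Percentage of nights whose sleep onset clock time falls in
    [19:00, 24:00), i.e. before midnight."""
    onsets = nights["onset"].dropna()
    if onsets.empty:
        return float("nan")
    before = onsets.map(lambda t: t.hour >= 19).sum()
    return 100.0 * float(before) / len(onsets)


def trend(night_index, values) -> float:
    """Pearson correlation between night index and a nightly variable.

    The index is the ordinal night of the wear period for nights where the
    variable is available (a period starting with a missing first night
    simply starts at index 2).  Missing when fewer than 3 nights carry the
    variable or the variable is constant.
    """
    x = np.asarray(night_index, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(y) == 0 or np.ptp(x) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def _onset_rel_hours(onset: pd.Timestamp) -> float:
    """Onset clock time as hours since 19:00, monotone across midnight for
    onsets within the 19:00-14:00 night window."""
    h = onset.hour + onset.minute / 60.0 + onset.second / 3600.0
    return (h - 19.0) % 24.0


def sleep_features_for_period(nights: pd.DataFrame) -> dict[str, float]:
    """All novel sleep features for one wear period.

    ``nights`` needs columns night_index, onset, offset, spt_dur_h,
    sibd_dur_h, n_sleep_periods, sleep_efficiency (one row per night).
    """
    nights = nights.sort_values("night_index").copy()
    nights["onset_rel_h"] = nights["onset"].map(
        lambda t: _onset_rel_hours(t) if pd.notna(t) else float("nan")
    )
    nights["offset_rel_h"] = nights["offset"].map(
        lambda t: (t.hour + t.minute / 60.0) if pd.notna(t) else float("nan")
    )
    out = {
        "we_wd_sleep_diff": we_wd_difference(nights),
        "pct_onset_before_midnight": pct_onset_before_midnight(nights),
    }
    for feat, col in TREND_VARS.items():
        out[feat] = trend(nights["night_index"], nights[col])
    return out
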