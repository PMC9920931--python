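"""Wrist-temperature features per wear period.

From the smoothed quarter-hour temperature series of each valid sleep night
and each valid 08:00-08:00 day, a canonical set of 19 per-period features is
aggregated: between-night variability of the nightly mean, summaries of
within-night dispersion (sd, IQR), timing of in-sleep temperature extrema
and of the maximum 15-min rates of change, clock-time variability of the
24-h extrema, normalized approximate entropy of sleep temperature (per
night and over all nights concatenated), the 24-h min-max temperature
difference, and the 48-h sleep-wake temperature difference.

The nightly mean temperature itself is deliberately not a feature: absolute
wrist temperature depends on uncontrolled externals (strap tightness,
ambient conditions), so only dispersion, timing, and entropy summaries are
kept, plus within-period contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig, DEFAULT_CONFIG
from .entropy import apen, apen_normalized
from .io import SleepWindow
from .preprocess import DayTempSeries, NightTempSeries

__all__ = [
    "NightTempSummary",
    "DayTempSummary",
    "summarize_night",
    "summarize_day",
    "sleep_wake_diff_48h",
    "aggregate_period",
    "TEMP_FEATURES",
    "TEMP_FEATURES_EXTENDED",
]

# Canonical 19-feature inventory (docs/methods.md enumerates the mapping).
TEMP_FEATURES = [
    "std_temp_mean",
    "mean_temp_std",
    "std_temp_std",
    "mean_temp_iqr",
    "std_temp_iqr",
    "std_time_temp_min",
    "std_time_temp_max",
    "mean_hrs_before_wake_temp_min",
    "std_hrs_before_wake_temp_min",
    "mean_hrs_after_onset_temp_max",
    "std_hrs_after_onset_temp_max",
    "mean_time_mroi",
    "std_time_mroi",
    "mean_time_mrod",
    "std_time_mrod",
    "mean_apen_sleep",
    "apen_sleep_all_nights",
    "temp_min_max_diff",
    "mean_sleep_wake_diff",
]

# Supplementary summaries, emitted under the "novel_extended" group.
TEMP_FEATURES_EXTENDED = [
    "std_apen_sleep",
    "mean_apen_24h",
    "std_apen_24h",
    "std_sleep_wake_diff",
    "mean_hrs_after_onset_temp_min",
    "std_hrs_after_onset_temp_min",
    "mean_hrs_before_wake_temp_max",
    "std_hrs_before_wake_temp_max",
]


@dataclass
class NightTempSummary:
    """Per-night summary of the smoothed sleep-temperature series."""

    T: float                    # mean sleep temperature
    S: float                    # sd of sleep temperature
    iqr: float
    t_min_after_onset: float    # hours after (rounded) onset of the minimum
    t_min_before_wake: float
    t_max_after_onset: float
    t_max_before_wake: float
    mroi: float                 # max 15-min rate of increase (degC / 15 min)
    mrod: float                 # max 15-min rate of decrease (>= 0)
    t_mroi: float               # hours after onset, end of winning interval
    t_mrod: float
    apen_night: float           # normalized ApEn (ApEn / K)
    K: int


@dataclass
class DayTempSummary:
    """Per-day (08:00-08:00) summary of the smoothed 97-point series."""

    time_min_h: float           # hours since 08:00
    time_max_h: float
    min_max_diff: float
    apen_day: float


def summarize_night(ns: NightTempSeries, config: PipelineConfig = DEFAULT_CONFIG) -> NightTempSummary:
    """Summary statistics of one valid night; ties in extrema and rate
    winners break to the earliest occurrence."""
    if not ns.valid:
        raise ValueError("summarize_night called on an invalid night")
    v = np.asarray(ns.values, dtype=float)
    k = v.size
    step_h = config.temp_bin_min / 60.0
    dur_h = step_h * (k - 1)

    i_min = int(np.argmin(v))
    i_max = int(np.argmax(v))
    diffs = np.diff(v)
    if diffs.size:
        i_up = int(np.argmax(diffs))
        i_dn = int(np.argmin(diffs))
        mroi = max(float(diffs[i_up]), 0.0)
        mrod = max(-float(diffs[i_dn]), 0.0)
        t_mroi = (i_up + 1) * step_h
        t_mrod = (i_dn + 1) * step_h
    else:  # pragma: no cover - guarded by min_sleep_points
        mroi = mrod = t_mroi = t_mrod = 0.0

    return NightTempSummary(
        T=float(np.mean(v)),
        S=float(np.std(v, ddof=1)),
        iqr=float(np.percentile(v, 75) - np.percentile(v, 25)),
        t_min_after_onset=i_min * step_h,
        t_min_before_wake=dur_h - i_min * step_h,
        t_max_after_onset=i_max * step_h,
        t_max_before_wake=dur_h - i_max * step_h,
        mroi=mroi,
        mrod=mrod,
        t_mroi=t_mroi,
        t_mrod=t_mrod,
        apen_night=apen_normalized(v, config.apen),
        K=k,
    )


def summarize_day(ds: DayTempSeries, config: PipelineConfig = DEFAULT_CONFIG) -> DayTempSummary:
    if not ds.valid:
        raise ValueError("summarize_day called on an invalid day")
    v = np.asarray(ds.values, dtype=float)
    step_h = config.temp_bin_min / 60.0
    i_min = int(np.argmin(v))
    i_max = int(np.argmax(v))
    return DayTempSummary(
        time_min_h=i_min * step_h,
        time_max_h=i_max * step_h,
        min_max_diff=float(v[i_max] - v[i_min]),
        apen_day=apen_normalized(v, config.apen),
    )


def sleep_wake_diff_48h(
    qtemp: pd.Series, windows: list[SleepWindow], window: SleepWindow
) -> float:
    """Mean sleep minus mean wake temperature over the 48 h starting at
    00:00 on the day of this window's sleep onset; missing when either class
    of quarter-hour bins is absent."""
    start = window.onset.normalize()
    end = start + pd.Timedelta(hours=48)
    span = qtemp[(qtemp.index >= start) & (qtemp.index < end)]
    if span.empty:
        return float("nan")
    in_sleep = np.zeros(len(span), dtype=bool)
    for w in windows:
        in_sleep |= (span.index >= w.onset) & (span.index < w.offset)
    sleep_vals = span[in_sleep].dropna()
    wake_vals = span[~in_sleep].dropna()
    if sleep_vals.empty or wake_vals.empty:
        return float("nan")
    return float(sleep_vals.mean() - wake_vals.mean())


def _mean(vals: list[float]) -> float:
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.mean(vals)) if vals else float("nan")


def _std(vals: list[float]) -> float:
    vals = [v for v in vals if np.isfinite(v)]
    return float(np.std(vals, ddof=1)) if len(vals) >= 2 else float("nan")


def aggregate_period(
    nights: list[NightTempSummary],
    days: list[DayTempSummary],
    diffs: list[float],
    night_series: list[NightTempSeries],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[dict[str, float], dict[str, float]]:
    """Aggregate night/day summaries into the canonical 19 period features
    plus the extended summaries.

    sd-type features need >= 2 valid nights (or days) and are missing
    otherwise; mean-type features need >= 1.
    """
    concat = [np.asarray(ns.values, dtype=float) for ns in night_series if ns.valid]
    apen_all = float("nan")
    if concat:
        x = np.concatenate(concat)
        if x.size >= config.apen.m + 2:
            apen_all = apen(x, config.apen) / x.size

    features = {
        "std_temp_mean": _std([n.T for n in nights]),
        "mean_temp_std": _mean([n.S for n in nights]),
        "std_temp_std": _std([n.S for n in nights]),
        "mean_temp_iqr": _mean([n.iqr for n in nights]),
        "std_temp_iqr": _std([n.iqr for n in nights]),
        "std_time_temp_min": _std([d.time_min_h for d in days]),
        "std_time_temp_max": _std([d.time_max_h for d in days]),
        "mean_hrs_before_wake_temp_min": _mean([n.t_min_before_wake for n in nights]),
        "std_hrs_before_wake_temp_min": _std([n.t_min_before_wake for n in nights]),
        "mean_hrs_after_onset_temp_max": _mean([n.t_max_after_onset for n in nights]),
        "std_hrs_after_onset_temp_max": _std([n.t_max_after_onset for n in nights]),
        "mean_time_mroi": _mean([n.t_mroi for n in nights]),
        "std_time_mroi": _std([n.t_mroi for n in nights]),
        "mean_time_mrod": _mean([n.t_mrod for n in nights]),
        "std_time_mrod": _std([n.t_mrod for n in nights]),
        "mean_apen_sleep": _mean([n.apen_night for n in nights]),
        "apen_sleep_all_nights": apen_all,
        "temp_min_max_diff": _mean([d.min_max_diff for d in days]),
        "mean_sleep_wake_diff": _mean(diffs),
    }
    extended = {
        "std_apen_sleep": _std([n.apen_night for n in nights]),
        "mean_apen_24h": _mean([d.apen_day for d in days]),
        "std_apen_24h": _std([d.apen_day for d in days]),
        "std_sleep_wake_diff": _std(diffs),
        "mean_hrs_after_onset_temp_min": _mean([n.t_min_after_onset for n in nights]),
        "std_hrs_after_onset_temp_min": _std([n.t_min_after_onset for n in nights]),
        "mean_hrs_before_wake_temp_max": _mean([n.t_max_before_wake for n in nights]),
        "std_hrs_before_wake_temp_max": _std([n.t_max_before_wake for n in nights]),
    }
    return features, extended
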