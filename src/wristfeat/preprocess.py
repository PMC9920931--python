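"""Signal conditioning for epoch-level wrist recordings.

Stages: ENMONZ activity summary, stillness-based non-wear detection,
valid-day / valid-night filtering, same-clock-time imputation of non-wear
activity epochs, low-temperature interpolation, quarter-hour temperature
averaging, moving-average smoothing, and extraction of the per-night and
per-day temperature series that feed feature extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .config import PipelineConfig, DEFAULT_CONFIG
from .io import Recording, SleepWindow

__all__ = [
    "compute_enmonz",
    "detect_nonwear",
    "nonwear_mask",
    "filter_valid_days",
    "impute_nonwear_epochs",
    "night_starts",
    "validate_night",
    "impute_low_temperature",
    "average_temp_15min",
    "moving_average",
    "extract_night_series",
    "extract_day_series",
    "NonWearInterval",
    "ValidDays",
    "NightTempSeries",
    "DayTempSeries",
]


@dataclass(frozen=True)
class NonWearInterval:
    """Block-aligned off-wrist interval, [start, end)."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("NonWearInterval end must follow start")


def compute_enmonz(recording: Recording) -> pd.Series:
    """Euclidean norm of the three acceleration axes minus 1 g, negatives
    clipped to zero, expressed in mg."""
    d = recording.data
    norm = np.sqrt(d["accel_x"] ** 2 + d["accel_y"] ** 2 + d["accel_z"] ** 2)
    return pd.Series(np.maximum(norm - 1.0, 0.0) * 1000.0, index=d.index, name="enmonz")


def detect_nonwear(
    recording: Recording, config: PipelineConfig = DEFAULT_CONFIG
) -> list[NonWearInterval]:
    """Classify 15-min blocks as non-wear from stillness of the raw axes.

    Each quarter-hour block (aligned to :00/:15/:30/:45) is classified from
    the 60-min window centred on it: the block is non-wear when at least two
    of the three axes show either a standard deviation below 13 mg or a value
    range below 50 mg within the window.  Adjacent non-wear blocks are merged
    into intervals.
    """
    d = recording.data
    if len(d) < 2:
        warnings.warn("recording too short for non-wear detection")
        return []
    es = recording.epoch_seconds
    span_s = (d.index[-1] - d.index[0]).total_seconds() + es
    if span_s < config.nonwear_window_min * 60:
        warnings.warn("recording shorter than one non-wear window; skipping detection")
        return []

    w = max(2, int(round(config.nonwear_window_min * 60 / es)))
    mg = d[["accel_x", "accel_y", "accel_z"]] * 1000.0
    roll = mg.rolling(window=w, center=True, min_periods=2)
    sd = roll.std().to_numpy()
    rng = (roll.max() - roll.min()).to_numpy()
    still = (sd < config.nonwear_sd_mg) | (rng < config.nonwear_range_mg)
    block_flag_per_epoch = still.sum(axis=1) >= config.nonwear_min_axes

    block = pd.Timedelta(minutes=config.nonwear_block_min)
    first = d.index[0].floor(f"{config.nonwear_block_min}min")
    starts = pd.date_range(first, d.index[-1], freq=block)
    # classify each block by the rolling statistics at the epoch nearest its midpoint
    mids = starts + block / 2
    pos = np.clip(d.index.searchsorted(mids), 0, len(d) - 1)
    flagged = block_flag_per_epoch[pos]

    intervals: list[NonWearInterval] = []
    run_start = None
    for s, f in zip(starts, flagged):
        if f and run_start is None:
            run_start = s
        elif not f and run_start is not None:
            intervals.append(NonWearInterval(run_start, s))
            run_start = None
    if run_start is not None:
        intervals.append(NonWearInterval(run_start, starts[-1] + block))
    return intervals


def nonwear_mask(index: pd.DatetimeIndex, intervals: list[NonWearInterval]) -> pd.Series:
    """Boolean per-epoch series, True inside any non-wear interval."""
    mask = np.zeros(len(index), dtype=bool)
    for iv in intervals:
        mask |= (index >= iv.start) & (index < iv.end)
    return pd.Series(mask, index=index, name="nonwear")


@dataclass
class ValidDays:
    """Wear-time accounting per calendar day."""

    wear_hours: dict[date, float]
    valid: set[date]
    min_valid_days: int

    @property
    def usable(self) -> bool:
        return len(self.valid) >= self.min_valid_days


def filter_valid_days(
    recording: Recording,
    intervals: list[NonWearInterval],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> ValidDays:
    """A day is valid when its wear time reaches 16 h; a wear period is
    usable when it has at least 7 valid days.

    Hours without recorded epochs count as non-wear, so partial first/last
    days are penalized naturally.
    """
    idx = recording.data.index
    es = recording.epoch_seconds
    worn = ~nonwear_mask(idx, intervals)
    hours = worn.groupby(idx.date).sum() * es / 3600.0
    wear_hours = {d: float(h) for d, h in hours.items()}
    thr = config.valid_day_hours
    if config.valid_day_inclusive:
        valid = {d for d, h in wear_hours.items() if h >= thr}
    else:
        valid = {d for d, h in wear_hours.items() if h > thr}
    return ValidDays(wear_hours, valid, config.min_valid_days)


def impute_nonwear_epochs(
    activity: pd.Series, mask: pd.Series, valid_days: ValidDays | None = None
) -> pd.Series:
    """Replace non-wear activity epochs by the mean of epochs at the same
    clock time on other days with worn data; epochs with no donor stay
    missing."""
    out = activity.copy().astype(float)
    m = mask.to_numpy()
    out[m] = np.nan
    if not m.any():
        return out
    tod = activity.index.time
    donors = out[~m].groupby(tod[~m]).mean()
    fill_pos = np.flatnonzero(m)
    if valid_days is not None:
        on_valid = np.isin(activity.index.date[fill_pos], list(valid_days.valid))
        fill_pos = fill_pos[on_valid]
    fill_vals = pd.Series(tod[fill_pos]).map(donors).to_numpy()
    out.iloc[fill_pos] = fill_vals
    return out


def night_starts(recording: Recording, config: PipelineConfig = DEFAULT_CONFIG) -> list[pd.Timestamp]:
    """Noon timestamps opening each 24-h night window touching the recording."""
    idx = recording.data.index
    first = pd.Timestamp(idx[0].date()) + pd.Timedelta(hours=config.night_def_start_hour)
    if first > idx[0]:
        first -= pd.Timedelta(days=1)
    out = []
    t = first
    while t < idx[-1]:
        out.append(t)
        t += pd.Timedelta(days=1)
    return out


def validate_night(
    mask: pd.Series, night_start: pd.Timestamp, config: PipelineConfig = DEFAULT_CONFIG
) -> bool:
    """True when non-wear occupies at most 10% of the noon-to-noon window.

    Epochs missing from the recording count as non-wear; the exclusion rule
    is strict (>10% excluded), so exactly 10% still validates.
    """
    end = night_start + pd.Timedelta(days=1)
    idx = mask.index
    es = (idx[1] - idx[0]).total_seconds() if len(idx) > 1 else 60.0
    expected = int(round(24 * 3600 / es))
    sel = (idx >= night_start) & (idx < end)
    worn = int((~mask[sel]).sum())
    frac_nonwear = 1.0 - worn / expected
    return frac_nonwear <= config.night_nonwear_max_frac + 1e-12


def impute_low_temperature(
    temp: pd.Series, threshold_c: float = DEFAULT_CONFIG.low_temp_c
) -> pd.Series:
    """Linearly interpolate temperature runs below the 24 degC threshold.

    Sub-threshold samples are replaced by interpolation between the nearest
    flanking samples at or above the threshold.  Leading/trailing runs have
    no anchor on one side and are left missing rather than extrapolated;
    originally-missing samples are preserved as missing.
    """
    low = temp < threshold_c
    if not low.any():
        return temp.copy()
    masked = temp.mask(low)
    if masked.notna().sum() == 0:
        warnings.warn("entire temperature series below threshold; all missing")
        return masked
    interp = masked.interpolate(method="index", limit_area="inside")
    return temp.mask(low, interp)


def average_temp_15min(temp: pd.Series, bin_min: int = DEFAULT_CONFIG.temp_bin_min) -> pd.Series:
    """Mean temperature per quarter-hour bin (bins aligned to :00/:15/:30/:45);
    bins with no data are missing."""
    return temp.resample(f"{bin_min}min").mean()


def moving_average(values, q: int) -> np.ndarray:
    """Centred moving average with window l = 2q+1, clipped at the series
    bounds (partial-window mean), so output length equals input length."""
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window=2 * q + 1, center=True, min_periods=1).mean().to_numpy()


@dataclass
class NightTempSeries:
    """Smoothed quarter-hour temperature from rounded sleep onset to offset."""

    window: SleepWindow
    times: pd.DatetimeIndex = field(repr=False)
    values: np.ndarray = field(repr=False)
    valid: bool = True
    reason: str | None = None
    n_interpolated: int = 0

    @property
    def K(self) -> int:
        return len(self.values)


@dataclass
class DayTempSeries:
    """Smoothed 97-point 08:00-to-08:00 temperature day."""

    day: date
    times: pd.DatetimeIndex = field(repr=False)
    values: np.ndarray = field(repr=False)
    valid: bool = True
    reason: str | None = None


def _fill_and_smooth(vals: pd.Series, q: int) -> tuple[np.ndarray, int]:
    """Interpolate residual missing bins, pad edges with the nearest value,
    then smooth; returns (values, number of filled bins)."""
    n_missing = int(vals.isna().sum())
    if n_missing:
        vals = vals.interpolate(method="linear", limit_area="inside").ffill().bfill()
    return moving_average(vals.to_numpy(), q), n_missing


def night_window_date(window: SleepWindow, config: PipelineConfig = DEFAULT_CONFIG) -> date:
    """Calendar date of the evening opening this night's 19:00-14:00 window."""
    onset = window.onset
    if onset.hour >= config.night_window_start_hour:
        return onset.date()
    return (onset - pd.Timedelta(days=1)).date()


def extract_night_series(
    qtemp: pd.Series,
    window: SleepWindow,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> NightTempSeries:
    """Extract one night's smoothed sleep-temperature series.

    The night is marked invalid (never raised) when the 19:00-14:00 night
    window holds fewer than 61 non-missing quarter-hour values, or fewer
    than 15 non-missing points lie between (rounded) sleep onset and offset.
    Onset is rounded down and offset rounded up to the nearest quarter hour;
    both boundary bins are included, giving 4h+1 points for an h-hour sleep.
    """
    bin_td = pd.Timedelta(minutes=config.temp_bin_min)
    d0 = pd.Timestamp(night_window_date(window, config))
    win_start = d0 + pd.Timedelta(hours=config.night_window_start_hour)
    win_end = d0 + pd.Timedelta(days=1, hours=config.night_window_end_hour)
    win_times = pd.date_range(win_start, win_end, freq=bin_td)
    coverage = int(qtemp.reindex(win_times).notna().sum())

    onset_q = window.onset.floor(bin_td)
    offset_q = window.offset.ceil(bin_td)
    times = pd.date_range(onset_q, offset_q, freq=bin_td)
    vals = qtemp.reindex(times)

    if coverage < config.min_night_coverage:
        return NightTempSeries(window, times, vals.to_numpy(), False, "night_coverage")
    n_sleep = int(vals.notna().sum())
    if n_sleep < config.min_sleep_points:
        return NightTempSeries(window, times, vals.to_numpy(), False, "sleep_points")

    smoothed, n_fill = _fill_and_smooth(vals, config.smooth_q)
    return NightTempSeries(window, times, smoothed, True, None, n_fill)


def extract_day_series(
    qtemp: pd.Series,
    day: date,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> DayTempSeries:
    """Extract one smoothed 08:00-to-08:00 temperature day (97 quarter-hour
    points); invalid when fewer than 77 points are present."""
    bin_td = pd.Timedelta(minutes=config.temp_bin_min)
    start = pd.Timestamp(day) + pd.Timedelta(hours=config.day_window_start_hour)
    times = pd.date_range(start, start + pd.Timedelta(days=1), freq=bin_td)
    vals = qtemp.reindex(times)
    if int(vals.notna().sum()) < config.min_day_coverage:
        return DayTempSeries(day, times, vals.to_numpy(), False, "day_coverage")
    smoothed, _ = _fill_and_smooth(vals, config.smooth_q)
    return DayTempSeries(day, times, smoothed, True, None)
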