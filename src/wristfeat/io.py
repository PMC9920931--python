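"""On-disk artifacts: recordings, sleep windows, night variables, outcomes,
feature tables.

Everything is plain delimited text (CSV with a named-column header).
Timestamps are ISO-8601; if an explicit UTC offset is present it is reduced
to naive local clock time on read, because every downstream rule (19:00
night-window start, noon-to-noon nights, the 08:00 day window) is a
wall-clock rule.

Column dictionaries
-------------------
recordings.csv   : timestamp, accel_x, accel_y, accel_z (g), temperature (degC),
                   light (lux, optional)
sleep_windows.csv: subject_id, period_id, night_index, onset, offset
night_vars.csv   : subject_id, period_id, night_index, onset, offset,
                   spt_dur_h, sibd_dur_h, n_sleep_periods, sleep_efficiency
outcomes.csv     : subject_id, sex, age, diagnosis, then <score>_<timepoint>
                   for score in {mrs, gad7, phq2, fq_ag, fq_soc, fq_sp} and
                   timepoint in {baseline, after1, after2} (phq2 has no after2)
features.csv     : subject_id, period_id, one column per feature; companion
                   file <stem>.groups.csv maps feature -> group
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "SleepWindow",
    "FeatureTable",
    "OutcomeTable",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_sleep_windows",
    "write_sleep_windows",
    "read_night_vars",
    "write_night_vars",
    "read_outcomes",
    "write_outcomes",
    "read_feature_table",
    "write_feature_table",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its schema."""


SCORE_RANGES = {
    "mrs": (0, 5),
    "gad7": (0, 21),
    "phq2": (0, 6),
    "fq_ag": (0, 40),
    "fq_soc": (0, 40),
    "fq_sp": (0, 40),
}
TIMEPOINTS = ("baseline", "after1", "after2")
# PHQ-2 is administered only at baseline and after the first wear period.
SCORE_COLUMNS = [
    f"{q}_{tp}"
    for q in SCORE_RANGES
    for tp in TIMEPOINTS
    if not (q == "phq2" and tp == "after2")
]


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class Recording:
    """Epoch-level multimodal time series for one subject and wear period.

    ``data`` is indexed by a strictly increasing, uniformly spaced naive
    DatetimeIndex and carries columns ``accel_x/y/z`` (g), ``temperature``
    (degC) and optionally ``light`` (lux).
    """

    subject_id: str
    period_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise FormatError("Recording index must be a DatetimeIndex")
        if idx.has_duplicates:
            row = int(np.flatnonzero(idx.duplicated())[0])
            raise FormatError(f"duplicated timestamp at row {row}: {idx[row]}")
        if len(idx) > 1:
            deltas = np.diff(idx.asi8)
            if (deltas <= 0).any():
                row = int(np.flatnonzero(deltas <= 0)[0]) + 1
                raise FormatError(f"non-increasing timestamp at row {row}: {idx[row]}")
            if len(np.unique(deltas)) > 1:
                raise FormatError("non-uniform epoch spacing")
        missing = {"accel_x", "accel_y", "accel_z", "temperature"} - set(self.data.columns)
        if missing:
            raise FormatError(f"missing mandatory channel(s): {sorted(missing)}")

    @property
    def epoch_seconds(self) -> float:
        idx = self.data.index
        if len(idx) < 2:
            return float("nan")
        return float((idx[1] - idx[0]).total_seconds())

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class SleepWindow:
    """One night's sleep period, onset to offset (wake)."""

    night_index: int
    onset: pd.Timestamp
    offset: pd.Timestamp

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise FormatError(f"night {self.night_index}: offset {self.offset} <= onset {self.onset}")
        if (self.offset - self.onset) >= pd.Timedelta(hours=19):
            raise FormatError(f"night {self.night_index}: implausible sleep duration >= 19 h")

    @property
    def duration_h(self) -> float:
        return (self.offset - self.onset).total_seconds() / 3600.0


class FeatureTable:
    """Wear-period x feature matrix with explicit missingness and column groups.

    ``data`` is a DataFrame indexed by (subject_id, period_id); ``groups``
    maps every column to a group label (demographic / sleep / pa / novel /
    novel_extended).
    """

    def __init__(self, data: pd.DataFrame, groups: dict[str, str]):
        if data.index.nlevels != 2:
            raise FormatError("FeatureTable index must be (subject_id, period_id)")
        if data.index.has_duplicates:
            raise FormatError("duplicate (subject_id, period_id) rows")
        ungrouped = [c for c in data.columns if c not in groups]
        if ungrouped:
            raise FormatError(f"columns without a group: {ungrouped}")
        self.data = data
        self.groups = {c: groups[c] for c in data.columns}

    def columns_in_group(self, *names: str) -> list[str]:
        return [c for c in self.data.columns if self.groups[c] in names]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FeatureTable({self.data.shape[0]} periods x {self.data.shape[1]} features)"


class OutcomeTable:
    """Per-subject demographics, diagnosis and questionnaire scores.

    One row per subject; score columns follow ``SCORE_COLUMNS``.  Scores are
    validated against their instrument ranges (mRS 0-5, GAD-7 0-21, PHQ-2
    0-6, FQ subscores 0-40); missing values are allowed and preserved.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise FormatError("duplicate subject_id rows in outcomes")
        for col in ("sex", "age", "diagnosis"):
            if col not in data.columns:
                raise FormatError(f"outcomes missing column {col!r}")
        bad_dx = set(data["diagnosis"].dropna()) - {"stroke", "tia"}
        if bad_dx:
            raise FormatError(f"unknown diagnosis value(s): {sorted(bad_dx)}")
        for col in SCORE_COLUMNS:
            if col not in data.columns:
                continue
            lo, hi = SCORE_RANGES[col.rsplit("_", 1)[0]]
            vals = data[col].dropna()
            out = vals[(vals < lo) | (vals > hi)]
            if len(out):
                sid = out.index[0]
                raise FormatError(
                    f"{col}={out.iloc[0]} for subject {sid} outside [{lo}, {hi}]"
                )
        self.data = data

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# readers / writers


def _parse_timestamps(values, context: str) -> pd.DatetimeIndex:
    try:
        ts = pd.to_datetime(values, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{context}: unparseable timestamp ({exc})") from exc
    if isinstance(ts, pd.Series):
        ts = pd.DatetimeIndex(ts)
    if ts.tz is not None:
        ts = ts.tz_localize(None)  # keep local wall-clock time
    return ts


def read_recording(path: str | Path, subject_id: str = "", period_id: str = "") -> Recording:
    """Read an epoch-level recording CSV (see module docstring for columns)."""
    path = Path(path)
    df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise FormatError(f"{path}: no 'timestamp' column")
    idx = _parse_timestamps(df.pop("timestamp"), str(path))
    df.index = idx
    df.index.name = "timestamp"
    if not subject_id:
        subject_id = str(df.pop("subject_id").iloc[0]) if "subject_id" in df else path.stem
    else:
        df = df.drop(columns=["subject_id"], errors="ignore")
    if not period_id:
        period_id = str(df.pop("period_id").iloc[0]) if "period_id" in df else "1"
    else:
        df = df.drop(columns=["period_id"], errors="ignore")
    return Recording(subject_id, period_id, df)


def write_recording(rec: Recording, path: str | Path) -> None:
    out = rec.data.copy()
    out.insert(0, "period_id", rec.period_id)
    out.insert(0, "subject_id", rec.subject_id)
    out.to_csv(path, index=True, index_label="timestamp", date_format="%Y-%m-%dT%H:%M:%S")


def read_sleep_windows(path: str | Path) -> dict[tuple[str, str], list[SleepWindow]]:
    """Read sleep windows keyed by (subject_id, period_id)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "period_id": str})
    for col in ("subject_id", "period_id", "night_index", "onset", "offset"):
        if col not in df.columns:
            raise FormatError(f"sleep windows missing column {col!r}")
    onsets = _parse_timestamps(df["onset"], "sleep onsets")
    offsets = _parse_timestamps(df["offset"], "sleep offsets")
    out: dict[tuple[str, str], list[SleepWindow]] = {}
    for (sid, pid), on, off, night in zip(
        zip(df["subject_id"], df["period_id"]), onsets, offsets, df["night_index"]
    ):
        out.setdefault((sid, pid), []).append(SleepWindow(int(night), on, off))
    for windows in out.values():
        windows.sort(key=lambda w: w.night_index)
    return out


def write_sleep_windows(windows: dict[tuple[str, str], list[SleepWindow]], path: str | Path) -> None:
    rows = [
        {
            "subject_id": sid,
            "period_id": pid,
            "night_index": w.night_index,
            "onset": w.onset.isoformat(),
            "offset": w.offset.isoformat(),
        }
        for (sid, pid), ws in windows.items()
        for w in ws
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


NIGHT_VAR_COLUMNS = [
    "subject_id", "period_id", "night_index", "onset", "offset",
    "spt_dur_h", "sibd_dur_h", "n_sleep_periods", "sleep_efficiency",
]


def read_night_vars(path: str | Path) -> pd.DataFrame:
    """Per-night sleep variables (externally detected, GGIR-style export)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "period_id": str})
    missing = set(NIGHT_VAR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"night vars missing column(s): {sorted(missing)}")
    df["onset"] = _parse_timestamps(df["onset"], "night var onsets")
    df["offset"] = _parse_timestamps(df["offset"], "night var offsets")
    eff = df["sleep_efficiency"].dropna()
    if ((eff < 0) | (eff > 1)).any():
        raise FormatError("sleep_efficiency outside [0, 1]")
    return df


def write_night_vars(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def read_outcomes(path: str | Path) -> OutcomeTable:
    df = pd.read_csv(path, dtype={"subject_id": str}).set_index("subject_id")
    return OutcomeTable(df)


def write_outcomes(table: OutcomeTable, path: str | Path) -> None:
    table.data.to_csv(path, index=True, index_label="subject_id")


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "period_id": str})
    df = df.set_index(["subject_id", "period_id"])
    groups_path = path.with_suffix(".groups.csv")
    if groups_path.exists():
        gdf = pd.read_csv(groups_path)
        groups = dict(zip(gdf["feature"], gdf["group"]))
    else:
        groups = {c: "unknown" for c in df.columns}
    return FeatureTable(df, groups)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    path = Path(path)
    table.data.to_csv(path, index=True)
    pd.DataFrame(
        {"feature": list(table.groups), "group": list(table.groups.values())}
    ).to_csv(path.with_suffix(".groups.csv"), index=False)
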