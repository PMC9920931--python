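"""End-to-end orchestration: recordings -> feature table -> models.

``extract_features`` runs the full conditioning chain per subject-period
(non-wear detection, valid-day/valid-night filters, low-temperature
interpolation, quarter-hour averaging) and assembles the canonical feature
table: demographics, the 19 temperature features, the 6 sleep features
(group "novel", 25 columns total) and the extended summaries (group
"novel_extended").  ``evaluate_subsets`` reproduces the study design:
RRCT selection inside a leave-one-subject-out loop, vote aggregation,
incremental-k logistic models, and the AUC-weighted ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .config import PipelineConfig, DEFAULT_CONFIG
from .io import FeatureTable, OutcomeTable, Recording, SleepWindow
from .models import auc_curve, loso_fit_predict, metrics, prepare_features, weighted_ensemble
from .preprocess import (
    average_temp_15min,
    detect_nonwear,
    extract_day_series,
    extract_night_series,
    filter_valid_days,
    impute_low_temperature,
    night_window_date,
    nonwear_mask,
    validate_night,
)
from .selection import loso_selection, vote_features
from .sleep import SLEEP_FEATURES, SLEEP_FEATURES_EXTENDED, sleep_features_for_period
from .temperature import (
    TEMP_FEATURES,
    TEMP_FEATURES_EXTENDED,
    aggregate_period,
    sleep_wake_diff_48h,
    summarize_day,
    summarize_night,
)

__all__ = [
    "extract_features",
    "temp_features_for_recording",
    "evaluate_subsets",
    "default_subsets",
    "PeriodReport",
]


@dataclass
class PeriodReport:
    """Filter accounting for one subject-period."""

    subject_id: str
    period_id: str
    usable: bool
    n_valid_days: int
    n_days: int
    nights_kept: int = 0
    nights_dropped: dict = field(default_factory=dict)
    days_kept: int = 0
    days_dropped: int = 0


def temp_features_for_recording(
    recording: Recording,
    windows: list[SleepWindow],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[dict | None, dict, PeriodReport]:
    """Temperature features for one recording, or (None, {}, report) when
    the period fails the 7-valid-day rule."""
    intervals = detect_nonwear(recording, config)
    vd = filter_valid_days(recording, intervals, config)
    report = PeriodReport(
        recording.subject_id,
        recording.period_id,
        vd.usable,
        len(vd.valid),
        len(vd.wear_hours),
    )
    if not vd.usable:
        return None, {}, report

    mask = nonwear_mask(recording.data.index, intervals)
    temp = impute_low_temperature(recording.data["temperature"], config.low_temp_c)
    qtemp = average_temp_15min(temp, config.temp_bin_min)

    night_series = []
    summaries = []
    diffs = []
    for w in windows:
        noon = pd.Timestamp(night_window_date(w, config)) + pd.Timedelta(
            hours=config.night_def_start_hour
        )
        if not validate_night(mask, noon, config):
            report.nights_dropped["nonwear_10pct"] = (
                report.nights_dropped.get("nonwear_10pct", 0) + 1
            )
            continue
        ns = extract_night_series(qtemp, w, config)
        if not ns.valid:
            report.nights_dropped[ns.reason] = report.nights_dropped.get(ns.reason, 0) + 1
            continue
        night_series.append(ns)
        summaries.append(summarize_night(ns, config))
        diffs.append(sleep_wake_diff_48h(qtemp, windows, w))
        report.nights_kept += 1

    day_summaries = []
    for day in sorted(set(recording.data.index.date))[:-1]:
        ds = extract_day_series(qtemp, day, config)
        if ds.valid:
            day_summaries.append(summarize_day(ds, config))
            report.days_kept += 1
        else:
            report.days_dropped += 1

    features, extended = aggregate_period(summaries, day_summaries, diffs, night_series, config)
    return features, extended, report


def extract_features(
    recordings: list[Recording],
    sleep_windows: dict[tuple[str, str], list[SleepWindow]],
    night_vars: pd.DataFrame,
    outcomes: OutcomeTable,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[FeatureTable, list[PeriodReport]]:
    """Assemble the canonical per-period feature table.

    Periods failing the valid-day rule are excluded; sex is encoded
    female=1 / male=0.
    """
    rows = {}
    reports = []
    for rec in recordings:
        key = (rec.subject_id, rec.period_id)
        feats, extended, report = temp_features_for_recording(
            rec, sleep_windows.get(key, []), config
        )
        reports.append(report)
        if feats is None:
            continue
        row = dict(feats)
        row.update(extended)
        nv = night_vars[
            (night_vars["subject_id"] == rec.subject_id)
            & (night_vars["period_id"] == rec.period_id)
        ]
        row.update(
            sleep_features_for_period(nv)
            if len(nv)
            else {f: np.nan for f in SLEEP_FEATURES + SLEEP_FEATURES_EXTENDED}
        )
        od = outcomes.data.loc[rec.subject_id]
        row["sex"] = 1.0 if od["sex"] == "f" else 0.0
        row["age"] = float(od["age"])
        rows[key] = row

    columns = (
        ["sex", "age"]
        + TEMP_FEATURES
        + SLEEP_FEATURES
        + TEMP_FEATURES_EXTENDED
        + SLEEP_FEATURES_EXTENDED
    )
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=columns)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["subject_id", "period_id"])
    groups = {"sex": "demographic", "age": "demographic"}
    groups.update({c: "novel" for c in TEMP_FEATURES + SLEEP_FEATURES})
    groups.update({c: "novel_extended" for c in TEMP_FEATURES_EXTENDED + SLEEP_FEATURES_EXTENDED})
    return FeatureTable(df, groups), reports


def default_subsets(table: FeatureTable) -> dict[str, list[str]]:
    """Feature subsets for the subset-model/ensemble design.

    External sleep/PA groups are used when present; otherwise the novel set
    is split into its temperature and sleep families so that the ensemble
    still has several component models.
    """
    subsets: dict[str, list[str]] = {}
    cols = set(table.data.columns)
    for g in ("sleep", "pa"):
        members = table.columns_in_group(g)
        if members:
            subsets[g] = members
    novel = table.columns_in_group("novel")
    if novel:
        subsets["novel"] = novel
        if not subsets.keys() - {"novel"}:
            temp = [c for c in TEMP_FEATURES if c in cols]
            slp = [c for c in SLEEP_FEATURES if c in cols]
            if temp:
                subsets["novel_temp"] = temp
            if slp:
                subsets["novel_sleep"] = slp
    combined = sorted(set().union(*subsets.values())) if subsets else []
    if combined:
        subsets["combined"] = combined
    return subsets


def evaluate_subsets(
    table: FeatureTable,
    y: pd.Series,
    subsets: dict[str, list[str]] | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
    with_ensemble: bool = True,
) -> dict:
    """Selection + LOSO classification per feature subset, then the
    AUC-weighted ensemble.

    For each subset, demographics (sex, age) are appended before selection;
    the selection matrix has one RRCT ranking per held-out subject and is
    merged by voting; logistic models are grown incrementally (top-1,
    top-2, ...) and the feature count maximizing LOSO AUC defines that
    subset's ensemble weight.
    """
    prepared = prepare_features(table)
    df = prepared.data
    ok = y.reindex(df.index).notna()
    df = df.loc[ok]
    yv = y.reindex(df.index).astype(float)
    subject_ids = df.index.get_level_values(0).to_numpy()
    demo = [c for c in ("sex", "age") if c in df.columns]
    if subsets is None:
        subsets = default_subsets(prepared)

    out: dict = {"subsets": {}, "n_samples": int(len(df))}
    probs = {}
    weights = {}
    for name, cols in subsets.items():
        cols = [c for c in cols if c in df.columns]
        if not cols:
            continue
        X = df[list(dict.fromkeys(cols + demo))]
        m_sel = min(config.m_sel, X.shape[1])
        matrix = loso_selection(X, yv.to_numpy(), subject_ids, m_sel)
        voted = vote_features(matrix, m_sel, list(X.columns))
        curve = auc_curve(X, yv.to_numpy(), subject_ids, voted.features, config)
        best_k = int(curve["auc"].idxmax())
        best_auc = float(curve.loc[best_k, "auc"])
        res = loso_fit_predict(X, yv.to_numpy(), subject_ids, voted.features, best_k, config)
        out["subsets"][name] = {
            "voted": voted,
            "selection_matrix": matrix,
            "auc_curve": curve,
            "best_k": best_k,
            "best_auc": best_auc,
            "prob": res.prob,
            "metrics": metrics(res.prob.to_numpy(), yv.to_numpy()),
        }
        probs[name] = res.prob
        weights[name] = best_auc

    # a subset model with zero AUC contributes nothing to Eq-style weighting;
    # drop it rather than pass a non-positive weight
    live = [k for k, w in weights.items() if w > 0]
    probs = {k: probs[k] for k in live}
    weights = {k: weights[k] for k in live}
    if with_ensemble and len(probs) >= 2:
        ens = weighted_ensemble(probs, weights)
        out["ensemble"] = {
            "weights": weights,
            "prob": ens,
            "metrics": metrics(ens.to_numpy(), yv.to_numpy()),
            "auc": float(roc_auc_score(yv.to_numpy(), ens.to_numpy())),
        }
    out["y"] = yv
    return out
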