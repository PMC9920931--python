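"""Outcome encoding, leave-one-subject-out classification, metrics, and the
AUC-weighted probability ensemble.

Classification uses L2-penalized logistic regression; inside every
leave-one-subject-out (LOSO) fold, features are standardized by the
training-fold mean and standard deviation only, so no statistic of the
held-out subject ever reaches the model.  Model subsets (sleep / PA / novel
/ combined) are merged by a weighted-average ensemble whose weights are
each subset model's maximum LOSO AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

from .config import PipelineConfig, DEFAULT_CONFIG
from .io import FeatureTable, OutcomeTable

__all__ = [
    "prepare_features",
    "diagnosis_target",
    "severity_target",
    "loso_fit_predict",
    "auc_curve",
    "weighted_ensemble",
    "metrics",
    "CVResult",
]


def prepare_features(table: FeatureTable, sleep_groups=("sleep", "novel")) -> FeatureTable:
    """Within-subject imputation, then column/row completeness filtering.

    Missing cells are first filled from the same feature in the same
    subject's other wear period(s) (no cross-subject leakage).  Rows whose
    sleep-derived features are entirely missing are dropped; columns still
    containing missing cells after imputation are removed.
    """
    df = table.data.copy()
    subj = df.index.get_level_values(0)
    df = df.groupby(subj, group_keys=False).transform(lambda g: g.fillna(g.mean()))

    sleep_cols = [c for c in df.columns if table.groups[c] in sleep_groups]
    if sleep_cols:
        all_masked = df[sleep_cols].isna().all(axis=1)
        df = df.loc[~all_masked]

    complete = df.columns[df.notna().all(axis=0)]
    df = df[complete]
    return FeatureTable(df, {c: table.groups[c] for c in df.columns})


def diagnosis_target(outcomes: OutcomeTable, index: pd.MultiIndex) -> pd.Series:
    """Binary diagnosis per wear period: stroke = 1, TIA = 0."""
    dx = outcomes.data["diagnosis"]
    subj = index.get_level_values(0)
    return pd.Series((dx.loc[subj] == "stroke").astype(int).to_numpy(), index=index, name="diagnosis")


def severity_target(outcomes: OutcomeTable, index: pd.MultiIndex) -> pd.Series:
    """Stroke-severity group per wear period from the mRS recorded after
    that period: 0 -> class 0, above 0 -> class 1.  Baseline mRS is never
    used."""
    vals = []
    for sid, pid in index:
        col = f"mrs_after{pid}"
        mrs = outcomes.data.at[sid, col] if col in outcomes.data.columns else np.nan
        vals.append(np.nan if pd.isna(mrs) else float(mrs > 0))
    return pd.Series(vals, index=index, name="severity")


@dataclass
class CVResult:
    """Held-out probabilities from a LOSO run."""

    prob: pd.Series          # one held-out probability per sample
    fold: pd.Series          # fold id (held-out subject) per sample
    features: list[str]


def loso_fit_predict(
    X: pd.DataFrame,
    y,
    subject_ids,
    features: list[str],
    k: int | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> CVResult:
    """LOSO logistic regression on the top-k features.

    Every fold standardizes train and test by the training-fold mean/sd and
    fits ``LogisticRegression(penalty="l2", C=config.logreg_c)``.  A training
    fold with a single class aborts loudly, naming the held-out subject.
    """
    feats = features if k is None else features[:k]
    subject_ids = np.asarray(subject_ids)
    y = np.asarray(y, dtype=float)
    Xv = X[feats].to_numpy(dtype=float)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("loso_fit_predict requires complete features")
    prob = np.full(len(y), np.nan)
    fold = np.empty(len(y), dtype=object)
    for s in pd.unique(subject_ids):
        test = subject_ids == s
        train = ~test
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"training fold holding out subject {s!r} has a single class")
        mu = Xv[train].mean(axis=0)
        sd = Xv[train].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        # L2 penalty is sklearn's default; strength via C
        clf = LogisticRegression(C=config.logreg_c, solver="lbfgs", max_iter=1000)
        clf.fit((Xv[train] - mu) / sd, y_tr)
        prob[test] = clf.predict_proba((Xv[test] - mu) / sd)[:, 1]
        fold[test] = s
    return CVResult(
        prob=pd.Series(prob, index=X.index, name="prob"),
        fold=pd.Series(fold, index=X.index, name="fold"),
        features=list(feats),
    )


def auc_curve(
    X: pd.DataFrame,
    y,
    subject_ids,
    voted_features: list[str],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """LOSO AUC for models using the top-1, top-2, ... voted features.

    Returns a frame indexed by k with columns ``auc``; the best feature
    count is ``frame["auc"].idxmax()`` (smallest k on ties)."""
    rows = []
    for k in range(1, len(voted_features) + 1):
        res = loso_fit_predict(X, y, subject_ids, voted_features, k=k, config=config)
        rows.append({"k": k, "auc": roc_auc_score(np.asarray(y), res.prob.to_numpy())})
    return pd.DataFrame(rows).set_index("k")


def weighted_ensemble(probs: dict[str, pd.Series], weights: dict[str, float]) -> pd.Series:
    """Weighted average of per-subset probabilities:
    p_i = sum_j w_j p_{i,j} / sum_j w_j.

    All subsets must cover identical samples and weights must be positive.
    """
    keys = list(probs)
    if not keys:
        raise ValueError("no component models")
    base = probs[keys[0]].index
    for j in keys[1:]:
        if not probs[j].index.equals(base):
            raise ValueError(f"component {j!r} covers different samples")
    w = np.array([weights[j] for j in keys], dtype=float)
    if (w <= 0).any():
        raise ValueError("ensemble weights must be positive")
    stacked = np.column_stack([probs[j].to_numpy() for j in keys])
    return pd.Series(stacked @ w / w.sum(), index=base, name="ensemble_prob")


def metrics(prob, y, threshold: float = 0.5) -> dict:
    """AUC (rank-based, ties averaged), ROC points, balanced accuracy and the
    confusion matrix at the given probability threshold."""
    prob = np.asarray(prob, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("metrics require both classes present")
    fpr, tpr, _ = roc_curve(y, prob)
    pred = (prob >= threshold).astype(float)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "auc": float(roc_auc_score(y, prob)),
        "roc": np.column_stack([fpr, tpr]),
        "balanced_accuracy": 0.5 * (sens + spec),
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }
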