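"""Feature ranking and fold-aggregated selection.

Features are ranked by a relevance-redundancy-complementarity trade-off
(RRCT): a greedy forward search where each step adds the candidate
maximizing

    score = relevance(c; y) - redundancy(c; selected)
            + complementarity(c; selected, y)

with all three terms built from Spearman correlations mapped through the
Gaussian mutual-information transform I(rho) = -1/2 ln(1 - rho^2);
complementarity uses the first-order partial correlation of the candidate
with the target given each already-selected feature.  Ranking is repeated
inside a leave-one-subject-out loop and the per-fold rankings are merged
with a voting scheme; a per-feature stability score records the percentage
of folds in which the feature was selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rrct_rank", "loso_selection", "vote_features", "VotedSubset"]

_RHO_CLIP = 0.999999


def _gauss_mi(rho: np.ndarray) -> np.ndarray:
    rho = np.clip(rho, -_RHO_CLIP, _RHO_CLIP)
    return -0.5 * np.log1p(-rho**2)


def _spearman_matrix(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman correlations among features and with the target, computed as
    Pearson on ranks; constant columns get correlation 0."""
    ranks = stats.rankdata(np.column_stack([X, y]), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(ranks, rowvar=False)
    c = np.nan_to_num(c, nan=0.0)
    return c[:-1, :-1], c[:-1, -1]


def _partial(r_cy: float, r_cs: float, r_sy: float) -> float:
    den = np.sqrt(max((1 - r_cs**2) * (1 - r_sy**2), 1e-12))
    return float(np.clip((r_cy - r_cs * r_sy) / den, -_RHO_CLIP, _RHO_CLIP))


def _rrct_scores(
    cand: np.ndarray, selected: list[int], rff: np.ndarray, rfy: np.ndarray
) -> np.ndarray:
    """Greedy step score for each candidate index; the single place where
    the relevance/redundancy/complementarity arithmetic lives."""
    relevance = _gauss_mi(rfy[cand])
    if not selected:
        return relevance
    redundancy = _gauss_mi(rff[np.ix_(cand, selected)]).mean(axis=1)
    comp = np.empty(len(cand))
    for k, c in enumerate(cand):
        gains = [
            _gauss_mi(np.array(_partial(rfy[c], rff[c, s], rfy[s]))) for s in selected
        ]
        comp[k] = float(np.mean(gains)) - relevance[k]
    return relevance - redundancy + comp


def rrct_rank(X: pd.DataFrame, y, m_sel: int | None = None) -> list[str]:
    """Rank features by greedy RRCT; returns the top ``m_sel`` column names
    in descending order of selection."""
    cols = list(X.columns)
    m_sel = len(cols) if m_sel is None else min(m_sel, len(cols))
    Xv = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("rrct_rank requires a complete (no-missing) matrix")
    rff, rfy = _spearman_matrix(Xv, yv)
    selected: list[int] = []
    remaining = list(range(len(cols)))
    while remaining and len(selected) < m_sel:
        cand = np.array(remaining)
        scores = _rrct_scores(cand, selected, rff, rfy)
        best = int(cand[int(np.argmax(scores))])  # argmax ties -> lowest index
        selected.append(best)
        remaining.remove(best)
    return [cols[i] for i in selected]


def loso_selection(X: pd.DataFrame, y, subject_ids, m_sel: int) -> pd.DataFrame:
    """One RRCT ranking per held-out subject.

    Returns the selection matrix: one row per left-out subject (index), one
    column per rank (1..m_sel), cells holding feature names.
    """
    subject_ids = np.asarray(subject_ids)
    y = np.asarray(y)
    subjects = pd.unique(subject_ids)
    if len(subjects) < 3:
        raise ValueError("leave-one-subject-out selection needs >= 3 subjects")
    rows = {}
    for s in subjects:
        keep = subject_ids != s
        if not keep.any():
            raise ValueError(f"subject {s!r} owns every sample")
        rows[s] = rrct_rank(X.loc[keep], y[keep], m_sel)
    return pd.DataFrame.from_dict(rows, orient="index", columns=range(1, m_sel + 1))


@dataclass
class VotedSubset:
    """Fold-aggregated feature subset with per-feature stability scores."""

    features: list[str]
    stability: dict[str, float]  # % of folds selecting the feature anywhere


def vote_features(matrix: pd.DataFrame, m_sel: int, feature_order: list[str]) -> VotedSubset:
    """Aggregate per-fold rankings into one ordered subset.

    For i = 1..m_sel, the feature occurring most frequently within the first
    i columns across all folds is appended if not already chosen (otherwise
    the most frequent not-yet-chosen feature); ties break to the feature
    appearing earlier in ``feature_order`` (the canonical column order).
    The result is invariant to fold/row order.
    """
    pos = {f: i for i, f in enumerate(feature_order)}
    chosen: list[str] = []
    ncols = matrix.shape[1]
    for i in range(1, min(m_sel, ncols) + 1):
        counts: dict[str, int] = {}
        for col in matrix.columns[:i]:
            for f in matrix[col]:
                if pd.notna(f):
                    counts[f] = counts.get(f, 0) + 1
        candidates = [f for f in counts if f not in chosen]
        if not candidates:
            continue
        best = min(candidates, key=lambda f: (-counts[f], pos.get(f, len(pos))))
        chosen.append(best)
    n_folds = len(matrix)
    stability = {
        f: 100.0 * sum(f in matrix.loc[r].values for r in matrix.index) / n_folds
        for f in chosen
    }
    return VotedSubset(chosen, stability)
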