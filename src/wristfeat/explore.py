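"""Exploratory association screen between features and questionnaire
outcomes.

Per questionnaire and wear period three derived outcomes are formed: the
value after the period ("after"), the change from the previous assessment
("change"), and the change from baseline ("diff_base"); PHQ-2, administered
only at baseline and after the first period, is passed through unmodified.
Associations are screened with pairwise-complete Spearman correlations and
flagged as strong (|rho| > 0.3) and/or significant (p < 0.05, two-sided
t approximation).  No multiple-testing correction is applied — the screen is
exploratory — but the number of tests is reported so readers can correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig, DEFAULT_CONFIG
from .io import FeatureTable, OutcomeTable

__all__ = ["derive_outcomes", "spearman_screen", "CorrelationReport", "plot_heatmap"]

_QUESTIONNAIRES = ("mrs", "gad7", "fq_ag", "fq_soc", "fq_sp")


def derive_outcomes(outcomes: OutcomeTable, periods: tuple[str, ...] = ("1", "2")) -> pd.DataFrame:
    """Per-(subject, period) derived questionnaire outcomes.

    Missing operands propagate to missing derived values.
    """
    od = outcomes.data
    rows = []
    for sid in od.index:
        for p in periods:
            row: dict = {"subject_id": sid, "period_id": p}
            for q in _QUESTIONNAIRES:
                base = od.at[sid, f"{q}_baseline"] if f"{q}_baseline" in od else np.nan
                after = od.at[sid, f"{q}_after{p}"] if f"{q}_after{p}" in od else np.nan
                if p == "1":
                    prev = base
                else:
                    prev_col = f"{q}_after{int(p) - 1}"
                    prev = od.at[sid, prev_col] if prev_col in od else np.nan
                row[f"{q}_after"] = after
                row[f"{q}_change"] = after - prev if pd.notna(after) and pd.notna(prev) else np.nan
                row[f"{q}_diff_base"] = after - base if pd.notna(after) and pd.notna(base) else np.nan
            # PHQ-2: two timepoints only, passed through on period-1 rows
            if p == "1":
                row["phq2_baseline"] = od.at[sid, "phq2_baseline"] if "phq2_baseline" in od else np.nan
                row["phq2_after1"] = od.at[sid, "phq2_after1"] if "phq2_after1" in od else np.nan
            else:
                row["phq2_baseline"] = np.nan
                row["phq2_after1"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows).set_index(["subject_id", "period_id"])


@dataclass
class CorrelationReport:
    """Feature x outcome grids of Spearman rho, p-value, and flags."""

    rho: pd.DataFrame
    pval: pd.DataFrame
    strong: pd.DataFrame
    significant: pd.DataFrame
    n_tests: int

    def filtered(self) -> pd.DataFrame:
        """Rho grid restricted to rows and columns with at least one
        significant cell (heatmap view); filtering is per cell."""
        keep_rows = self.significant.any(axis=1)
        keep_cols = self.significant.any(axis=0)
        return self.rho.loc[keep_rows, keep_cols]


def spearman_screen(
    features: FeatureTable | pd.DataFrame,
    derived: pd.DataFrame,
    config: PipelineConfig = DEFAULT_CONFIG,
    min_pairs: int = 5,
) -> CorrelationReport:
    """Pairwise-complete Spearman correlation of every feature against every
    derived outcome; cells with fewer than ``min_pairs`` paired observations
    are missing."""
    fdf = features.data if isinstance(features, FeatureTable) else features
    common = fdf.index.intersection(derived.index)
    fdf = fdf.loc[common]
    ddf = derived.loc[common]
    rho = pd.DataFrame(index=fdf.columns, columns=ddf.columns, dtype=float)
    pval = rho.copy()
    n_tests = 0
    for fc in fdf.columns:
        fv = fdf[fc].to_numpy(dtype=float)
        for oc in ddf.columns:
            ov = ddf[oc].to_numpy(dtype=float)
            ok = np.isfinite(fv) & np.isfinite(ov)
            if ok.sum() < min_pairs:
                continue
            r, p = stats.spearmanr(fv[ok], ov[ok])
            if np.isnan(r):
                continue
            rho.at[fc, oc] = r
            pval.at[fc, oc] = p
            n_tests += 1
    strong = rho.abs() > config.spearman_strong
    significant = pval < config.spearman_alpha
    return CorrelationReport(rho, pval, strong, significant, n_tests)


def plot_heatmap(report: CorrelationReport, path) -> None:
    """Labelled heatmap of the significance-filtered correlation grid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = report.filtered()
    fig, ax = plt.subplots(figsize=(2 + 0.4 * grid.shape[1], 1 + 0.3 * grid.shape[0]))
    if grid.size:
        im = ax.imshow(grid.to_numpy(dtype=float), cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(grid.shape[0]), grid.index, fontsize=7)
        fig.colorbar(im, ax=ax, label="Spearman rho")
    ax.set_title(
        "Feature-outcome Spearman correlations\n"
        "(cells filtered to rows/columns with >= 1 significant correlation)",
        fontsize=8,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
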