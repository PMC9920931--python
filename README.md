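# wristfeat

Sleep and wrist-temperature feature engineering for wrist-worn wearable
recordings, with leave-one-subject-out classification of clinical labels.

Modern wrist devices (GENEActiv-class) record tri-axial acceleration, wrist
skin temperature and ambient light continuously for weeks.  In stroke and
TIA cohorts, passively collected recordings of this kind may carry clinical
signal — about circadian regulation, sleep habits and day-to-day behaviour —
that questionnaires miss.  `wristfeat` is for researchers who have such
epoch-level recordings (plus externally detected sleep windows and
questionnaire outcomes) and want a reproducible path from raw epochs to:

* a per-wear-period table of **novel sleep and temperature features** —
  between-night variability of the nightly mean wrist temperature,
  within-sleep dispersion (sd, IQR), timing of in-sleep temperature extrema
  and of the maximum 15-min warming/cooling rates, normalized approximate
  entropy of sleep temperature, the 48-h sleep–wake temperature contrast,
  weekend–weekday sleep-duration difference, percentage of pre-midnight
  sleep onsets, and per-period trends of sleep variables;
* **feature selection** by a relevance–redundancy–complementarity (RRCT)
  ranking inside a leave-one-subject-out (LOSO) loop, merged across folds by
  a voting scheme with per-feature stability scores;
* **LOSO logistic-regression models** (fold-wise standardization, L2
  penalty, incremental feature counts, AUC / balanced accuracy) and an
  **AUC-weighted probability ensemble** over feature subsets,
  p̂ᵢ = Σⱼ wⱼ pᵢⱼ / Σⱼ wⱼ with wⱼ each subset model's best LOSO AUC;
* an exploratory **Spearman screen** of features against questionnaire
  deltas (|ρ| > 0.3 flagged strong, p < 0.05 significant).

The core regularity statistic is approximate entropy,
ApEn(m, r, K) = Φᵐ(r) − Φᵐ⁺¹(r) with Chebyshev template matching, m = 2 and
r = 0.2·sd(x), normalized by series length.  Signal conditioning follows
the standard actigraphy rules: ENMONZ activity summary; non-wear from
stillness (sd < 13 mg or range < 50 mg on ≥ 2 axes over 60-min windows);
valid days ≥ 16 h wear, usable periods ≥ 7 valid days; noon-to-noon nights
with > 10% non-wear excluded; sub-24 °C temperatures interpolated;
quarter-hour temperature averaging with a 7-point moving average.
`docs/methods.md` documents every rule, convention and default.

Because no clinical recordings ship with the package, a first-class
synthetic-cohort generator (`wristfeat.synthetic`) produces multi-day
multimodal recordings with planted, recoverable structure — circadian
temperature cycles, sleep plateaus, group differences in nightly
temperature variability and entropy, sleep-variable trends, non-wear
episodes, and outcomes linearly coupled to the planted parameters — so the
entire pipeline is testable end to end.

## Worked example

```bash
wristfeat simulate --out cohort --subjects 8 --periods 2 --days 10 --seed 42
wristfeat features --recordings cohort/recordings \
    --sleep cohort/sleep_windows.csv --night-vars cohort/night_vars.csv \
    --outcomes cohort/outcomes.csv --out features.csv
wristfeat select --features features.csv --outcomes cohort/outcomes.csv \
    --target diagnosis --group novel --msel 5 --out selection
wristfeat model  --features features.csv --outcomes cohort/outcomes.csv \
    --target diagnosis --out model
```

which prints

```
wrote 16 recordings to cohort
16 periods x 37 features (0 periods dropped by the valid-day rule)
std_temp_mean  (88%)
mean_apen_sleep  (75%)
mean_temp_iqr  (25%)
std_time_temp_min  (62%)
std_time_temp_max  (38%)
{
  "novel": {"best_k": 7, "best_auc": 0.9167, "balanced_accuracy": 0.7833},
  "novel_temp": {"best_k": 1, "best_auc": 0.9, "balanced_accuracy": 0.7833},
  "novel_sleep": {"best_k": 3, "best_auc": 0.55, "balanced_accuracy": 0.4667},
  "combined": {"best_k": 3, "best_auc": 0.9167, "balanced_accuracy": 0.7833},
  "ensemble": {"auc": 0.8833,
               "weights": {"novel": 0.9167, "novel_temp": 0.9,
                           "novel_sleep": 0.55, "combined": 0.9167}}
}
```

Reading: the voted top novel features are led by `std_temp_mean` — the
standard deviation over nights of the mean sleep temperature, which the
generator plants as the group-separating quantity (0.9 °C TIA vs 0.5 °C
stroke) — selected in 88% of LOSO folds.  The novel-feature model reaches
its best LOSO AUC (0.917) at 7 features; the temperature half alone
achieves 0.90 with a single feature; the sleep half is near chance on this
small cohort, and the ensemble weights each subset by its best AUC.  The
same commands accept `--target severity` (disability group, mRS 0 vs > 0),
and `wristfeat explore` writes the feature × outcome Spearman grid
(here: `34 significant of 629 tested cells`).

The identical analysis is available as a library:

```python
from wristfeat import CohortSpec, generate_cohort, extract_features, evaluate_subsets
from wristfeat.models import diagnosis_target

cohort = generate_cohort(CohortSpec(n_subjects=8, days_per_period=10, seed=42))
table, reports = extract_features(cohort.recordings, cohort.sleep_windows,
                                  cohort.night_vars, cohort.outcomes)
result = evaluate_subsets(table, diagnosis_target(cohort.outcomes, table.data.index))
```

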