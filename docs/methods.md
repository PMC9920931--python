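# Methods

`wristfeat` turns epoch-level wrist-worn sensor recordings (tri-axial
acceleration, wrist skin temperature, ambient light) into a per-wear-period
feature table, and maps selected features onto binary clinical labels with
leave-one-subject-out (LOSO) logistic regression.  This note documents the
model, every tunable that matters, the synthetic-data generator, and the
numerical conventions — including the places where the design was genuinely
open and a choice had to be made.

## 1. Data model

A *recording* is one subject's wear period: uniformly spaced epochs
(default 60 s) carrying calibrated acceleration in g, wrist temperature in
degC, and optionally light in lux.  *Sleep windows* (onset/offset per
night) come from an external sleep-detection tool — estimating them from
accelerometry is explicitly out of scope — or from the synthetic generator.
An *outcome table* holds per-subject demographics, diagnosis (stroke vs
TIA), and questionnaire scores (mRS 0–5, GAD-7 0–21, PHQ-2 0–6, FQ
subscores 0–40) at baseline and after each wear period; PHQ-2 exists only
at baseline and after the first period.

All clock rules below are wall-clock rules; timestamps with explicit UTC
offsets are reduced to local civil time on read.

## 2. Signal conditioning

| rule | default | unit | note |
|---|---|---|---|
| non-wear sd threshold | 13 | mg | per axis, 60-min window |
| non-wear range threshold | 50 | mg | per axis, 60-min window |
| axes required | 2 of 3 | – | sd *or* range criterion per axis |
| block / window | 15 / 60 | min | blocks aligned to :00/:15/:30/:45 |
| valid day | ≥ 16 | h wear | inclusive (see below) |
| usable period | ≥ 7 | valid days | |
| invalid night | > 10% | non-wear | nights are noon-to-noon |
| low-temperature cut | 24 | degC | linear interpolation |
| temperature binning | 15 | min | mean per bin |
| smoothing | q = 3 (l = 7) | points | centred moving average |

**ENMONZ** is `max(0, sqrt(x²+y²+z²) − 1)` in mg — the Euclidean norm of
acceleration minus one gravity, negatives clipped (sensor noise).

**Non-wear** classifies each quarter-hour block from the 60-min window
centred on its midpoint; a block is non-wear when ≥ 2 axes are still
(sd < 13 mg or range < 50 mg).  Adjacent flagged blocks are merged first,
then non-wear activity epochs on valid days are imputed from the mean of
same-clock-time epochs on other worn days (no donor → left missing).  The
detector is structurally blind to roughly the first and last 15 min of an
off-wrist episode: a window mixing still and worn epochs is dominated by
wake variance.  This matters for validation design (Section 8) but not for
the day/night filters, whose margins are hours.

**Open readings resolved**: the valid-day rule appears both as "> 16 h" and
"at least 16 h" in the source descriptions; the inclusive reading is used
(`valid_day_hours: 16, inclusive: true` in config).  The night/day
coverage thresholds 61 (of 77 quarter-hour points, 19:00–14:00) and 77 (of
97 points, 08:00–08:00) are taken at face value even though they are not
exactly 80% of the window sizes.  Non-wear blocks are merged before
imputation.

**Temperature chain**: sub-24 degC runs are linearly interpolated between
the nearest flanking readings ≥ 24 degC; leading/trailing runs have no
anchor and stay missing — extrapolation would fabricate data.  Temperatures
are then averaged into quarter-hour bins, and each extracted night/day
series is smoothed with a 7-point centred moving average whose window is
clipped at the series bounds (partial-window mean), preserving series
length and hence the 97-point day and the 4·h+1-point night counts.

**Night series**: sleep onset is rounded down and offset rounded up to the
quarter hour; both boundary bins are included (closed interval), so an
h-hour sleep yields 4·h+1 points.  A night is dropped when its 19:00–14:00
window has fewer than 61 non-missing bins or fewer than 15 non-missing
bins lie within the sleep window.  Residual missing bins inside a
surviving night are linearly interpolated (edges padded with the nearest
value) before smoothing and entropy; the count of filled bins is kept on
the series object.

## 3. Approximate entropy

ApEn(m, r, K) = Φ^m(r) − Φ^{m+1}(r), where Φ^m is the mean natural log of
the fraction of m-length templates within Chebyshev distance r of each
template.  Conventions: self-matches are counted (keeps the log defined),
the log is natural, sd uses the (K−1)-denominator sample convention, and
the default parameterization is m = 2, r = 0.2·sd(x).  A constant series
returns 0 under the relative tolerance.  Per-night and per-day entropies
are normalized by the series length (ApEn/K) so longer nights do not score
higher mechanically; the all-nights entropy is ApEn of the concatenated
night series divided by the total point count.

## 4. Feature inventory

The canonical **temperature set (19 features)** per wear period, computed
over valid nights i (mean T_i, sd S_i of the smoothed in-sleep series) and
valid 08:00–08:00 days:

1. `std_temp_mean` — sd of {T_i} (absolute temperature level is never a
   feature; strap tightness and environment confound it)
2–3. `mean_temp_std`, `std_temp_std` — mean/sd of {S_i}
4–5. `mean_temp_iqr`, `std_temp_iqr` — mean/sd of the in-sleep IQR
6–7. `std_time_temp_min`, `std_time_temp_max` — sd of the clock time
   (hours since 08:00) of the daily minimum/maximum
8–9. `mean/std_hrs_before_wake_temp_min` — timing of the in-sleep minimum
10–11. `mean/std_hrs_after_onset_temp_max` — timing of the in-sleep maximum
12–15. `mean/std_time_mroi`, `mean/std_time_mrod` — timing of the maximum
   15-min rate of temperature increase/decrease during sleep
16. `mean_apen_sleep` — mean normalized per-night ApEn
17. `apen_sleep_all_nights` — normalized ApEn of all nights concatenated
18. `temp_min_max_diff` — mean daily max−min range
19. `mean_sleep_wake_diff` — mean 48-h sleep−wake temperature contrast
   (each 48-h span starts at 00:00 on the day of that night's onset)

The canonical **sleep set (6 features)**: `we_wd_sleep_diff` (mean weekend
minus weekday sleep duration; a night is "weekend" when its wake-up falls
on Saturday/Sunday — the free-day convention of social-jetlag work),
`pct_onset_before_midnight`, and the Pearson trends of SPT duration,
daytime sustained-inactivity duration, number of sleep periods, and sleep
efficiency against the available-night index.

The published description of this feature family is internally
inconsistent about counts: the summary table says 19 temperature + 6 sleep
features, while the prose enumerates more summary statistics (sd of the
nightly ApEn, mean/sd of 24-h ApEn, sd of the sleep–wake contrast, trends
of onset and offset time).  This package fixes the enumeration above as
the canonical 25 — it covers every feature that actually appears in the
family's reported results — and emits the remainder under the group
`novel_extended` (eight extra temperature summaries, two extra trends), so
no described quantity is lost.  Selection and modelling over the group
"novel" use only the canonical 25.

Timing conventions: extrema and rate winners break ties to the earliest
occurrence; MROI/MROD timing is the end of the winning 15-min interval, in
hours after (rounded) onset; clock-time sds use linear statistics on
hours-since-08:00 rather than circular statistics, staying close to a plain
"standard deviation of the time" and avoiding wraparound inside the
08:00–08:00 day.  In-sleep minimum timing is stored relative to waking and
maximum timing relative to onset (matching how these quantities are
reported); the complements are emitted in the extended group.

Degenerate inputs: sd-type features need ≥ 2 valid nights (or days) and
are otherwise missing; mean-type features need ≥ 1; trends need ≥ 3 nights
and a non-constant variable; the weekend contrast needs at least one night
of each class.

## 5. Feature selection

RRCT (relevance–redundancy–complementarity trade-off) ranks features
greedily.  With all correlations Spearman (Pearson on ranks) and
I(ρ) = −½ ln(1−ρ²) the Gaussian mutual-information transform, step k adds
the candidate c maximizing

    I(ρ(c, y)) − mean_{s∈S} I(ρ(c, s)) + mean_{s∈S} [ I(ρ(c, y | s)) − I(ρ(c, y)) ]

where S is the selected set and ρ(c, y | s) the first-order partial
correlation.  Constant features get zero relevance and never block a run.
All scoring lives in a single function so an alternative scheme can be
swapped without touching the LOSO loop.

Selection runs once per LOSO fold (leave out all samples of one subject,
rank on the rest), giving an n-subjects × M_sel matrix.  The voting scheme
merges it: for i = 1..M_sel, count occurrences over the first i columns of
all rows and append the most frequent feature not yet chosen; ties break
to the earlier column in the canonical feature order.  When the raw winner
is already chosen, the best *unchosen* feature is appended — otherwise
slots could go unfilled.  The per-feature stability score is the
percentage of folds whose ranking contains the feature anywhere.
M_sel defaults to 10.  Demographics (sex, age) are appended to every
subset before selection.

## 6. Classification and ensembling

Targets: diagnosis (stroke = 1, TIA = 0) and the stroke-severity group
(mRS after the wear period: 0 vs > 0; baseline mRS is never an input).
Before modelling, missing cells are imputed within subject (from the same
feature in the subject's other period), rows whose sleep-derived features
are entirely missing are dropped, and columns still containing missing
values are removed.

Inside every LOSO fold, the training-fold mean and sd standardize both
train and test, and an L2-penalized logistic regression is fit
(inverse-regularization C = 1.0, the common default, exposed in config;
lbfgs, deterministic).  Features are added incrementally (top-1, top-2,
…, top-M_sel) and the per-k LOSO AUC curve is reported; the best k is the
argmax (smallest k on ties).  Balanced accuracy and confusion matrices use
a 0.5 probability threshold.  A training fold with a single class aborts
loudly, naming the held-out subject — at small n a silent skip would bias
results.

The per-subset models (sleep / PA / novel / combined when external feature
groups are supplied; otherwise novel, its temperature and sleep halves,
and combined) are merged by a weighted average of held-out probabilities,
p̂_i = Σ_j w_j p_{i,j} / Σ_j w_j, with w_j the subset's maximum LOSO AUC.
The output is a convex combination of its components by construction.
A subset whose best AUC is zero (possible only at degenerate desk scales)
is dropped rather than given a non-positive weight.

## 7. Exploratory association screen

Per questionnaire and period, three derived outcomes: value after the
period, change from the previous assessment, and change from baseline;
PHQ-2 passes through unmodified at its two timepoints.  Every feature ×
outcome pair gets a pairwise-complete Spearman ρ (≥ 5 pairs required) with
a two-sided p from the t approximation, appropriate at the n ≈ 40 regime
this screen targets.  Flags: *strong* when |ρ| > 0.3, *significant* when
p < 0.05.  No multiple-testing correction is applied — the screen is
exploratory by design — but the number of tests is reported so a reader
can Bonferroni.  The heatmap view filters per cell: rows/columns with at
least one significant cell are kept.

## 8. Synthetic cohorts

The generator exists so that every downstream stage is testable with known
ground truth; no field data ship with the package.

**Temperature**: per-subject baseline ~ N(33.2, 0.4) degC, a 24-h cosine
(amplitude 0.5 degC, peak 04:00 — distal skin temperature peaks at night),
a sleep plateau of +1.2 degC with 30-min ramps at onset/offset, a planted
per-night level shift δ_i ~ N(0, σ_subject) applied flat across the sleep
window, and AR(1) noise (sd 0.12 degC, φ = 0.95 at 60 s).  σ_subject is
drawn per subject from N(level_group, 0.2) with default group levels 0.5
(stroke) vs 0.9 (TIA) degC — the planted quantity that `std_temp_mean`
estimates.  Within-sleep noise is multiplied by a per-group irregularity
scale (default 1.3 stroke vs 1.0 TIA), planting the elevated sleep-
temperature entropy reported for stroke cohorts.

**Sleep schedule**: onset ~ N(23:00 + subject shift, 0.75 h) clamped to
the 19:00–14:00 night window; duration ~ N(8, 0.75) h plus a per-subject
drift (slope sd 0.03 h/night — about ±0.6 h over three weeks, the planted
"trend") and a weekend surplus (subject mean 0.5 h, sd 0.3 h).  Night
variables (SIBD duration, number of sleep periods, sleep efficiency) get
their own baselines and correlated drifts; the number-of-sleep-periods
drift is coupled to the duration drift (1.3×), mirroring their positive
association.

**Non-wear**: Poisson episodes (default 0.3/day, daytime, 0.5–6 h,
quarter-hour aligned): acceleration freezes at its last value and
temperature decays exponentially toward 21 degC ambient (τ = 10 min), so a
single mechanism exercises both the stillness rule and the 24-degC rule.

**Acceleration**: unit-gravity orientation plus per-axis epoch-scale
jitter — 25 mg awake, 18 mg asleep — plus occasional activity bouts.  The
series is epoch-level (60 s means), not raw 10–100 Hz: every in-scope
computation operates at epoch/15-min scale, so raw-rate simulation would
add cost without exercising anything.  Jitter levels are set so ordinary
wake/sleep never trips the 13 mg/50 mg stillness rule while frozen
non-wear always does.

**Outcomes** are linear in planted parameters plus Gaussian noise, so the
expected sign of every exploratory correlation is analytic: higher
between-night temperature variability → lower (better) mRS; positive
sleep-duration/sleep-period trends → lower GAD-7 after wear; larger
weekend sleep surplus → higher specific-phobia scores.  mRS baseline and
after-period values share a latent, giving the strong baseline–outcome
correlation typical of such cohorts.  `outcome_effect` scales all
couplings (0 = null cohort).

All randomness flows from one integer seed through spawned
`SeedSequence` streams; the schedule/outcome streams are separate from the
signal stream, so cohorts regenerated without signals are identical in
their windows, night variables, outcomes and truth.

**What the generator does not emulate**: raw-rate accelerometry and
device calibration error; postural/behavioural temperature artifacts
beyond the non-wear mechanism; light beyond a day/night square wave;
missing questionnaires; any nonlinear feature–outcome structure.  Passing
tests on these cohorts demonstrates that the *pipeline* recovers planted
structure under its stated rules — not that the features carry clinical
signal in real cohorts.

## 9. Validation scales and calibrations

These constants were fixed from the model (analytically or by Monte-Carlo
sweeps of the generator itself) before being frozen into tests.

* **Discrimination/recovery experiment**: 60 subjects × 21 days × 20
  seeds, group σ levels 0.5 vs 0.845 degC with between-subject sd 0.2.
  With ~20 nights the sample sd of nightly means carries sampling noise
  σ/√(2·19), giving a pooled extracted-feature sd ≈ 0.23 and an
  extracted-scale group gap of 1.50 pooled sd.  The feature recovers the
  planted levels up to a ~5–8% attenuation: the outward rounding of
  onset/offset means boundary bins average unshifted wake epochs — a
  property of the measurement convention, covered by the Monte-Carlo
  tolerance in the tests.
* **Permutation null**: LOSO is pessimistically biased under label
  permutation — the held-out subject's label anti-correlates with the
  training-fold class prior, and with strong shrinkage the intercept
  alone drives AUC below 0.5.  Measured null means are ~0.43 at 25
  subjects and ~0.46 at 60 subjects (10 features); the null experiment is
  therefore run at 60 subjects, where residual bias is small against the
  0.45–0.55 acceptance band.  Optimistic leakage would move the mean the
  other way; the outlier-injection check guards leakage independently of
  scale.
* **Non-wear fidelity fixture**: one 16-h planted episode in a 9-day
  recording.  Because the detector cannot see ~15 min at each episode
  edge (Section 2), minute-level recall ≥ 95% is only geometrically
  attainable for episodes of many hours; 16 h (a day off-wrist) yields a
  deterministic 96.9% recall and exercises the valid-day and valid-night
  filters with exact intended counts (8 of 9 days, 7 of 10 nights).
* **Problem sizes in the test suite** are desk-scale: cohorts of 6–60
  subjects, 7–21 days, chosen as the smallest sizes at which each planted
  effect is resolvable with comfortable margin.

## 10. Known limitations

* The RRCT scoring follows the published description of the algorithm
  family (correlation-based relevance/redundancy with partial-correlation
  complementarity); exact numerical agreement with other implementations
  is not claimed, and the scoring function is isolated so it can be
  swapped.
* The L2 strength, classification threshold and ApEn log base are
  conventions (C = 1, 0.5, natural log) exposed in config, not fitted.
* The sleep–wake 48-h contrast and the day summaries use the quarter-hour
  series; nights/days failing coverage are silently absent from period
  aggregates (by design, with counts in the filter report).
* Severity modelling at very small n can produce single-class training
  folds; the pipeline aborts loudly rather than skipping.
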