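"""Synthetic multimodal cohorts with known planted structure.

Emulates the data regime of a two-arm wrist-wearable stroke/TIA study:
per subject, one or two multi-day wear periods of epoch-level tri-axial
acceleration (g), wrist temperature (degC) and ambient light (lux), plus
per-night sleep windows, per-night sleep variables (as an external sleep
detector would provide), and questionnaire outcomes.

The temperature model is a baseline plus 24-h sinusoid plus a night-time
plateau (distal skin temperature rises during sleep) plus AR(1) noise; each
night additionally receives a planted mean-level shift drawn with a
per-subject, group-dependent standard deviation — the quantity the
"std. of temp. mean" feature estimates.  Non-wear is simulated as frozen
acceleration with exponential temperature decay toward ambient, which
triggers both the stillness rule and the sub-24-degC rule at once.
Outcomes are linear in planted per-subject parameters plus Gaussian noise,
so the expected sign of every exploratory correlation is known.

All randomness flows from a single integer seed through spawned
``numpy.random.SeedSequence`` streams; identical (spec, seed) gives
byte-identical cohorts, and the signal stream is separate from the
schedule/outcome streams so sleep-and-outcome-only generation
(``signals=False``) matches the full run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import OutcomeTable, Recording, SleepWindow

__all__ = [
    "CohortSpec",
    "RecordingParams",
    "CohortData",
    "SyntheticTruth",
    "generate_cohort",
    "generate_recording",
    "nonwear_validation_recording",
]

PERIOD_STARTS = {"1": pd.Timestamp("2023-03-06"), "2": pd.Timestamp("2023-05-08")}  # Mondays


class ConfigurationError(ValueError):
    """Invalid cohort specification; the message names the field."""


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    ``temp_sd_of_mean`` sets, per diagnosis group, the mean of the
    per-subject between-night temperature-level standard deviation (degC);
    ``temp_apen_scale`` multiplies within-sleep noise (temperature
    irregularity); ``trend_slope`` is the between-subject sd of the
    per-night sleep-duration drift (h/night); ``outcome_effect`` scales the
    linear coupling of planted parameters into questionnaire scores.
    """

    n_subjects: int = 25
    periods_per_subject: int = 2
    days_per_period: int = 14
    epoch_seconds: float = 60.0
    group_fraction: float = 0.6  # fraction in the "stroke" group
    temp_sd_of_mean: dict = field(default_factory=lambda: {"stroke": 0.5, "tia": 0.9})
    temp_sd_between: float = 0.2
    temp_apen_scale: dict = field(default_factory=lambda: {"stroke": 1.3, "tia": 1.0})
    sleep_onset_mean: float = 23.0  # clock hours
    sleep_onset_sd: float = 0.75
    sleep_dur_mean: float = 8.0
    sleep_dur_sd: float = 0.75
    weekend_bonus_h: float = 0.5
    trend_slope: float = 0.03
    nonwear_rate: float = 0.3  # expected episodes / day
    outcome_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "periods_per_subject", "days_per_period"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.periods_per_subject > 2:
            raise ConfigurationError("periods_per_subject must be 1 or 2")
        if self.days_per_period < 7:
            raise ConfigurationError("days_per_period must be >= 7 (valid-day rule)")
        if not 0 <= self.group_fraction <= 1:
            raise ConfigurationError("group_fraction must lie in [0, 1]")
        if self.epoch_seconds <= 0:
            raise ConfigurationError("epoch_seconds must be positive")
        if self.nonwear_rate < 0:
            raise ConfigurationError("nonwear_rate must be non-negative")
        for name in ("sleep_onset_sd", "sleep_dur_sd", "temp_sd_between"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("temp_sd_of_mean", "temp_apen_scale"):
            d = getattr(self, name)
            if set(d) != {"stroke", "tia"}:
                raise ConfigurationError(f"{name} must map groups 'stroke' and 'tia'")


@dataclass
class RecordingParams:
    """Signal-model knobs for one subject-period recording."""

    base_temp: float = 33.2
    circ_amp: float = 0.5
    circ_peak_h: float = 4.0       # clock hour of the circadian temperature peak
    sleep_elev: float = 1.2        # night-time plateau height (degC)
    ramp_min: float = 30.0
    noise_sd: float = 0.12
    noise_phi: float = 0.95
    apen_scale: float = 1.0        # within-sleep noise multiplier
    wake_jitter_g: float = 0.025
    sleep_jitter_g: float = 0.018
    activity_bout_g: float = 0.08
    orientation: tuple = (0.1, -0.2, 0.97)
    ambient_c: float = 21.0
    decay_tau_min: float = 10.0
    with_light: bool = True


@dataclass
class SyntheticTruth:
    """Planted parameters, reproducible from the seed."""

    subjects: pd.DataFrame   # subject_id, group, sigma_night, apen_scale, slopes, ...
    nights: pd.DataFrame     # subject_id, period_id, night_index, planted shift, window
    nonwear: pd.DataFrame    # subject_id, period_id, start, end


@dataclass
class CohortData:
    recordings: list[Recording]
    sleep_windows: dict[tuple[str, str], list[SleepWindow]]
    night_vars: pd.DataFrame
    outcomes: OutcomeTable
    truth: SyntheticTruth


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * np.sqrt(1 - phi**2), n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + innov[i]
    return out


def generate_recording(
    subject_id: str,
    period_id: str,
    start: pd.Timestamp,
    days: int,
    epoch_seconds: float,
    params: RecordingParams,
    windows: list[SleepWindow],
    night_shifts: dict[int, float],
    nonwear: list[tuple[pd.Timestamp, pd.Timestamp]],
    rng: np.random.Generator,
) -> Recording:
    """Synthesize one epoch-level recording from planted structure.

    ``night_shifts`` maps night_index to the planted temperature shift
    applied during that night's sleep window.
    """
    n = int(round(days * 86400 / epoch_seconds))
    idx = pd.date_range(start, periods=n, freq=pd.Timedelta(seconds=epoch_seconds))
    t_s = (idx.asi8 - idx.asi8[0]) / 1e9
    clock_h = np.asarray(idx.hour + idx.minute / 60.0 + idx.second / 3600.0, dtype=float)

    # --- temperature: baseline + circadian + sleep plateau + nightly shift
    temp = params.base_temp + params.circ_amp * np.cos(
        2 * np.pi * (clock_h - params.circ_peak_h) / 24.0
    )
    sleep_mask = np.zeros(n, dtype=bool)
    ramp_s = params.ramp_min * 60.0
    t0 = idx.asi8[0] / 1e9
    for w in windows:
        on_s = w.onset.value / 1e9 - t0
        off_s = w.offset.value / 1e9 - t0
        inside = (t_s >= on_s) & (t_s < off_s)
        sleep_mask |= inside
        if not inside.any():
            continue
        rel = np.zeros(n)
        rel[inside] = np.minimum.reduce(
            [
                np.ones(inside.sum()),
                (t_s[inside] - on_s) / ramp_s,
                (off_s - t_s[inside]) / ramp_s,
            ]
        )
        # the plateau ramps in and out; the planted nightly level shift is
        # flat across the window so the night-mean shift equals the draw
        shift = night_shifts.get(w.night_index, 0.0)
        temp = temp + rel * params.sleep_elev + inside * shift

    noise = _ar1(rng, n, params.noise_sd, params.noise_phi)
    if params.apen_scale != 1.0:
        noise = noise * np.where(sleep_mask, params.apen_scale, 1.0)
    temp = temp + noise

    # --- acceleration: unit-gravity orientation + posture jitter
    ori = np.asarray(params.orientation, dtype=float)
    ori = ori / np.linalg.norm(ori)
    jitter_sd = np.where(sleep_mask, params.sleep_jitter_g, params.wake_jitter_g)
    accel = ori[None, :] + rng.normal(0.0, 1.0, (n, 3)) * jitter_sd[:, None]
    # occasional wake activity bouts (adds ENMONZ signal, harmless to non-wear)
    active = (~sleep_mask) & (rng.random(n) < 0.2)
    if params.activity_bout_g > 0:
        accel[active] += rng.normal(0.0, params.activity_bout_g, (int(active.sum()), 3))

    # --- planted non-wear: frozen axes, temperature decays toward ambient
    for nw_start, nw_end in nonwear:
        inside = (idx >= nw_start) & (idx < nw_end)
        if not inside.any():
            continue
        i0 = int(np.flatnonzero(inside)[0])
        accel[inside] = accel[i0 - 1] if i0 > 0 else ori
        dt_min = (t_s[inside] - t_s[inside][0]) / 60.0
        t_at = temp[i0 - 1] if i0 > 0 else temp[i0]
        temp[inside] = params.ambient_c + (t_at - params.ambient_c) * np.exp(
            -dt_min / params.decay_tau_min
        )
        # recovery after re-wear toward the model course
        after = np.flatnonzero(idx >= nw_end)
        if after.size:
            j0 = after[0]
            dt_rec = (t_s[j0:] - t_s[j0]) / 60.0
            gap = temp[j0 - 1] - temp[j0]
            temp[j0:] = temp[j0:] + gap * np.exp(-dt_rec / (1.5 * params.decay_tau_min))

    data = pd.DataFrame(
        {
            "accel_x": accel[:, 0],
            "accel_y": accel[:, 1],
            "accel_z": accel[:, 2],
            "temperature": temp,
        },
        index=idx,
    )
    data.index.name = "timestamp"
    if params.with_light:
        daylight = (clock_h >= 7) & (clock_h < 21)
        data["light"] = np.where(daylight, 400.0, 1.0) + rng.normal(0, 5.0, n).clip(-5, None)
    return Recording(subject_id, period_id, data)


def _subject_schedule(
    spec: CohortSpec,
    subject: dict,
    period_id: str,
    rng: np.random.Generator,
) -> tuple[list[SleepWindow], dict[int, float], pd.DataFrame]:
    """Sleep windows, planted nightly temperature shifts, and per-night
    sleep variables for one subject-period."""
    start = PERIOD_STARTS[period_id]
    windows: list[SleepWindow] = []
    shifts: dict[int, float] = {}
    rows = []
    for night in range(spec.days_per_period - 1):
        day = start + pd.Timedelta(days=night)
        onset_h = float(
            np.clip(
                rng.normal(spec.sleep_onset_mean + subject["onset_shift"], spec.sleep_onset_sd),
                19.25,
                27.0,
            )
        )
        wake_day = day + pd.Timedelta(days=1)
        weekend = wake_day.dayofweek >= 5
        dur = (
            subject["dur_mean"]
            + subject["slope_dur"] * night
            + (subject["we_bonus"] if weekend else 0.0)
            + rng.normal(0.0, spec.sleep_dur_sd)
        )
        dur = float(np.clip(dur, 4.0, min(12.0, 38.0 - 0.25 - onset_h)))
        onset = day + pd.Timedelta(hours=onset_h)
        offset = onset + pd.Timedelta(hours=dur)
        w = SleepWindow(night + 1, onset.round("s"), offset.round("s"))
        windows.append(w)
        shifts[w.night_index] = float(rng.normal(0.0, subject["sigma_night"]))
        rows.append(
            {
                "subject_id": subject["subject_id"],
                "period_id": period_id,
                "night_index": w.night_index,
                "onset": w.onset,
                "offset": w.offset,
                "spt_dur_h": dur,
                "sibd_dur_h": float(
                    np.clip(
                        subject["sibd_base"] + subject["slope_sibd"] * night + rng.normal(0, 0.5),
                        0.0,
                        12.0,
                    )
                ),
                "n_sleep_periods": int(
                    np.clip(
                        round(subject["nper_base"] + subject["slope_nper"] * night + rng.normal(0, 0.8)),
                        1,
                        12,
                    )
                ),
                "sleep_efficiency": float(
                    np.clip(
                        subject["eff_base"] + subject["slope_eff"] * night + rng.normal(0, 0.04),
                        0.5,
                        1.0,
                    )
                ),
            }
        )
    return windows, shifts, pd.DataFrame(rows)


def _draw_nonwear(
    spec: CohortSpec, period_id: str, rng: np.random.Generator
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    start = PERIOD_STARTS[period_id]
    n_episodes = rng.poisson(spec.nonwear_rate * spec.days_per_period)
    episodes = []
    for _ in range(n_episodes):
        day = int(rng.integers(0, spec.days_per_period))
        start_h = float(rng.uniform(10.0, 18.0))
        dur_h = float(np.clip(rng.lognormal(0.3, 0.5), 0.5, 6.0))
        s = (start + pd.Timedelta(days=day, hours=start_h)).floor("15min")
        e = (s + pd.Timedelta(hours=dur_h)).ceil("15min")
        episodes.append((s, e))
    episodes.sort()
    return episodes


def _draw_outcomes(spec: CohortSpec, subjects: list[dict], rng: np.random.Generator) -> OutcomeTable:
    """Questionnaire scores as linear functions of planted parameters.

    Planted directions: larger between-night temperature variability ->
    lower (better) mRS; positive sleep-duration/n-sleep-period trends ->
    lower GAD-7 after wear; larger weekend-weekday sleep surplus -> higher
    specific-phobia scores.
    """
    eff = spec.outcome_effect
    rows = []
    for s in subjects:
        sigma_dev = s["sigma_night"] - float(np.mean(list(spec.temp_sd_of_mean.values())))
        mrs_latent = 0.9 + 1.0 * (s["group"] == "stroke") - eff * 2.0 * sigma_dev
        gad_base = float(np.clip(round(rng.normal(7, 3)), 0, 21))
        fq_sp_base = float(np.clip(round(rng.normal(12, 6)), 0, 40))
        row = {
            "subject_id": s["subject_id"],
            "sex": s["sex"],
            "age": s["age"],
            "diagnosis": s["group"],
            "mrs_baseline": float(np.clip(round(mrs_latent + rng.normal(0, 0.6)), 0, 5)),
            "gad7_baseline": gad_base,
            "phq2_baseline": float(np.clip(round(rng.normal(1.5, 1.2)), 0, 6)),
            "fq_ag_baseline": float(np.clip(round(rng.normal(8, 5)), 0, 40)),
            "fq_soc_baseline": float(np.clip(round(rng.normal(10, 6)), 0, 40)),
            "fq_sp_baseline": fq_sp_base,
        }
        for p in (1, 2):
            row[f"mrs_after{p}"] = float(
                np.clip(round(mrs_latent - 0.15 * p + rng.normal(0, 0.6)), 0, 5)
            )
            row[f"gad7_after{p}"] = float(
                np.clip(round(gad_base - eff * 60.0 * s["slope_dur"] - eff * 8.0 * s["slope_nper"] + rng.normal(0, 2.0)), 0, 21)
            )
            row[f"fq_ag_after{p}"] = float(np.clip(round(row["fq_ag_baseline"] + rng.normal(0, 3)), 0, 40))
            row[f"fq_soc_after{p}"] = float(np.clip(round(row["fq_soc_baseline"] + rng.normal(0, 3)), 0, 40))
            row[f"fq_sp_after{p}"] = float(
                np.clip(round(fq_sp_base + eff * 4.0 * (s["we_bonus"] - spec.weekend_bonus_h) + rng.normal(0, 3)), 0, 40)
            )
        row["phq2_after1"] = float(np.clip(round(row["phq2_baseline"] + rng.normal(0, 1.0)), 0, 6))
        rows.append(row)
    return OutcomeTable(pd.DataFrame(rows).set_index("subject_id"))


def generate_cohort(spec: CohortSpec, signals: bool = True) -> CohortData:
    """Generate a full synthetic cohort; with ``signals=False`` the
    (expensive) epoch-level recordings are skipped while sleep windows,
    night variables, outcomes and truth are identical to the full run."""
    root = np.random.SeedSequence(spec.seed)
    subj_seqs = root.spawn(spec.n_subjects)
    outcome_rng = np.random.default_rng(root.spawn(1)[0])

    n_stroke = int(round(spec.group_fraction * spec.n_subjects))
    recordings: list[Recording] = []
    sleep_windows: dict[tuple[str, str], list[SleepWindow]] = {}
    night_var_frames: list[pd.DataFrame] = []
    subjects: list[dict] = []
    truth_nights = []
    truth_nonwear = []

    for i, seq in enumerate(subj_seqs):
        param_seq, sched_seq, signal_seq = seq.spawn(3)
        param_rng = np.random.default_rng(param_seq)
        group = "stroke" if i < n_stroke else "tia"
        slope_dur = float(param_rng.normal(0.0, spec.trend_slope))
        subject = {
            "subject_id": f"S{i + 1:03d}",
            "group": group,
            "sex": "f" if param_rng.random() < 0.5 else "m",
            "age": int(param_rng.integers(40, 82)),
            "sigma_night": float(
                max(param_rng.normal(spec.temp_sd_of_mean[group], spec.temp_sd_between), 0.05)
            ),
            "apen_scale": spec.temp_apen_scale[group],
            "base_temp": float(param_rng.normal(33.2, 0.4)),
            "onset_shift": float(param_rng.normal(0.0, 0.5)),
            "dur_mean": float(param_rng.normal(spec.sleep_dur_mean, 0.5)),
            "we_bonus": float(param_rng.normal(spec.weekend_bonus_h, 0.3)),
            "slope_dur": slope_dur,
            "slope_sibd": float(param_rng.normal(0.0, 0.6 * spec.trend_slope)),
            "slope_nper": float(1.3 * slope_dur + param_rng.normal(0.0, 0.03)),
            "slope_eff": float(param_rng.normal(0.0, 0.1 * spec.trend_slope)),
            "sibd_base": float(param_rng.normal(3.0, 1.0)),
            "nper_base": float(param_rng.normal(3.0, 1.0)),
            "eff_base": float(np.clip(param_rng.normal(0.88, 0.04), 0.6, 0.98)),
        }
        subjects.append(subject)

        sched_rngs = [np.random.default_rng(s) for s in sched_seq.spawn(spec.periods_per_subject)]
        signal_rngs = [np.random.default_rng(s) for s in signal_seq.spawn(spec.periods_per_subject)]
        for p in range(spec.periods_per_subject):
            period_id = str(p + 1)
            windows, shifts, nvars = _subject_schedule(spec, subject, period_id, sched_rngs[p])
            sleep_windows[(subject["subject_id"], period_id)] = windows
            night_var_frames.append(nvars)
            for w in windows:
                truth_nights.append(
                    {
                        "subject_id": subject["subject_id"],
                        "period_id": period_id,
                        "night_index": w.night_index,
                        "onset": w.onset,
                        "offset": w.offset,
                        "planted_shift": shifts[w.night_index],
                    }
                )
            nonwear = _draw_nonwear(spec, period_id, sched_rngs[p])
            for s_, e_ in nonwear:
                truth_nonwear.append(
                    {"subject_id": subject["subject_id"], "period_id": period_id, "start": s_, "end": e_}
                )
            if signals:
                params = RecordingParams(
                    base_temp=subject["base_temp"],
                    apen_scale=subject["apen_scale"],
                )
                recordings.append(
                    generate_recording(
                        subject["subject_id"],
                        period_id,
                        PERIOD_STARTS[period_id],
                        spec.days_per_period,
                        spec.epoch_seconds,
                        params,
                        windows,
                        shifts,
                        nonwear,
                        signal_rngs[p],
                    )
                )

    outcomes = _draw_outcomes(spec, subjects, outcome_rng)
    truth = SyntheticTruth(
        subjects=pd.DataFrame(subjects).set_index("subject_id"),
        nights=pd.DataFrame(truth_nights),
        nonwear=pd.DataFrame(truth_nonwear, columns=["subject_id", "period_id", "start", "end"]),
    )
    return CohortData(
        recordings=recordings,
        sleep_windows=sleep_windows,
        night_vars=pd.concat(night_var_frames, ignore_index=True),
        outcomes=outcomes,
        truth=truth,
    )


def nonwear_validation_recording(seed: int = 0):
    """Fixture recording for filter-fidelity checks: 9 full days with one
    planted 16-h non-wear episode (noon day 3 to 04:00 day 4).

    Returns (recording, planted_intervals, expected) where ``expected``
    holds the construction's intended valid-day and valid-night counts:
    9 calendar days of which day 3 fails the 16-h wear rule (8 valid), and
    10 touching noon-to-noon night windows of which the two data-less edge
    windows and the episode's window fail the 10% rule (7 valid).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    start = PERIOD_STARTS["1"]
    days = 9
    windows = [
        SleepWindow(
            n + 1,
            start + pd.Timedelta(days=n, hours=23),
            start + pd.Timedelta(days=n + 1, hours=7),
        )
        for n in range(days - 1)
    ]
    nw = [
        (
            start + pd.Timedelta(days=3, hours=12),
            start + pd.Timedelta(days=4, hours=4),
        )
    ]
    rec = generate_recording(
        "FIX", "1", start, days, 60.0, RecordingParams(), windows,
        {w.night_index: 0.0 for w in windows}, nw, rng,
    )
    expected = {"valid_days": 8, "n_days": 9, "valid_nights": 7, "n_nights": 10}
    return rec, nw, expected
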