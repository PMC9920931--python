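import numpy as np
import pandas as pd
import pytest

from wristfeat.io import SleepWindow
from wristfeat.preprocess import NightTempSeries
from wristfeat.pipeline import extract_features
from wristfeat.synthetic import CohortSpec, generate_cohort


def make_night_series(values, onset="2023-03-06 23:00") -> NightTempSeries:
    """Construct a (already-smoothed) night series directly from values."""
    onset = pd.Timestamp(onset)
    values = np.asarray(values, dtype=float)
    times = pd.date_range(onset, periods=len(values), freq="15min")
    window = SleepWindow(1, onset, times[-1])
    return NightTempSeries(window, times, values, valid=True)


@pytest.fixture(scope="session")
def small_cohort():
    spec = CohortSpec(
        n_subjects=6, periods_per_subject=2, days_per_period=8, nonwear_rate=0.3, seed=7
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    table, reports = extract_features(
        small_cohort.recordings,
        small_cohort.sleep_windows,
        small_cohort.night_vars,
        small_cohort.outcomes,
    )
    return table, reports
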