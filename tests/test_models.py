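"""Feature preparation, LOSO logistic regression (leakage checks), metrics
against a U-statistic oracle, and the weighted ensemble contract."""

import numpy as np
import pandas as pd
import pytest

from wristfeat.io import FeatureTable, OutcomeTable
from wristfeat.models import (
    auc_curve,
    diagnosis_target,
    loso_fit_predict,
    metrics,
    prepare_features,
    severity_target,
    weighted_ensemble,
)


def _mk_index(pairs):
    return pd.MultiIndex.from_tuples(pairs, names=["subject_id", "period_id"])


class TestPrepareFeatures:
    def _table(self, df):
        return FeatureTable(df, {c: "novel" for c in df.columns})

    def test_within_subject_imputation(self):
        idx = _mk_index([("S1", "1"), ("S1", "2"), ("S2", "1")])
        df = pd.DataFrame({"f": [np.nan, 4.0, 9.0], "g": [1.0, 2.0, 3.0]}, index=idx)
        out = prepare_features(self._table(df))
        assert out.data.at[("S1", "1"), "f"] == 4.0  # copied from the other period
        assert "f" in out.data.columns

    def test_unimputable_column_dropped(self):
        idx = _mk_index([("S1", "1"), ("S2", "1")])
        df = pd.DataFrame({"f": [np.nan, 4.0], "g": [1.0, 2.0]}, index=idx)
        out = prepare_features(self._table(df))
        assert list(out.data.columns) == ["g"]

    def test_fully_masked_sleep_row_removed(self):
        idx = _mk_index([("S1", "1"), ("S2", "1"), ("S3", "1")])
        df = pd.DataFrame(
            {"sleepy": [np.nan, 1.0, 2.0], "other": [0.1, 0.2, 0.3]}, index=idx
        )
        table = FeatureTable(df, {"sleepy": "sleep", "other": "pa"})
        out = prepare_features(table)
        assert ("S1", "1") not in out.data.index

    def test_complete_table_identity(self):
        idx = _mk_index([("S1", "1"), ("S2", "1")])
        df = pd.DataFrame({"f": [1.0, 2.0]}, index=idx)
        out = prepare_features(self._table(df))
        pd.testing.assert_frame_equal(out.data, df)


def test_target_encodings():
    od = pd.DataFrame(
        {
            "sex": ["f", "m"],
            "age": [60, 70],
            "diagnosis": ["stroke", "tia"],
            "mrs_after1": [0.0, 2.0],
            "mrs_after2": [1.0, np.nan],
        },
        index=pd.Index(["S1", "S2"], name="subject_id"),
    )
    outcomes = OutcomeTable(od)
    idx = _mk_index([("S1", "1"), ("S1", "2"), ("S2", "1"), ("S2", "2")])
    assert diagnosis_target(outcomes, idx).tolist() == [1, 1, 0, 0]
    sev = severity_target(outcomes, idx)
    assert sev.tolist()[:3] == [0.0, 1.0, 1.0]
    assert np.isnan(sev.iloc[3])


def _toy_loso(offset=5.0, n_subjects=8, seed=0):
    rng = np.random.default_rng(seed)
    idx = _mk_index([(f"S{i}", "1") for i in range(n_subjects)])
    y = np.array([i % 2 for i in range(n_subjects)], dtype=float)
    X = pd.DataFrame(
        {"f1": y * offset + rng.normal(0, 0.3, n_subjects), "f2": rng.normal(0, 1, n_subjects)},
        index=idx,
    )
    subjects = idx.get_level_values(0).to_numpy()
    return X, y, subjects


def test_separable_problem_reaches_auc_one():
    X, y, subjects = _toy_loso()
    res = loso_fit_predict(X, y, subjects, ["f1"])
    assert metrics(res.prob, y)["auc"] == 1.0


def test_single_class_training_fold_raises_with_subject_name():
    X, y, subjects = _toy_loso(n_subjects=3)
    y = np.array([0.0, 0.0, 1.0])
    with pytest.raises(ValueError, match="S2"):
        loso_fit_predict(X, y, subjects, ["f1"])


def test_heldout_outlier_cannot_touch_its_folds_training_statistics():
    """Injecting an extreme outlier into a held-out subject changes nothing
    about that fold's training-side model: the fold's prediction for the
    outlier equals a model fit and standardized on the unperturbed training
    rows alone, applied to the outlier."""
    from sklearn.linear_model import LogisticRegression

    X, y, subjects = _toy_loso(offset=2.0)
    X2 = X.copy()
    X2.loc[("S3", "1")] = [1e6, -1e6]  # outlier only in the held-out subject
    pert = loso_fit_predict(X2, y, subjects, ["f1", "f2"])

    # oracle fold: train on the unperturbed rows of everyone but S3
    keep = X.index.get_level_values(0) != "S3"
    train = X[keep].to_numpy()
    mu, sd = train.mean(axis=0), train.std(axis=0)
    clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
    clf.fit((train - mu) / sd, y[keep.to_numpy() if hasattr(keep, "to_numpy") else keep])
    expected = clf.predict_proba((X2.loc[[("S3", "1")]].to_numpy() - mu) / sd)[0, 1]
    assert pert.prob.loc[("S3", "1")] == pytest.approx(expected, abs=1e-12)


def test_auc_curve_shape_and_determinism():
    X, y, subjects = _toy_loso()
    curve1 = auc_curve(X, y, subjects, ["f1", "f2"])
    curve2 = auc_curve(X, y, subjects, ["f1", "f2"])
    assert list(curve1.index) == [1, 2]
    assert ((curve1["auc"] >= 0) & (curve1["auc"] <= 1)).all()
    pd.testing.assert_frame_equal(curve1, curve2)
    assert curve1.loc[1, "auc"] == 1.0  # f1 separates perfectly


class TestMetrics:
    def test_perfect_ranking(self):
        y = [0, 0, 0, 1, 1, 1]
        p = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        m = metrics(p, y)
        assert m["auc"] == 1.0 and m["balanced_accuracy"] == 1.0
        assert m["confusion"] == {"tp": 3, "tn": 3, "fp": 0, "fn": 0}

    def test_constant_probability_ties_give_half(self):
        assert metrics([0.4] * 6, [0, 0, 0, 1, 1, 1])["auc"] == 0.5

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            p = rng.normal(size=30) + y  # some signal plus ties unlikely
            pos = p[y == 1]
            neg = p[y == 0]
            # U-statistic oracle: pairwise comparison with half-credit ties
            wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
            expected = wins / (len(pos) * len(neg))
            assert metrics(p, y)["auc"] == pytest.approx(expected, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            metrics([0.2, 0.8], [1, 1])


class TestWeightedEnsemble:
    def _probs(self, values):
        idx = _mk_index([(f"S{i}", "1") for i in range(len(next(iter(values.values()))))])
        return {k: pd.Series(v, index=idx) for k, v in values.items()}

    def test_equal_weights_are_plain_mean(self):
        probs = self._probs({"a": [0.2, 0.5], "b": [0.6, 0.7]})
        out = weighted_ensemble(probs, {"a": 1.0, "b": 1.0})
        assert out.tolist() == pytest.approx([0.4, 0.6])

    def test_all_weight_on_one_model_is_identity(self):
        probs = self._probs({"a": [0.2, 0.5], "b": [0.6, 0.7]})
        out = weighted_ensemble(probs, {"a": 1.0, "b": 1e-12})
        assert out.tolist() == pytest.approx([0.2, 0.5], abs=1e-9)

    def test_convexity_with_reported_style_weights(self):
        rng = np.random.default_rng(7)
        vals = {k: rng.uniform(0, 1, 10) for k in ("sleep", "pa", "novel", "combined")}
        probs = self._probs(vals)
        weights = dict(zip(probs, (0.766, 0.778, 0.684, 0.807)))
        out = weighted_ensemble(probs, weights)
        stacked = np.column_stack([vals[k] for k in probs])
        assert (out.to_numpy() >= stacked.min(axis=1) - 1e-12).all()
        assert (out.to_numpy() <= stacked.max(axis=1) + 1e-12).all()

    def test_mismatched_samples_rejected(self):
        probs = self._probs({"a": [0.2, 0.5], "b": [0.6, 0.7]})
        probs["b"] = probs["b"].iloc[:1]
        with pytest.raises(ValueError, match="different samples"):
            weighted_ensemble(probs, {"a": 1.0, "b": 1.0})

    def test_nonpositive_weight_rejected(self):
        probs = self._probs({"a": [0.2], "b": [0.3]})
        with pytest.raises(ValueError, match="positive"):
            weighted_ensemble(probs, {"a": 1.0, "b": 0.0})
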