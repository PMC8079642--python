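"""Logistic models, confusion metrics, CV reports, cohort comparison."""

import types
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stimmap.model import (
    ESMClassifier,
    compare_models,
    confusion_metrics,
    cohort_comparison,
    fit_cv,
    summarize_cohort,
)


def _features(X, y, cols=("f_pca",)):
    df = pd.DataFrame(np.atleast_2d(X), columns=list(cols))
    for c in ("f_alltime", "f_pca", "f_centrality", "f_ccep_z", "f_ccep_edges"):
        if c not in df.columns:
            df[c] = 0.0
    df["esm_label"] = y
    df["pair"] = [f"p{i}" for i in range(len(df))]
    return df


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((8, 3, 5, 1), (72.7, 83.3, 76.5)),
            ((9, 1, 0, 7), (90.0, 0.0, 52.9)),
            ((9, 1, 6, 1), (90.0, 85.7, 88.2)),
            ((10, 1, 4, 2), (90.9, 66.7, 82.4)),
            ((8, 2, 2, 5), (80.0, 28.6, 58.8)),
        ],
    )
    def test_reported_rates(self, counts, expected):
        assert confusion_metrics(*counts) == expected

    def test_empty_positive_class_flagged_undefined(self):
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            sens, spec, acc = confusion_metrics(0, 0, 10, 0)
        assert np.isnan(sens) and spec == 100.0 and acc == 100.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)


class TestCompareModels:
    def test_identical_lists(self):
        t, p = compare_models([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_published_accuracy_comparison(self):
        t, p = compare_models(
            [76.5, 75.0, 78.6, 83.3, 58.8], [82.4, 83.3, 92.9, 91.7, 88.2]
        )
        assert abs(p - 0.022) < 5e-4

    def test_null_calibration_p_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(2000):
            a = rng.normal(size=5)
            b = rng.normal(size=5)
            ps.append(compare_models(a, b)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_models([1.0, 2.0], [1.0, 2.0, 3.0])


class TestClassifier:
    def test_sklearn_contract(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] + 0.3 * rng.normal(size=60) > 0).astype(int)
        clf = ESMClassifier().fit(X, y)
        assert clf.coef_.shape == (1, 2)
        assert clf.predict_proba(X).shape == (60, 2)
        assert clf.get_params()["ridge_lambda"] == 1e-6
        assert (clf.predict(X) == y).mean() > 0.8

    def test_separable_data_gets_finite_coefficients(self):
        X = np.linspace(-1, 1, 20)[:, None]
        y = (X[:, 0] > 0).astype(int)
        clf = ESMClassifier().fit(X, y)
        assert clf.separation_
        assert np.all(np.isfinite(clf.coef_))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            ESMClassifier().fit(np.zeros((10, 1)), np.ones(10))


class TestFitCV:
    def test_label_independent_features_near_chance(self):
        rng = np.random.default_rng(1)
        df = _features(rng.normal(size=(200, 1)), rng.integers(0, 2, 200))
        rep = fit_cv(df, "eq2", seed=3)
        assert 35.0 < rep.accuracy < 65.0
        assert 0.35 < rep.auc < 0.65

    def test_planted_coefficient_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        p = 1 / (1 + np.exp(-3.0 * x))
        y = (rng.uniform(size=200) < p).astype(int)
        rep = fit_cv(_features(x[:, None], y), "eq2", seed=0)
        assert rep.coefficients["f_pca"] > 0
        assert rep.auc > 0.9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        df = _features(rng.normal(size=(40, 1)), rng.integers(0, 2, 40))
        r1 = fit_cv(df, "eq2", seed=7)
        r2 = fit_cv(df, "eq2", seed=7)
        assert r1.oof_proba == r2.oof_proba
        assert r1.coefficients == r2.coefficients
        assert (r1.tp, r1.fn, r1.tn, r1.fp) == (r2.tp, r2.fn, r2.tn, r2.fp)

    def test_confusion_counts_match_counting_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        y = (x + rng.normal(size=60) > 0).astype(int)
        rep = fit_cv(_features(x[:, None], y), "eq2", seed=1)
        proba = np.array(rep.oof_proba)
        labels = np.array(rep.labels)
        assert rep.tp == int(((proba >= 0.5) & (labels == 1)).sum())
        assert rep.tn == int(((proba < 0.5) & (labels == 0)).sum())
        assert rep.tp + rep.fn + rep.tn + rep.fp == rep.n

    def test_auc_invariant_to_monotone_transform(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        x = rng.normal(size=80)
        y = (x + rng.normal(size=80) > 0).astype(int)
        rep = fit_cv(_features(x[:, None], y), "eq2", seed=1)
        proba = np.array(rep.oof_proba)
        assert roc_auc_score(y, proba**3) == pytest.approx(rep.auc)

    def test_missing_ccep_rows_dropped_not_imputed(self):
        rng = np.random.default_rng(6)
        df = _features(rng.normal(size=(40, 1)), rng.integers(0, 2, 40))
        df.loc[:4, "f_ccep_z"] = np.nan
        rep = fit_cv(df, "eq3_ccep_z", seed=0)
        assert rep.n == 35

    def test_single_class_rejected(self):
        df = _features(np.zeros((10, 1)), np.ones(10, dtype=int))
        with pytest.raises(ValueError):
            fit_cv(df, "eq2")


def _stub_reports(accs, aucs, model_ids=("eq1", "eq2", "eq3")):
    out = {}
    for i, pat in enumerate(["1", "2", "3", "4", "5"]):
        out[pat] = {
            m: types.SimpleNamespace(accuracy=accs[m][i], auc=aucs[m][i])
            for m in model_ids
        }
    return out


TABLE_ACC = {
    "eq1": [76.5, 75.0, 71.4, 83.3, 52.9],
    "eq2": [76.5, 75.0, 78.6, 83.3, 58.8],
    "eq3": [82.4, 83.3, 92.9, 91.7, 88.2],
}
TABLE_AUC = {
    "eq1": [0.70, 0.19, 0.25, 0.72, 0.31],
    "eq2": [0.83, 0.31, 0.48, 0.72, 0.39],
    "eq3": [0.86, 0.56, 0.92, 1.00, 0.81],
}


class TestCohortSummary:
    def test_averaged_row(self):
        table = summarize_cohort(_stub_reports(TABLE_ACC, TABLE_AUC))
        avg = table[table.patient == "Averaged"].iloc[0]
        assert avg["accuracy_eq1"] == 71.8 and avg["auc_eq1"] == 0.43
        assert avg["accuracy_eq2"] == 74.4 and avg["auc_eq2"] == 0.55
        assert avg["accuracy_eq3"] == 87.7 and avg["auc_eq3"] == 0.83

    def test_single_patient_mean_is_identity(self):
        reports = {
            "1": {
                "eq1": types.SimpleNamespace(accuracy=76.5, auc=0.70),
            }
        }
        table = summarize_cohort(reports)
        avg = table[table.patient == "Averaged"].iloc[0]
        assert avg["accuracy_eq1"] == 76.5 and avg["auc_eq1"] == 0.7

    def test_model_comparison_p_values(self):
        reports = _stub_reports(TABLE_ACC, TABLE_AUC)
        comp = cohort_comparison(reports, "eq2", "eq3")
        assert abs(comp["accuracy_p"] - 0.022) < 5e-4
        assert 0.0 < comp["auc_p"] < 0.1

    def test_mismatched_model_sets_rejected(self):
        reports = _stub_reports(TABLE_ACC, TABLE_AUC)
        del reports["5"]["eq3"]
        with pytest.raises(ValueError, match="same model set"):
            summarize_cohort(reports)
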