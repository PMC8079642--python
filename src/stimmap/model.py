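"""Logistic prediction of ESM outcomes and its cross-validated report.

Five model variants map pair-level predictors to the probability of an
ESM+ outcome through a logit link:

* ``eq1``                — integrated HG over the whole task window
* ``eq2``                — HG restricted to PCA-selected windows
* ``eq3_centrality_only``— HG_pca + network centrality
* ``eq3_ccep_z``         — HG_pca + centrality + z-weighted CCEP term
* ``eq3_ccep_edges``     — HG_pca + centrality + edge-count CCEP term

Each variant is evaluated with stratified 5-fold cross-validation:
features standardized with training-fold statistics, maximum-likelihood
logistic fit (a tiny ridge engages only on separation), out-of-fold
probabilities pooled, classified at 0.5, and summarized as confusion
counts, sensitivity/specificity/accuracy (percent) and AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

MODEL_FEATURES = {
    "eq1": ["f_alltime"],
    "eq2": ["f_pca"],
    "eq3_centrality_only": ["f_pca", "f_centrality"],
    "eq3_ccep_z": ["f_pca", "f_centrality", "f_ccep_z"],
    "eq3_ccep_edges": ["f_pca", "f_centrality", "f_ccep_edges"],
}

#: coefficient-norm beyond which (on standardized features) the
#: unpenalized fit is treated as separated
_SEPARATION_NORM = 1e4


class ESMClassifier(ClassifierMixin, BaseEstimator):
    """Standardized maximum-likelihood logistic regression.

    A plain GLM fit (no penalty); if the data are separable the
    coefficients diverge, in which case a tiny ridge
    (``ridge_lambda`` on standardized features) is engaged to keep them
    finite without materially biasing estimates.

    Attributes
    ----------
    coef_, intercept_ : fitted coefficients on the standardized scale
    scaler_ : the fitted StandardScaler
    classes_ : class labels
    separation_ : True when the ridge fallback engaged
    """

    def __init__(self, ridge_lambda: float = 1e-6, max_iter: int = 2000):
        self.ridge_lambda = ridge_lambda
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if np.unique(y).size < 2:
            raise ValueError("need both ESM classes to fit")
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        self.separation_ = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            lr = LogisticRegression(
                C=np.inf, solver="lbfgs", max_iter=self.max_iter
            ).fit(Z, y)
        separated = (
            not np.all(np.isfinite(lr.coef_))
            or np.linalg.norm(lr.coef_) > _SEPARATION_NORM
            or (np.linalg.norm(lr.coef_) > 0 and np.all(lr.predict(Z) == y))
        )
        if separated:
            self.separation_ = True
            lr = LogisticRegression(
                C=1.0 / self.ridge_lambda,
                solver="lbfgs",
                max_iter=self.max_iter,
            ).fit(Z, y)
        self.lr_ = lr
        self.coef_ = lr.coef_
        self.intercept_ = lr.intercept_
        self.classes_ = lr.classes_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "lr_")
        X = check_array(X)
        return self.lr_.predict_proba(self.scaler_.transform(X))

    def predict(self, X):
        check_is_fitted(self, "lr_")
        X = check_array(X)
        return self.lr_.predict(self.scaler_.transform(X))


@dataclass
class ModelReport:
    """Cross-validated evaluation of one model variant on one patient."""

    model_id: str
    coefficients: dict
    pairs: list
    labels: list
    oof_proba: list
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    k: int
    seed: int
    n: int

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls(**json.load(fh))


def confusion_metrics(tp: int, fn: int, tn: int, fp: int):
    """Sensitivity, specificity and accuracy (percent, 1 decimal).

    An empty class makes the corresponding rate 0/0; it is returned as
    NaN with a warning (a zero numerator over a nonempty denominator is
    a plain 0.0).
    """
    total = tp + fn + tn + fp
    if min(tp, fn, tn, fp) < 0 or total == 0:
        raise ValueError("counts must be nonnegative with a positive total")
    if tp + fn == 0:
        warnings.warn("no positive pairs; sensitivity undefined")
        sens = float("nan")
    else:
        sens = round(100.0 * tp / (tp + fn), 1)
    if tn + fp == 0:
        warnings.warn("no negative pairs; specificity undefined")
        spec = float("nan")
    else:
        spec = round(100.0 * tn / (tn + fp), 1)
    acc = round(100.0 * (tp + tn) / total, 1)
    return sens, spec, acc


def fit_cv(
    features: pd.DataFrame,
    model_id: str,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> ModelReport:
    """Stratified k-fold cross-validated logistic evaluation.

    Rows with missing values in the variant's feature columns (pairs
    never probed with single-pulse stimulation) are dropped, not
    imputed. The reported coefficients come from a full-data refit on
    the standardized features.
    """
    cols = MODEL_FEATURES[model_id]
    df = features.dropna(subset=cols)
    X = df[cols].to_numpy(dtype=np.float64)
    y = df["esm_label"].to_numpy(dtype=int)
    pairs = df["pair"].tolist()
    n = len(y)
    if n < k:
        raise ValueError(f"{n} pairs < {k} folds")
    if np.unique(y).size < 2:
        raise ValueError("both ESM classes must be present")
    if np.bincount(y).min() < k:
        raise ValueError(
            "minority class smaller than the fold count; stratified "
            f"{k}-fold CV impossible"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.empty(n)
    for train, test in skf.split(X, y):
        clf = ESMClassifier().fit(X[train], y[train])
        oof[test] = clf.predict_proba(X[test])[:, 1]
    pred = oof >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    sens, spec, acc = confusion_metrics(tp, fn, tn, fp)
    auc = float(roc_auc_score(y, oof))
    full = ESMClassifier().fit(X, y)
    coefs = {c: float(v) for c, v in zip(cols, full.coef_.ravel())}
    coefs["intercept"] = float(full.intercept_[0])
    return ModelReport(
        model_id=model_id,
        coefficients=coefs,
        pairs=pairs,
        labels=y.tolist(),
        oof_proba=oof.tolist(),
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        auc=auc,
        k=k,
        seed=seed,
        n=n,
    )


def compare_models(metric_a, metric_b):
    """Pooled-variance two-sample two-sided t-test between per-patient metrics."""
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.size != b.size or a.size < 2:
        raise ValueError("need equal-length lists with n >= 2")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        if np.allclose(a, b):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def summarize_cohort(reports: dict) -> pd.DataFrame:
    """Cohort table: per-patient accuracy/AUC per model + averaged row.

    Parameters
    ----------
    reports : dict patient -> dict model_id -> ModelReport
    """
    patients = list(reports)
    model_ids = list(next(iter(reports.values())))
    for pat in patients:
        if list(reports[pat]) != model_ids:
            raise ValueError("all patients must share the same model set")
    rows = []
    for pat in patients:
        row = {"patient": pat}
        for m in model_ids:
            row[f"accuracy_{m}"] = reports[pat][m].accuracy
            row[f"auc_{m}"] = reports[pat][m].auc
        rows.append(row)
    df = pd.DataFrame(rows)
    avg = {"patient": "Averaged"}
    for m in model_ids:
        avg[f"accuracy_{m}"] = round(float(df[f"accuracy_{m}"].mean()), 1)
        avg[f"auc_{m}"] = round(float(df[f"auc_{m}"].mean()), 2)
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)


def cohort_comparison(reports: dict, model_a: str, model_b: str) -> dict:
    """Accuracy and AUC comparison p-values between two model variants."""
    acc_a = [reports[p][model_a].accuracy for p in reports]
    acc_b = [reports[p][model_b].accuracy for p in reports]
    auc_a = [reports[p][model_a].auc for p in reports]
    auc_b = [reports[p][model_b].auc for p in reports]
    t_acc, p_acc = compare_models(acc_a, acc_b)
    t_auc, p_auc = compare_models(auc_a, auc_b)
    return {
        "accuracy_t": t_acc,
        "accuracy_p": p_acc,
        "auc_t": t_auc,
        "auc_p": p_auc,
    }
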