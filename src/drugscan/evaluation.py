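"""Regression metrics, data splits and per-group performance reports.

The central quantity is the coefficient of determination about the observed
mean,

    R^2 = 1 - sum_i (y_i - f_i)^2 / sum_i (y_i - ybar)^2,

which may be negative for predictors worse than the constant mean.  RMSE is
reported in ln(IC50) units.  Sensitivity classification uses the fixed
cutoff ln(IC50) < -2 (about 0.135 uM); AUROC scores how well lower predicted
ln(IC50) ranks truly sensitive pairs above insensitive ones, ties counted
half.

Splits are stratified by cancer type so every type contributes the same
fraction of held-out instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR

from .exceptions import UndefinedMetricError, UsageError

SENSITIVITY_CUTOFF = -2.0  # ln(IC50 uM); exp(-2) ~ 0.135 uM


@dataclass
class EvalReport:
    """Metrics for one evaluation group."""

    group: str            # overall | cancer_type | cell_line | drug
    key: str              # group member id ("" for overall)
    n: int
    r2: float
    rmse: float
    pearson_r: float | None = None
    pearson_p: float | None = None
    auroc: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _check_pair(y, f, min_n: int = 1):
    y = np.asarray(y, dtype=float).ravel()
    f = np.asarray(f, dtype=float).ravel()
    if y.shape != f.shape:
        raise UsageError(f"length mismatch: {y.shape} vs {f.shape}")
    if y.size < min_n:
        raise UndefinedMetricError(f"metric undefined for n={y.size} < {min_n}")
    return y, f


def r_squared(y, f) -> float:
    """Coefficient of determination about the observed mean (may be negative)."""
    y, f = _check_pair(y, f, min_n=2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 undefined: observed values have zero variance")
    return 1.0 - float(np.sum((y - f) ** 2)) / ss_tot


def rmse(y, f) -> float:
    y, f = _check_pair(y, f, min_n=1)
    return float(np.sqrt(np.mean((y - f) ** 2)))


def auroc_sensitivity(y, f, cutoff: float = SENSITIVITY_CUTOFF) -> float:
    """AUROC for detecting sensitive pairs (observed ln IC50 < cutoff).

    The score is -f: lower predicted ln(IC50) means more sensitive.  Computed
    rank-based (Mann-Whitney U), ties counted half.
    """
    y, f = _check_pair(y, f, min_n=2)
    labels = y < cutoff
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUROC undefined: single class after binarizing at {cutoff}"
        )
    ranks = stats.rankdata(-f)  # average ranks handle ties as half-counts
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u) / (n_pos * n_neg)


def pearson(y, f) -> tuple[float, float]:
    """Pearson r and two-sided p (t-distribution approximation)."""
    y, f = _check_pair(y, f, min_n=2)
    r, p = stats.pearsonr(y, f)
    return float(r), float(p)


@dataclass(frozen=True)
class SplitSpec:
    """Held-out split stratified by cancer type."""

    test_fraction: float = 0.05
    stratify_by: str = "cancer_type"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise UsageError(f"test_fraction must be in (0,1), got {self.test_fraction}")


def stratified_split(instances: pd.DataFrame, spec: SplitSpec):
    """Split instances into (train, test) with per-stratum test counts.

    Each stratum contributes round(test_fraction * stratum size) test
    instances (round-half-to-even); strata too small to contribute get a
    warning via the returned report and land entirely in train.
    """
    df = pd.DataFrame(instances)
    rng = np.random.default_rng(spec.seed)
    test_idx = []
    warnings = []
    for key, grp in df.groupby(spec.stratify_by, sort=True):
        n_test = int(np.round(spec.test_fraction * len(grp)))
        if n_test == 0:
            warnings.append(f"stratum {key!r} (n={len(grp)}) contributes no test instances")
            continue
        take = rng.permutation(len(grp))[:n_test]
        test_idx.extend(grp.index[take])
    test_mask = df.index.isin(test_idx)
    for w in warnings:
        logging.getLogger(__name__).warning(w)
    return df[~test_mask], df[test_mask]


def kfold_cv(n: int, k: int = 5, seed: int = 0):
    """Disjoint fold index arrays covering range(n), sizes differing by <= 1."""
    if k < 2:
        raise UsageError(f"k must be >= 2, got {k}")
    if k > n:
        raise UsageError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def kfold_reports(X, y, estimator, k: int = 5, seed: int = 0):
    """Fit a fresh clone of ``estimator`` on each fold complement and report
    metrics on the held fold.

    Returns (folds, reports): the held-out index arrays and one
    :class:`EvalReport` per fold.
    """
    from sklearn.base import clone

    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    folds = kfold_cv(len(y), k=k, seed=seed)
    reports = []
    for i, held in enumerate(folds):
        fit_idx = np.setdiff1d(np.arange(len(y)), held)
        model = clone(estimator)
        model.fit(X[fit_idx], y[fit_idx])
        reports.append(evaluate(y[held], model.predict(X[held]),
                                group="fold", key=str(i), with_auroc=False))
    return folds, reports


def evaluate(y, f, group: str = "overall", key: str = "", with_auroc: bool = True) -> EvalReport:
    """Full report for one set of (observed, predicted) pairs."""
    y, f = _check_pair(y, f, min_n=2)
    r, p = pearson(y, f)
    try:
        auc = auroc_sensitivity(y, f) if with_auroc else None
    except UndefinedMetricError:
        auc = None
    return EvalReport(group=group, key=key, n=int(y.size),
                      r2=r_squared(y, f), rmse=rmse(y, f),
                      pearson_r=r, pearson_p=p, auroc=auc)


def centric_reports(instances: pd.DataFrame, predictions, axis: str, min_n: int = 3):
    """Per-group reports along cancer_type, cell_line or drug.

    Groups with fewer than ``min_n`` instances are skipped (their keys are
    returned separately), mirroring the exclusion of cell lines assayed
    against only one or two compounds.
    """
    col = {"cancer_type": "cancer_type", "cell_line": "cell_line_id", "drug": "drug_id"}.get(axis)
    if col is None:
        raise UsageError(f"unknown axis {axis!r}")
    df = pd.DataFrame(instances).copy()
    df["_pred"] = np.asarray(predictions, dtype=float)
    reports, skipped = [], []
    for key, grp in df.groupby(col, sort=True):
        if len(grp) < min_n:
            skipped.append(str(key))
            continue
        try:
            reports.append(evaluate(grp["ln_ic50"], grp["_pred"], group=axis, key=str(key)))
        except UndefinedMetricError:
            skipped.append(str(key))
    return reports, skipped


def baseline_models(X_train, y_train, X_test, y_test, seed: int = 0,
                    rf_estimators: int = 100):
    """Random-forest and support-vector regression baselines on the same features.

    Both are fit on the identical concatenated fingerprint matrix and scored
    with the same metrics as the convolutional ensemble.
    """
    rf = RandomForestRegressor(n_estimators=rf_estimators, random_state=seed, n_jobs=1)
    rf.fit(X_train, y_train)
    svm = SVR()
    svm.fit(X_train, y_train)
    return {
        "random_forest": evaluate(y_test, rf.predict(X_test), group="overall", key="random_forest"),
        "svm": evaluate(y_test, svm.predict(X_test), group="overall", key="svm"),
    }


def reports_frame(reports) -> pd.DataFrame:
    """Tabulate a list of EvalReports."""
    return pd.DataFrame([r.to_dict() for r in reports])
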