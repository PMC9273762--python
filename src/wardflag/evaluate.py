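"""Imbalance-aware evaluation, bootstrap CIs, covariate balance, baselines.

AUC-PRC is computed by step-wise (non-interpolated) integration of the
precision-recall curve; linear interpolation is optimistically biased on
imbalanced data.  Confidence intervals follow the Student-t construction on
stratified bootstrap resamples that preserve the test prevalence exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .config import RunConfig
from .features import FEATURE_COLUMNS
from .forest import TreeSpec, draw_subsample

log = logging.getLogger(__name__)


def auc_roc(probs, labels) -> float:
    """Rank-based (Mann-Whitney) AUC-ROC with tie correction."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, np.asarray(probs, dtype=float)))


def average_precision(probs, labels) -> float:
    """AUC-PRC by step integration: sum of (ΔR · P) over thresholds."""
    y = np.asarray(labels, dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        return float("nan")
    return float(average_precision_score(y, np.asarray(probs, dtype=float)))


@dataclass
class MetricsReport:
    """Discrimination and threshold metrics at a stated decision threshold."""

    auc_roc: float
    auc_prc: float
    precision: float
    recall: float
    npv: float
    f1: float
    threshold: float
    n: int
    prevalence: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compute_metrics(probs, labels, threshold: float = 0.5) -> MetricsReport:
    """Confusion-matrix metrics at ``p > threshold`` plus both AUCs.

    With single-class labels the AUCs are undefined (NaN) but threshold
    metrics are still computed.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = p > threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    f1 = (
        2 * precision * recall / (precision + recall)
        if np.isfinite(precision) and np.isfinite(recall) and precision + recall > 0
        else float("nan")
    )
    return MetricsReport(
        auc_roc=auc_roc(p, y),
        auc_prc=average_precision(p, y),
        precision=precision,
        recall=recall,
        npv=npv,
        f1=f1,
        threshold=threshold,
        n=len(y),
        prevalence=float(y.mean()) if len(y) else float("nan"),
    )


def stratified_resample_indices(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One with-replacement resample drawn within class, preserving prevalence."""
    y = np.asarray(labels, dtype=int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    return np.concatenate(
        [pos[rng.integers(0, len(pos), len(pos))], neg[rng.integers(0, len(neg), len(neg))]]
    )


def stratified_bootstrap_ci(
    probs,
    labels,
    R: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
    method: str = "t",
) -> pd.DataFrame:
    """Per-metric mean and 95% CI over R class-stratified resamples.

    Resamples are drawn with replacement within each class so every
    resample reproduces the test prevalence exactly.  The default CI is the
    Student-t construction ``mean ± t_{0.975,R-1} · sd/√R``; percentile
    intervals are available with ``method="percentile"``.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present for stratified resampling")
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(R):
        idx = stratified_resample_indices(y, rng)
        records.append(compute_metrics(p[idx], y[idx], threshold).to_dict())
    df = pd.DataFrame(records)
    rows = []
    for metric in ("auc_roc", "auc_prc", "precision", "recall", "npv", "f1"):
        vals = df[metric].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            rows.append({"metric": metric, "mean": np.nan, "ci_lo": np.nan, "ci_hi": np.nan, "R": R})
            continue
        m = float(vals.mean())
        if method == "percentile":
            lo, hi = np.percentile(vals, [2.5, 97.5])
        else:
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            half = stats.t.ppf(0.975, len(vals) - 1) * sd / np.sqrt(len(vals))
            lo, hi = m - half, m + half
        rows.append({"metric": metric, "mean": m, "ci_lo": float(lo), "ci_hi": float(hi), "R": R})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# covariate balance


def _smd_continuous(a: np.ndarray, b: np.ndarray) -> float:
    s2 = (a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2) / 2.0
    diff = abs(a.mean() - b.mean())
    if s2 == 0:
        return 0.0 if diff == 0 else float("inf")
    return float(diff / np.sqrt(s2))


def _smd_categorical(a: pd.Series, b: pd.Series) -> float:
    """Multinomial standardised difference (Mahalanobis form on proportions)."""
    levels = sorted(set(a.unique()) | set(b.unique()))[1:]  # drop one reference level
    if not levels:
        return 0.0
    pa = np.array([(a == l).mean() for l in levels])
    pb = np.array([(b == l).mean() for l in levels])
    pm = (pa + pb) / 2.0
    S = (np.diag(pa) - np.outer(pa, pa) + np.diag(pb) - np.outer(pb, pb)) / 2.0
    diff = pa - pb
    try:
        return float(np.sqrt(diff @ np.linalg.pinv(S) @ diff))
    except np.linalg.LinAlgError:
        return float("nan")


def covariate_balance(
    train: pd.DataFrame, test: pd.DataFrame, variables: list[str] | None = None
) -> pd.DataFrame:
    """Welch-t / chi-square balance table with standardised mean differences."""
    variables = variables or [c for c in train.columns if c in test.columns]
    rows = []
    for var in variables:
        a, b = train[var].dropna(), test[var].dropna()
        if pd.api.types.is_numeric_dtype(train[var]) and train[var].nunique() > 2:
            t_p = stats.ttest_ind(a, b, equal_var=False).pvalue if len(a) > 1 and len(b) > 1 else np.nan
            rows.append(
                {
                    "variable": var,
                    "train_summary": f"{a.mean():.2f} ({a.std(ddof=1):.2f})",
                    "test_summary": f"{b.mean():.2f} ({b.std(ddof=1):.2f})",
                    "p_value": float(t_p),
                    "smd": _smd_continuous(a.to_numpy(dtype=float), b.to_numpy(dtype=float)),
                }
            )
        else:
            levels = sorted(set(a.unique()) | set(b.unique()))
            tab = np.array(
                [[(a == l).sum() for l in levels], [(b == l).sum() for l in levels]]
            )
            if tab.shape[1] > 1 and (tab.sum(axis=0) > 0).all():
                chi_p = stats.chi2_contingency(tab).pvalue
            else:
                chi_p = np.nan
            rows.append(
                {
                    "variable": var,
                    "train_summary": "/".join(f"{(a == l).mean():.1%}" for l in levels),
                    "test_summary": "/".join(f"{(b == l).mean():.1%}" for l in levels),
                    "p_value": float(chi_p),
                    "smd": _smd_categorical(a, b),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# baseline comparison harness (thin wrappers over standard implementations)


def _make_baseline(name: str, seed: int):
    if name == "LR":
        return make_pipeline(
            SimpleImputer(strategy="median"),
            StandardScaler(),
            LogisticRegression(penalty="l1", solver="liblinear", C=1.0, random_state=seed),
        )
    if name == "DT":
        return DecisionTreeClassifier(max_depth=8, min_samples_leaf=5, random_state=seed)
    if name == "RF":
        return RandomForestClassifier(n_estimators=50, max_depth=8, random_state=seed, n_jobs=1)
    if name == "XGB":
        import xgboost as xgb

        return xgb.XGBClassifier(
            n_estimators=100,
            max_depth=5,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    raise ValueError(f"unknown baseline {name!r}")


def run_baselines(
    train: pd.DataFrame,
    test: pd.DataFrame,
    label_col: str,
    config: RunConfig | None = None,
    models: tuple[str, ...] = ("LR", "DT", "RF", "XGB"),
    n_bootstrap: int | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Train each baseline on the same encounter-level sub-samples as EF
    (shared seeds) and aggregate by probability averaging."""
    config = config or RunConfig()
    B = n_bootstrap if n_bootstrap is not None else config.n_bootstrap
    Xtr = train[FEATURE_COLUMNS].to_numpy(dtype=float)
    ytr = train[label_col].to_numpy(dtype=int)
    Xte = test[FEATURE_COLUMNS].to_numpy(dtype=float)
    yte = test[label_col].to_numpy(dtype=int)
    rows = []
    for name in models:
        try:
            _make_baseline(name, 0)
        except ImportError as exc:  # optional dependency absent
            warnings.warn(f"baseline {name} skipped: {exc}", stacklevel=2)
            continue
        acc = np.zeros(len(test))
        n_ok = 0
        for b in range(B):
            seed = int(config.random_seed + b)
            sub = draw_subsample(train, label_col, seed, balance=config.balance)
            clf = _make_baseline(name, seed % (2**31 - 1))
            yb = ytr[sub.indices]
            if len(np.unique(yb)) < 2:
                continue
            clf.fit(Xtr[sub.indices], yb)
            proba = clf.predict_proba(Xte)
            acc += proba[:, list(clf.classes_).index(1)]
            n_ok += 1
        if n_ok == 0:
            continue
        report = compute_metrics(acc / n_ok, yte, threshold)
        rows.append({"model": name, **report.to_dict()})
    return pd.DataFrame(rows)
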