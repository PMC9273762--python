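"""Probability calibration curves and the deterioration risk index.

The calibration curve bins predictions into probability quantiles (default
10) and compares mean predicted probability with the observed event
proportion (Wilson 95% intervals).  Predicted probabilities then map to a
three-level susceptibility grouping with strict thresholds: index 1 for
p > 0.95, index 2 for 0.85 < p <= 0.95, index 3 for 0.70 < p <= 0.85, and
no index at or below 0.70.  Boundary values fall to the lower-risk index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint


def calibration_curve(
    probs: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Quantile-binned reliability summary.

    Bins are equal-count probability quantiles with ties kept together;
    when fewer distinct probabilities than bins exist, bins merge and the
    returned frame simply has fewer rows.  Columns: ``bin``, ``mean_pred``,
    ``obs_prop``, ``n``, ``ci_lo``, ``ci_hi``.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.unique(np.quantile(probs, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:  # constant predictions: a single merged bin
        bin_idx = np.zeros(len(probs), dtype=int)
        n_eff = 1
    else:
        bin_idx = np.clip(np.searchsorted(edges, probs, side="right") - 1, 0, len(edges) - 2)
        n_eff = len(edges) - 1
    rows = []
    for b in range(n_eff):
        sel = bin_idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        k = int(labels[sel].sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append(
            {
                "bin": b,
                "mean_pred": float(probs[sel].mean()),
                "obs_prop": k / n,
                "n": n,
                "ci_lo": float(lo),
                "ci_hi": float(hi),
            }
        )
    return pd.DataFrame(rows)


def assign_risk_index(
    probs,
    thresholds: tuple[float, float, float] = (0.95, 0.85, 0.70),
    mode: str = "threshold",
) -> np.ndarray:
    """Vectorised risk-index assignment; 0 encodes "no index".

    ``mode="threshold"`` (default) reads the thresholds as fixed
    probabilities; ``mode="quantile"`` reads them as population quantile
    levels of the supplied scores (top 5%/15%/30% of this batch), which
    coincides with the fixed reading only when the score distribution
    matches the levels.
    """
    t1, t2, t3 = thresholds
    if not t1 > t2 > t3:
        raise ValueError("thresholds must be strictly decreasing")
    p = np.atleast_1d(np.asarray(probs, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if mode == "quantile":
        t1, t2, t3 = (float(np.quantile(p, t)) for t in (t1, t2, t3))
    elif mode != "threshold":
        raise ValueError(f"unknown mode {mode!r}")
    idx = np.zeros(len(p), dtype=int)
    idx[p > t3] = 3
    idx[p > t2] = 2
    idx[p > t1] = 1
    return idx


def risk_group_assessment(
    probs: np.ndarray,
    labels: np.ndarray,
    thresholds: tuple[float, float, float] = (0.95, 0.85, 0.70),
) -> pd.DataFrame:
    """Per-risk-index precision and recall.

    Two recalls are reported: ``recall_within`` uses the group itself as
    denominator (identically 1 for any non-empty group under the threshold
    construction, since no alerted-group positive can be missed within its
    own group) and ``recall_vs_all_events`` divides the group's true
    positives by all positives in the evaluated set.  Empty groups get NaN
    precision, never 0.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    idx = assign_risk_index(p, thresholds)
    n_pos_total = int(y.sum())
    rows = []
    for g in (1, 2, 3):
        sel = idx == g
        n = int(sel.sum())
        tp = int(y[sel].sum())
        rows.append(
            {
                "risk_index": g,
                "n": n,
                "precision": tp / n if n else float("nan"),
                "recall_within": 1.0 if n else float("nan"),
                "recall_vs_all_events": tp / n_pos_total if n_pos_total else float("nan"),
            }
        )
    return pd.DataFrame(rows)
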