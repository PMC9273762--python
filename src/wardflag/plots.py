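"""Plain matplotlib renderings of explanations and calibration curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_global_importance(importance: pd.Series, top_k: int = 10, path=None):
    """Horizontal bar chart of mean |φ| per feature, largest on top."""
    top = importance.head(top_k)[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(top) + 1))
    ax.barh(top.index, top.to_numpy(), color="steelblue")
    ax.set_xlabel("mean |φ| (probability units)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_contribution_summary(
    phis: np.ndarray, values: np.ndarray, feature_names: list[str], top_k: int = 10, path=None
):
    """Beeswarm-style summary: one jittered row per feature, colour = raw
    feature value (red high, blue low), x = Shapley contribution."""
    mean_abs = np.abs(phis).mean(axis=0)
    order = np.argsort(-mean_abs)[:top_k]
    rng = np.random.default_rng(0)
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(order) + 1))
    for row, j in enumerate(order[::-1]):
        v = values[:, j]
        with np.errstate(invalid="ignore"):
            lo, hi = np.nanmin(v), np.nanmax(v)
        c = (v - lo) / (hi - lo) if hi > lo else np.full(len(v), 0.5)
        c = np.where(np.isfinite(c), c, 0.5)
        ax.scatter(
            phis[:, j],
            row + rng.uniform(-0.25, 0.25, len(v)),
            c=c,
            cmap="coolwarm",
            s=12,
            edgecolors="none",
        )
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([feature_names[j] for j in order[::-1]])
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("φ (probability units)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_calibration(curve: pd.DataFrame, path=None):
    """Reliability plot: observed proportion on x, mean predicted on y."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.errorbar(
        curve["obs_prop"],
        curve["mean_pred"],
        xerr=[curve["obs_prop"] - curve["ci_lo"], curve["ci_hi"] - curve["obs_prop"]],
        fmt="o-",
        capsize=3,
    )
    ax.set_xlabel("observed event proportion")
    ax.set_ylabel("mean predicted probability")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
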