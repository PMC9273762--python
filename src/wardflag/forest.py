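"""Encounter-based forest: class-balanced encounter-level bootstrap ensemble.

Ward feature tables contain many correlated rows per hospital encounter, and
sicker, longer-staying patients contribute disproportionately many rows.  A
conventional row-level bootstrap therefore over-represents them.  The
encounter-based forest (EF) instead draws, for every bootstrap sub-sample,
exactly one prediction point per unique encounter:

* stage 1 — within each encounter, one point is selected with probability
  proportional to the inverse frequency of its label class inside that
  encounter (an encounter with both classes contributes either with equal
  chance);
* stage 2 (balancing on) — the one-per-encounter pool is re-sampled with
  replacement at the pool's size, drawing half the draws from each class
  (the inverse-class-frequency weighting conditioned on exact balance), so
  every sub-sample is evenly split between event and no-event rows.

One depth-limited CART tree is fitted per sub-sample and the ensemble
probability is the plain average of the per-tree leaf probabilities.
Hyperparameters are chosen on a chronologically later validation partition
by maximising the area under the precision-recall curve, the appropriate
selection criterion at 5–8% prevalence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .config import RunConfig
from .features import FEATURE_COLUMNS, SCHEMA_VERSION

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TreeSpec:
    """Hyperparameters of each ensemble member."""

    max_depth: int | None = 8
    min_samples_leaf: int = 5
    criterion: str = "gini"

    def __post_init__(self) -> None:
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")


def default_grid() -> list[TreeSpec]:
    return [
        TreeSpec(max_depth=d, min_samples_leaf=m)
        for d in (3, 5, 8, 12, None)
        for m in (1, 5, 20, 50)
    ]


@dataclass
class Subsample:
    """Row indices of one bootstrap sub-sample plus realised class counts."""

    indices: np.ndarray
    n_positive: int
    n_negative: int

    @property
    def positive_fraction(self) -> float:
        tot = self.n_positive + self.n_negative
        return self.n_positive / tot if tot else float("nan")


def draw_subsample(
    table: pd.DataFrame,
    label_col: str,
    seed: int,
    balance: str = "pool",
    encounter_sampling: str = "once",
) -> Subsample:
    """Draw one encounter-level bootstrap sub-sample.

    Stage 1 keeps every encounter once (``encounter_sampling="once"``, the
    default — randomness comes from within-encounter selection); the
    non-default ``"replacement"`` mode bootstraps encounters themselves,
    at the cost of an encounter appearing more than once.  Stage 2
    (``balance="pool"``) re-samples the pool with replacement to an exact
    50/50 class split.  Deterministic under ``seed``.
    """
    if len(table) == 0:
        raise ValueError("feature table is empty")
    rng = np.random.default_rng(seed)
    eids = table["encounter_id"].to_numpy()
    labels = table[label_col].to_numpy(dtype=int)

    # stage 1: within-encounter inverse-class-frequency selection via the
    # Gumbel-max trick (one vectorised pass, no per-encounter python loop)
    df = pd.DataFrame({"eid": eids, "label": labels})
    class_n = df.groupby(["eid", "label"])["label"].transform("size").to_numpy()
    weight = 1.0 / class_n
    keys = np.log(weight) + rng.gumbel(size=len(df))
    order = np.lexsort((keys, eids))  # within eid, ascending key
    # last row of each eid group after sorting by key = argmax
    sorted_eids = eids[order]
    is_last = np.r_[sorted_eids[1:] != sorted_eids[:-1], True]
    stage1 = order[is_last]
    if encounter_sampling == "replacement":
        stage1 = stage1[rng.integers(0, len(stage1), len(stage1))]
    elif encounter_sampling != "once":
        raise ValueError(f"unknown encounter_sampling {encounter_sampling!r}")

    pool_labels = labels[stage1]
    if balance == "pool":
        n_pos = int((pool_labels == 1).sum())
        n_neg = int((pool_labels == 0).sum())
        if n_pos == 0 or n_neg == 0:
            warnings.warn(
                "single-class pool: balancing disabled for this sub-sample", stacklevel=2
            )
            chosen = stage1
        else:
            n = len(stage1)
            pos_pool = stage1[pool_labels == 1]
            neg_pool = stage1[pool_labels == 0]
            n_pos_draw = n // 2
            chosen = np.concatenate(
                [
                    pos_pool[rng.integers(0, len(pos_pool), n_pos_draw)],
                    neg_pool[rng.integers(0, len(neg_pool), n - n_pos_draw)],
                ]
            )
    elif balance == "off":
        chosen = stage1
    else:
        raise ValueError(f"unknown balance mode {balance!r}")

    final_labels = labels[chosen]
    return Subsample(
        indices=np.sort(chosen),
        n_positive=int((final_labels == 1).sum()),
        n_negative=int((final_labels == 0).sum()),
    )


@dataclass
class EFModel:
    """Fitted encounter-based forest."""

    trees: list[DecisionTreeClassifier]
    seeds: list[int]
    feature_names: list[str]
    label_col: str
    tree_spec: TreeSpec
    schema_version: str = SCHEMA_VERSION
    config_hash: str = ""
    leaf_smoothing: float = 0.0

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _tree_p1(tree: DecisionTreeClassifier, X: np.ndarray, smoothing: float = 0.0) -> np.ndarray:
    """Positive-class probability, tolerant of single-class trees."""
    proba = tree.predict_proba(X)
    classes = list(tree.classes_)
    if 1 not in classes:
        p1 = np.zeros(len(X))
    else:
        p1 = proba[:, classes.index(1)]
    if smoothing > 0.0:
        # Laplace-style shrink toward 1/2
        n = tree.tree_.n_node_samples[tree.apply(X)]
        p1 = (p1 * n + smoothing) / (n + 2.0 * smoothing)
    return p1


def fit_ef(
    train_table: pd.DataFrame,
    config: RunConfig,
    tree_spec: TreeSpec | None = None,
    label_col: str | None = None,
    n_bootstrap: int | None = None,
) -> EFModel:
    """Fit B trees, tree ``b`` on the sub-sample drawn with ``base_seed + b``."""
    tree_spec = tree_spec or TreeSpec()
    label_col = label_col or _default_label(train_table)
    B = n_bootstrap if n_bootstrap is not None else config.n_bootstrap
    if B < 1:
        raise ValueError("number of bootstrap sub-samples must be >= 1")
    X = train_table[FEATURE_COLUMNS].to_numpy(dtype=float)
    trees, seeds = [], []
    for b in range(B):
        seed = int(config.random_seed + b)
        sub = draw_subsample(train_table, label_col, seed, balance=config.balance)
        tree = DecisionTreeClassifier(
            criterion=tree_spec.criterion,
            max_depth=tree_spec.max_depth,
            min_samples_leaf=tree_spec.min_samples_leaf,
            random_state=seed % (2**31 - 1),
        )
        y = train_table[label_col].to_numpy(dtype=int)[sub.indices]
        tree.fit(X[sub.indices], y)
        trees.append(tree)
        seeds.append(seed)
    return EFModel(
        trees=trees,
        seeds=seeds,
        feature_names=list(FEATURE_COLUMNS),
        label_col=label_col,
        tree_spec=tree_spec,
        config_hash=config.config_hash(),
        leaf_smoothing=config.leaf_smoothing,
    )


def _default_label(table: pd.DataFrame) -> str:
    labels = [c for c in table.columns if c.startswith("label_")]
    if len(labels) != 1:
        raise ValueError(
            "label column ambiguous; pass label_col explicitly "
            f"(found {labels or 'none'})"
        )
    return labels[0]


def _check_schema(model: EFModel, rows: pd.DataFrame) -> None:
    missing = [c for c in model.feature_names if c not in rows.columns]
    if missing:
        raise ValueError(f"rows do not conform to model schema; missing: {', '.join(missing)}")


def predict_proba(model: EFModel, rows: pd.DataFrame) -> np.ndarray:
    """Bootstrap-aggregated probability: mean of per-tree leaf probabilities."""
    _check_schema(model, rows)
    X = rows[model.feature_names].to_numpy(dtype=float)
    acc = np.zeros(len(rows))
    for tree in model.trees:
        acc += _tree_p1(tree, X, model.leaf_smoothing)
    return acc / model.n_trees


def save_model(model: EFModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> EFModel:
    model = joblib.load(path)
    if not isinstance(model, EFModel):
        raise TypeError(f"{path} does not contain an EFModel")
    return model


def _spec_sort_key(spec: TreeSpec) -> tuple[float, float]:
    depth = float("inf") if spec.max_depth is None else spec.max_depth
    return (depth, -spec.min_samples_leaf)


def tune_hyperparameters(
    train_early: pd.DataFrame,
    validation: pd.DataFrame,
    grid: list[TreeSpec] | None = None,
    config: RunConfig | None = None,
    label_col: str | None = None,
) -> tuple[TreeSpec, pd.DataFrame]:
    """Grid search maximising validation AUC-PRC.

    The fit partition must be chronologically earlier than the validation
    partition (caller's responsibility; the pipeline splits by admission
    time).  Ties break toward the simpler model: smaller depth, then larger
    leaf size.  Returns the winning spec and the per-grid-point results.
    """
    from .evaluate import average_precision

    grid = grid if grid is not None else default_grid()
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    config = config or RunConfig()
    label_col = label_col or _default_label(train_early)
    y_val = validation[label_col].to_numpy(dtype=int)
    rows = []
    for spec in grid:
        model = fit_ef(
            train_early, config, spec, label_col, n_bootstrap=config.n_bootstrap_tune
        )
        p = predict_proba(model, validation)
        rows.append(
            {
                "max_depth": spec.max_depth,
                "min_samples_leaf": spec.min_samples_leaf,
                "auc_prc": average_precision(p, y_val),
            }
        )
    results = pd.DataFrame(rows)
    best_score = results["auc_prc"].max()
    tied = [
        spec
        for spec, score in zip(grid, results["auc_prc"])
        if score >= best_score - 1e-12
    ]
    best = min(tied, key=_spec_sort_key)
    return best, results
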