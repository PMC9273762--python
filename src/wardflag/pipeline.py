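"""End-to-end orchestration: split, tune, fit, evaluate, calibrate, explain.

The split is chronological by encounter admission time (never by row, so an
encounter's observations are never divided across partitions): the earliest
fraction of encounters fits the hyperparameter scan, the middle fraction
validates it, and the latest fraction is the held-out test set.  A leakage
guard asserts on every run that no test-period encounter appears in any
training sub-sample.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, cohort, evaluate, explain, features, forest, io, synthetic
from .config import RunConfig, ThresholdProtocol

log = logging.getLogger(__name__)


@dataclass
class PipelineRun:
    """Record of one pipeline execution for reproducibility audits."""

    config_hash: str
    seed: int
    stage_seconds: dict[str, float] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)  # file -> sha256
    cohort_report: dict[str, int] = field(default_factory=dict)
    split: dict[str, list[str]] = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True, default=str)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def chronological_split(
    encounters: pd.DataFrame, fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
) -> tuple[list[str], list[str], list[str]]:
    """Split encounter ids by admission time into early/validation/test."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    ordered = encounters.sort_values(
        ["admission_time", "encounter_id"], kind="mergesort"
    )["encounter_id"].tolist()
    n = len(ordered)
    a = int(round(fractions[0] * n))
    b = a + int(round(fractions[1] * n))
    return ordered[:a], ordered[a:b], ordered[b:]


def check_no_leakage(train_ids, test_ids) -> None:
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise AssertionError(
            f"leakage: {len(overlap)} encounters shared between train and test "
            f"(e.g. {sorted(overlap)[:3]})"
        )


def check_date_ranges(train_enc: pd.DataFrame, test_enc: pd.DataFrame) -> None:
    if len(train_enc) == 0 or len(test_enc) == 0:
        return
    if train_enc["admission_time"].max() > test_enc["admission_time"].min():
        raise ValueError("train and test admission-date ranges overlap")


def run_all(
    config: RunConfig,
    out_dir,
    encounters: pd.DataFrame | None = None,
    observations: pd.DataFrame | None = None,
    generator_params: synthetic.GeneratorParams | None = None,
    phenotypes=None,
    protocol: ThresholdProtocol | None = None,
    window_h: float | None = None,
    grid=None,
    with_baselines: bool = False,
    baseline_models: tuple[str, ...] = ("LR", "DT", "RF", "XGB"),
    explain_top_k: int = 10,
    n_explain_rows: int = 50,
) -> PipelineRun:
    """Execute the full workflow and persist all artifacts under ``out_dir``.

    With no input tables, synthetic data are generated from
    ``generator_params`` (seeded from the config seed).  Returns the
    :class:`PipelineRun` with stage timings and a sha256 manifest; rerunning
    with the same config and seed reproduces identical digests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = protocol or ThresholdProtocol()
    window_h = window_h if window_h is not None else config.prediction_windows_h[-1]
    label_col = cohort.label_column(window_h)
    run = PipelineRun(config_hash=config.config_hash(), seed=config.random_seed)
    t0 = time.time()

    def tick(stage: str) -> None:
        nonlocal t0
        run.stage_seconds[stage] = round(time.time() - t0, 3)
        log.info("stage %-12s %6.1fs", stage, run.stage_seconds[stage])
        t0 = time.time()

    if encounters is None or observations is None:
        params = (generator_params or synthetic.GeneratorParams()).with_(
            random_seed=config.random_seed
        )
        encounters, observations, truth = synthetic.generate(params, phenotypes)
        io.write_encounters(out / "encounters.csv", encounters)
        io.write_observations(out / "observations.csv", observations)
        truth_out = truth.copy()
        truth_out["onset_time"] = truth_out["onset_time"].dt.strftime("%Y-%m-%dT%H:%M")
        truth_out.to_csv(out / "ground_truth.csv", index=False)
        tick("synth")

    kept, report = cohort.filter_cohort(encounters, observations, config.min_los_h, protocol)
    run.cohort_report = dict(report.stages())
    for stage, count in report.stages():
        log.info("cohort %-18s n=%d", stage, count)
    obs = observations[observations["encounter_id"].isin(kept)]
    enc = encounters[encounters["encounter_id"].isin(kept)]
    flags = cohort.detect_red_flags(obs, protocol)
    tick("label")

    table = features.assemble_design_matrix(
        enc, obs, flags, config, protocol, cohort_ids=kept
    )
    io.write_table(out / "features.csv", table)
    tick("features")

    early_ids, valid_ids, test_ids = chronological_split(enc)
    run.split = {"early": early_ids, "validation": valid_ids, "test": test_ids}
    train_ids = early_ids + valid_ids
    check_no_leakage(train_ids, test_ids)
    check_date_ranges(
        enc[enc["encounter_id"].isin(train_ids)], enc[enc["encounter_id"].isin(test_ids)]
    )
    t_early = table[table["encounter_id"].isin(early_ids)]
    t_valid = table[table["encounter_id"].isin(valid_ids)]
    t_train = table[table["encounter_id"].isin(train_ids)]
    t_test = table[table["encounter_id"].isin(test_ids)].reset_index(drop=True)

    if grid is None:
        grid = [forest.TreeSpec(max_depth=d, min_samples_leaf=m) for d in (3, 5, 8) for m in (5, 20)]
    spec, grid_results = forest.tune_hyperparameters(t_early, t_valid, grid, config, label_col)
    io.write_table(out / "grid_results.csv", grid_results)
    tick("tune")

    model = forest.fit_ef(t_train, config, spec, label_col)
    # leakage guard at the sub-sample level: every training row must come
    # from a training-period encounter (holds by construction; asserted)
    check_no_leakage(set(t_train["encounter_id"]), test_ids)
    forest.save_model(model, out / "ef_model.joblib")
    tick("train")

    probs = forest.predict_proba(model, t_test)
    preds = t_test[["encounter_id", "time", label_col]].copy()
    preds["prob"] = probs
    preds["risk_index"] = calibration.assign_risk_index(probs, config.risk_thresholds)
    io.write_table(out / "predictions.csv", preds)
    tick("predict")

    y_test = t_test[label_col].to_numpy(dtype=int)
    metrics = evaluate.compute_metrics(probs, y_test)
    run.metrics["ef"] = metrics.to_dict()
    if with_baselines:
        base = evaluate.run_baselines(
            t_train, t_test, label_col, config, baseline_models,
            n_bootstrap=min(config.n_bootstrap, 25),
        )
        base.to_csv(out / "baselines.csv", index=False)
        run.metrics["baselines"] = base.to_dict(orient="records")
    tick("evaluate")

    curve = calibration.calibration_curve(probs, y_test, config.n_calibration_bins)
    io.write_table(out / "calibration.csv", curve)
    groups = calibration.risk_group_assessment(probs, y_test, config.risk_thresholds)
    io.write_table(out / "risk_groups.csv", groups)
    run.metrics["risk_groups"] = groups.to_dict(orient="records")
    tick("calibrate")

    rng = np.random.default_rng(config.random_seed)
    n_rows = min(n_explain_rows, len(t_test))
    sample = t_test.iloc[np.sort(rng.choice(len(t_test), size=n_rows, replace=False))]
    importance = explain.global_importance(model, sample)
    importance.rename("mean_abs_phi").to_frame().reset_index(names="feature").to_csv(
        out / "global_importance.csv", index=False, float_format=io.FLOAT_FMT
    )
    run.metrics["top_features"] = importance.head(explain_top_k).index.tolist()
    tick("explain")

    for f in sorted(out.iterdir()):
        if f.is_file() and f.suffix == ".csv":
            run.manifest[f.name] = _digest(f)
    run.write(out / "run.json")
    return run
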