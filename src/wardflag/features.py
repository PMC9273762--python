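"""Rolling-window feature engineering for irregular vital-sign streams.

Each prediction point becomes an 82-column vector: for each of the seven
aggregable vitals, eleven window statistics over the 24-h lookback
``(t-H, t]`` (min, max, mean, median, population SD, frequency, number of
distinct vitals at ``t``, number of observations in the window, last value,
interval between the last two observations, slope of the last two); plus
binary O2-flow and AVPU presence flags, age, sex (male=1) and length of stay
at ``t`` in minutes.  Vitals unobserved in the window get missing aggregates,
which the tree models route through their learned missing branch.

Frequency is a rate, ``n_in_window / H`` observations per hour, so it stays
distinct from the raw window count whenever H is reconfigured.  The
per-vital ``n_at_current`` columns share one underlying value (distinct
vitals measured at the point's timestamp); they are replicated per vital to
keep the per-vital feature blocks uniform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AGG_VITALS, RunConfig, ThresholdProtocol
from . import cohort as _cohort

SCHEMA_VERSION = "wardflag-features-1"

PER_VITAL_STATS = (
    "min",
    "max",
    "mean",
    "median",
    "std",
    "freq",
    "n_at_current",
    "n_window",
    "last",
    "last_interval",
    "slope",
)

GLOBAL_FEATURES = ("O2_flow_flag", "AVPU_flag", "age", "sex_male", "los_min")

FEATURE_COLUMNS: list[str] = [
    f"{v}_{s}" for v in AGG_VITALS for s in PER_VITAL_STATS
] + list(GLOBAL_FEATURES)

ID_COLUMNS = ["encounter_id", "time"]


def compute_slope(y1: float, t1, y2: float, t2) -> float:
    """Change per minute over the two most recent observations.

    ``t2`` must be the later timestamp; coincident timestamps yield missing
    (no division failure), as does a single observation upstream.
    """
    dt_min = (pd.Timestamp(t2) - pd.Timestamp(t1)).total_seconds() / 60.0
    if dt_min <= 0:
        return float("nan")
    return (y2 - y1) / dt_min


def _window_stats(times: np.ndarray, values: np.ndarray, lo: int, hi: int) -> list[float]:
    """Aggregates for one vital over the slice [lo, hi) of its sorted stream."""
    n = hi - lo
    if n <= 0:
        return [np.nan] * 5 + [0.0, np.nan, 0.0, np.nan, np.nan, np.nan]
    seg = values[lo:hi]
    last = float(seg[-1])
    if n >= 2:
        dt = (times[hi - 1] - times[hi - 2]) / np.timedelta64(1, "m")
        last_interval = float(dt)
        slope = (seg[-1] - seg[-2]) / dt if dt > 0 else np.nan
        std = float(seg.std())  # population formula; 0 only when all equal
    else:
        last_interval = np.nan
        slope = np.nan
        std = 0.0
    return [
        float(seg.min()),
        float(seg.max()),
        float(seg.mean()),
        float(np.median(seg)),
        std,
        np.nan,  # freq filled by caller (needs H)
        np.nan,  # n_at_current filled by caller
        float(n),
        last,
        last_interval,
        float(slope) if np.isfinite(slope) else np.nan,
    ]


def compute_window_features(
    obs_enc: pd.DataFrame,
    t: pd.Timestamp,
    historical_window_h: float = 24.0,
    admission_time: pd.Timestamp | None = None,
    age: float = np.nan,
    sex: str = "",
) -> dict[str, float]:
    """Feature dict for a single encounter at a single prediction time."""
    if admission_time is not None and t < admission_time:
        raise ValueError(f"prediction time {t} precedes admission {admission_time}")
    rows = _encounter_features(
        obs_enc,
        pd.DatetimeIndex([t]),
        historical_window_h,
        admission_time=admission_time,
        age=age,
        sex=sex,
    )
    return {c: rows[c][0] for c in FEATURE_COLUMNS}


def _encounter_features(
    obs_enc: pd.DataFrame,
    times: pd.DatetimeIndex,
    H_h: float,
    admission_time: pd.Timestamp | None,
    age: float,
    sex: str,
) -> dict[str, np.ndarray]:
    """Vectorised window aggregation for all prediction times of one encounter."""
    n_t = len(times)
    t_np = times.to_numpy()
    h_delta = np.timedelta64(round(H_h * 60), "m")
    out: dict[str, np.ndarray] = {}

    # distinct vitals measured at exactly t (shared across vital blocks)
    at_t = obs_enc.groupby("timestamp")["vital"].nunique()
    n_at_current = (
        at_t.reindex(times).fillna(0).to_numpy(dtype=float) if len(at_t) else np.zeros(n_t)
    )

    by_vital = {v: g for v, g in obs_enc.groupby("vital", sort=False)}
    for vital in AGG_VITALS:
        g = by_vital.get(vital)
        cols = np.empty((len(PER_VITAL_STATS), n_t))
        if g is None or len(g) == 0:
            for i in range(n_t):
                cols[:, i] = _window_stats(np.array([]), np.array([]), 0, 0)
        else:
            vt = g["timestamp"].to_numpy()
            vv = g["value"].to_numpy(dtype=float)
            lo = np.searchsorted(vt, t_np - h_delta, side="right")
            hi = np.searchsorted(vt, t_np, side="right")
            for i in range(n_t):
                cols[:, i] = _window_stats(vt, vv, lo[i], hi[i])
        cols[PER_VITAL_STATS.index("freq"), :] = cols[PER_VITAL_STATS.index("n_window"), :] / H_h
        cols[PER_VITAL_STATS.index("n_at_current"), :] = n_at_current
        for j, s in enumerate(PER_VITAL_STATS):
            out[f"{vital}_{s}"] = cols[j]

    for flag_vital, name in (("O2FLOW", "O2_flow_flag"), ("AVPU", "AVPU_flag")):
        g = by_vital.get(flag_vital)
        if g is None or len(g) == 0:
            out[name] = np.zeros(n_t)
        else:
            vt = g["timestamp"].to_numpy()
            lo = np.searchsorted(vt, t_np - h_delta, side="right")
            hi = np.searchsorted(vt, t_np, side="right")
            out[name] = (hi > lo).astype(float)

    out["age"] = np.full(n_t, age, dtype=float)
    out["sex_male"] = np.full(n_t, 1.0 if sex == "male" else 0.0)
    if admission_time is None:
        out["los_min"] = np.full(n_t, np.nan)
    else:
        out["los_min"] = (t_np - np.datetime64(admission_time)) / np.timedelta64(1, "m")
    return out


def assemble_design_matrix(
    encounters: pd.DataFrame,
    observations: pd.DataFrame,
    flags: pd.DataFrame,
    config: RunConfig | None = None,
    protocol: ThresholdProtocol | None = None,
    cohort_ids: list[str] | None = None,
) -> pd.DataFrame:
    """One labelled feature row per retained prediction point.

    Rows are ordered by ``(encounter_id, time)``; the column order is the
    versioned schema ``FEATURE_COLUMNS`` followed by per-window labels.
    """
    config = config or RunConfig()
    protocol = protocol or ThresholdProtocol()
    if cohort_ids is None:
        cohort_ids, _ = _cohort.filter_cohort(
            encounters, observations, config.min_los_h, protocol
        )
    enc = encounters[encounters["encounter_id"].isin(cohort_ids)]
    obs = observations[observations["encounter_id"].isin(cohort_ids)]
    points = _cohort.prediction_points(
        obs, flags, censor_after_first_flag=config.censor_after_first_flag
    )
    labelled = _cohort.label_all_windows(points, flags, config.prediction_windows_h)
    label_cols = [_cohort.label_column(w) for w in config.prediction_windows_h]

    enc_info = enc.set_index("encounter_id")
    frames = []
    for eid, g in labelled.groupby("encounter_id", sort=True):
        info = enc_info.loc[eid]
        obs_e = obs[obs["encounter_id"] == eid]
        times = pd.DatetimeIndex(g["time"])
        feats = _encounter_features(
            obs_e,
            times,
            config.historical_window_h,
            admission_time=info["admission_time"],
            age=float(info["age"]),
            sex=str(info["sex"]),
        )
        block = pd.DataFrame(feats, columns=FEATURE_COLUMNS)
        block.insert(0, "encounter_id", eid)
        block.insert(1, "time", times)
        for c in label_cols:
            block[c] = g[c].to_numpy()
        frames.append(block)
    if not frames:
        return pd.DataFrame(columns=ID_COLUMNS + FEATURE_COLUMNS + label_cols)
    table = pd.concat(frames, ignore_index=True)
    return table.sort_values(ID_COLUMNS, kind="mergesort").reset_index(drop=True)
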