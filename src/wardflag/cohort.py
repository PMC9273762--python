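"""Cohort selection, red-flag detection and per-window response labelling.

The cohort funnel keeps acute-care encounters with enough stay and data to
compute features and a response.  A red flag is any observation breaching its
vital's red-zone predicate.  The response at a prediction point ``t`` and
horizon ``W`` is 1 iff a red flag occurs in the half-open interval
``(t, t+W]`` — the method is pre-emptive, so a point at which a flag is
concurrently firing (flag at exactly ``t``) is not a prediction point at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ThresholdProtocol

log = logging.getLogger(__name__)

FLAG_COLUMNS = ["encounter_id", "timestamp", "vital", "value", "level"]


@dataclass
class CohortReport:
    """Per-stage retention counts of the selection funnel."""

    n_all: int = 0
    n_acute: int = 0
    n_min_los: int = 0
    n_has_vitals: int = 0
    n_label_computable: int = 0

    def stages(self) -> list[tuple[str, int]]:
        return [
            ("all", self.n_all),
            ("acute_care", self.n_acute),
            ("min_los", self.n_min_los),
            ("has_vitals", self.n_has_vitals),
            ("label_computable", self.n_label_computable),
        ]


def filter_cohort(
    encounters: pd.DataFrame,
    observations: pd.DataFrame,
    min_los_h: float = 24.0,
    protocol: ThresholdProtocol | None = None,
) -> tuple[list[str], CohortReport]:
    """Apply the staged cohort filters; returns kept ids and the funnel."""
    protocol = protocol or ThresholdProtocol()
    report = CohortReport(n_all=len(encounters))

    acute = encounters[encounters["care_type"] == "Acute Care"]
    report.n_acute = len(acute)

    los_min = (acute["discharge_time"] - acute["admission_time"]).dt.total_seconds() / 60.0
    long_enough = acute[los_min >= min_los_h * 60.0]
    report.n_min_los = len(long_enough)

    with_obs_ids = set(observations["encounter_id"].unique())
    has_vitals = long_enough[long_enough["encounter_id"].isin(with_obs_ids)]
    report.n_has_vitals = len(has_vitals)

    protocol_vitals = set(protocol.red_zones) | {"AVPU"}
    labelable_ids = set(
        observations.loc[observations["vital"].isin(protocol_vitals), "encounter_id"].unique()
    )
    final = has_vitals[has_vitals["encounter_id"].isin(labelable_ids)]
    report.n_label_computable = len(final)
    return final["encounter_id"].tolist(), report


def detect_red_flags(
    observations: pd.DataFrame, protocol: ThresholdProtocol | None = None
) -> pd.DataFrame:
    """One flag event per observation satisfying its vital's red predicate."""
    protocol = protocol or ThresholdProtocol()
    obs = observations
    mask = np.zeros(len(obs), dtype=bool)
    vital = obs["vital"].to_numpy()
    value = obs["value"].to_numpy(dtype=float)
    for v in pd.unique(obs["vital"]):
        sel = vital == v
        if v == "AVPU":
            mask[sel] = obs.loc[sel, "level"].isin(protocol.avpu_red).to_numpy()
        elif v in protocol.red_zones:
            lo, hi = protocol.red_zones[v]
            m = np.zeros(sel.sum(), dtype=bool)
            if lo is not None:
                m |= value[sel] < lo
            if hi is not None:
                m |= value[sel] > hi
            mask[sel] = m
        else:
            log.info("vital %s has no red-zone predicate; it never triggers", v)
    flags = obs.loc[mask, FLAG_COLUMNS].copy()
    return flags.sort_values(["encounter_id", "timestamp"], kind="mergesort").reset_index(
        drop=True
    )


def prediction_points(
    observations: pd.DataFrame,
    flags: pd.DataFrame,
    censor_after_first_flag: bool = False,
) -> pd.DataFrame:
    """Distinct observation timestamps usable as prediction points.

    A timestamp at which a red flag is concurrently firing is excluded
    (predicting an alert already raised is vacuous).  With censoring on, all
    points at or after the encounter's first flag are dropped.
    """
    pts = observations[["encounter_id", "timestamp"]].drop_duplicates()
    pts = pts.rename(columns={"timestamp": "time"})
    if len(flags):
        flag_keys = set(zip(flags["encounter_id"], flags["timestamp"]))
        concurrent = [
            (e, t) in flag_keys for e, t in zip(pts["encounter_id"], pts["time"])
        ]
        pts = pts[~np.asarray(concurrent)]
        if censor_after_first_flag:
            first = flags.groupby("encounter_id")["timestamp"].min()
            cut = pts["encounter_id"].map(first)
            pts = pts[cut.isna() | (pts["time"] < cut)]
    return pts.sort_values(["encounter_id", "time"], kind="mergesort").reset_index(drop=True)


def label_windows(points: pd.DataFrame, flags: pd.DataFrame, window_h: float) -> np.ndarray:
    """Binary response: 1 iff >=1 flag in ``(t, t+W]`` for that encounter."""
    labels = np.zeros(len(points), dtype=int)
    if len(flags) == 0 or len(points) == 0:
        return labels
    w = pd.Timedelta(minutes=round(window_h * 60))
    flag_times = {
        eid: np.sort(g["timestamp"].to_numpy())
        for eid, g in flags.groupby("encounter_id", sort=False)
    }
    for eid, idx in points.groupby("encounter_id", sort=False).groups.items():
        ft = flag_times.get(eid)
        if ft is None:
            continue
        t = points.loc[idx, "time"].to_numpy()
        left = np.searchsorted(ft, t, side="right")
        right = np.searchsorted(ft, t + w.to_numpy(), side="right")
        labels[points.index.get_indexer(idx)] = (right > left).astype(int)
    return labels


def label_all_windows(
    points: pd.DataFrame, flags: pd.DataFrame, windows_h: tuple[float, ...]
) -> pd.DataFrame:
    """Attach one ``label_{W}h`` column per horizon to the points table."""
    out = points.copy()
    for w in windows_h:
        out[label_column(w)] = label_windows(points, flags, w)
    return out


def label_column(window_h: float) -> str:
    return f"label_{window_h:g}h"
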