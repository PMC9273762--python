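"""Readers and writers for the long-format observation stream and tables.

File dialect: comma-separated UTF-8, ISO-8601 timestamps at minute
resolution, one observation per row.  Floats are written with 12 significant
digits so feature tables round-trip to that precision; ids and labels
round-trip bit-exactly.  Missing values are empty fields.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ALL_VITALS, AVPU_LEVELS, ValidityRanges

OBS_COLUMNS = ["encounter_id", "patient_id", "timestamp", "vital", "value"]
ENC_COLUMNS = [
    "encounter_id",
    "patient_id",
    "admission_time",
    "discharge_time",
    "age",
    "sex",
    "care_type",
]

FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    """Fatal structural problem in an input file."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")


def _to_minutes(ts: pd.Series) -> pd.Series:
    """Parse timestamps, flooring to minute resolution; NaT on failure."""
    parsed = pd.to_datetime(ts, errors="coerce", format="ISO8601")
    return parsed.dt.floor("min")


def read_observations(
    path, ranges: ValidityRanges | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long-format observation stream and screen implausible values.

    Returns ``(observations, rejections)``.  Observations are sorted by
    ``(encounter_id, timestamp)`` with numeric values in ``value`` (NaN for
    AVPU rows) and AVPU levels in ``level``.  Rejections carry the original
    row plus a ``reason`` column; AVPU rows are never range-screened.
    """
    ranges = ranges or ValidityRanges()
    raw = pd.read_csv(path, dtype={"encounter_id": str, "patient_id": str, "vital": str})
    _require_columns(raw, OBS_COLUMNS, path)
    raw = raw[OBS_COLUMNS].copy()

    ts = _to_minutes(raw["timestamp"].astype(str))
    vital = raw["vital"]
    value_str = raw["value"].astype(str).str.strip()
    is_avpu = vital == "AVPU"
    numeric = pd.to_numeric(raw["value"], errors="coerce")

    reason = pd.Series("", index=raw.index, dtype=object)
    reason[ts.isna()] = "bad_timestamp"
    unknown = ~vital.isin(ALL_VITALS)
    reason[(reason == "") & unknown] = "unknown_vital"
    bad_avpu = is_avpu & ~value_str.isin(AVPU_LEVELS)
    reason[(reason == "") & bad_avpu] = "bad_avpu_level"
    missing_val = ~is_avpu & (raw["value"].isna() | (value_str == "") | numeric.isna())
    reason[(reason == "") & missing_val] = "missing_value"

    in_range = np.ones(len(raw), dtype=bool)
    num = numeric.to_numpy(dtype=float)
    for v, (lo, hi) in ranges.ranges.items():
        m = ((vital == v) & ~is_avpu).to_numpy()
        in_range[m] = (num[m] >= lo) & (num[m] <= hi)
    reason[(reason == "").to_numpy() & ~in_range] = "out_of_range"

    rejected = raw[reason != ""].copy()
    rejected["reason"] = reason[reason != ""]

    keep = reason == ""
    obs = pd.DataFrame(
        {
            "encounter_id": raw.loc[keep, "encounter_id"],
            "patient_id": raw.loc[keep, "patient_id"],
            "timestamp": ts[keep],
            "vital": vital[keep],
            "value": numeric[keep],
            "level": value_str[keep].where(is_avpu[keep], other=pd.NA),
        }
    )
    obs = obs.sort_values(["encounter_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    return obs, rejected.reset_index(drop=True)


def write_observations(path, obs: pd.DataFrame) -> None:
    out = obs.copy()
    out["value"] = out["value"].map(
        lambda x: "" if pd.isna(x) else (FLOAT_FMT % x), na_action=None
    )
    out.loc[out["vital"] == "AVPU", "value"] = out.loc[out["vital"] == "AVPU", "level"]
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
    out[OBS_COLUMNS].to_csv(path, index=False)


def read_encounters(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the encounter/demographics table.

    One row per encounter; a duplicated ``encounter_id`` is a fatal error.
    Rows with discharge at or before admission, or age outside the plausible
    [1, 106] band, are rejected with a reason.
    """
    raw = pd.read_csv(path, dtype={"encounter_id": str, "patient_id": str})
    _require_columns(raw, ENC_COLUMNS, path)
    raw = raw[ENC_COLUMNS].copy()

    dup = raw["encounter_id"][raw["encounter_id"].duplicated()]
    if len(dup):
        raise ParseError(f"duplicate encounter_id: {dup.iloc[0]}")

    adm = _to_minutes(raw["admission_time"].astype(str))
    dis = _to_minutes(raw["discharge_time"].astype(str))
    age = pd.to_numeric(raw["age"], errors="coerce")

    reason = pd.Series("", index=raw.index, dtype=object)
    reason[adm.isna() | dis.isna()] = "bad_timestamp"
    reason[(reason == "") & (dis <= adm)] = "discharge_before_admission"
    reason[(reason == "") & (age.isna() | (age < 1) | (age > 106))] = "age_out_of_range"
    reason[(reason == "") & ~raw["sex"].isin(["male", "female"])] = "bad_sex"

    rejected = raw[reason != ""].copy()
    rejected["reason"] = reason[reason != ""]

    keep = reason == ""
    enc = raw[keep].copy()
    enc["admission_time"] = adm[keep]
    enc["discharge_time"] = dis[keep]
    enc["age"] = age[keep]
    enc = enc.sort_values("encounter_id", kind="mergesort").reset_index(drop=True)
    return enc, rejected.reset_index(drop=True)


def write_encounters(path, enc: pd.DataFrame) -> None:
    out = enc.copy()
    for c in ("admission_time", "discharge_time"):
        out[c] = out[c].dt.strftime("%Y-%m-%dT%H:%M")
    out["age"] = out["age"].map(lambda x: FLOAT_FMT % x)
    out[ENC_COLUMNS].to_csv(path, index=False)


def write_table(path, table: pd.DataFrame) -> None:
    """Write a feature/prediction table; floats at 12 significant digits,
    missing as empty fields, timestamps ISO-8601 to the minute."""
    out = table.copy()
    for c in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[c]):
            out[c] = out[c].dt.strftime("%Y-%m-%dT%H:%M")
    out.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_table(path, time_columns: tuple[str, ...] = ("time",)) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"encounter_id": str})
    for c in time_columns:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c], format="ISO8601")
    return df
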