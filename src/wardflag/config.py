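"""Shared domain constants and run configuration.

The package predicts red-flag alerts of a ward track-and-trigger observation
chart ("between the flags"-style) from seven numeric vital signs plus the AVPU
consciousness scale and supplemental-oxygen flow.  Everything that a run can
vary — windows, ensemble size, risk thresholds, red-zone predicates, validity
screening bounds — lives here as plain dataclasses with YAML round-tripping.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, replace

import yaml

# The seven vitals that receive full window aggregates.
AGG_VITALS: tuple[str, ...] = ("SBP", "DBP", "MAP", "HR", "TEMP", "RR", "SPO2")
# Vitals carrying numeric values (O2 flow gets only a presence flag).
NUMERIC_VITALS: tuple[str, ...] = AGG_VITALS + ("O2FLOW",)
ALL_VITALS: tuple[str, ...] = NUMERIC_VITALS + ("AVPU",)

AVPU_LEVELS: tuple[str, ...] = ("Alert", "Verbal", "Pain", "Unresponsive")

#: Plausibility screening bounds (closed intervals).  A value on the bound is
#: retained.  AVPU is categorical and never range-screened.
DEFAULT_VALIDITY_RANGES: dict[str, tuple[float, float]] = {
    "SBP": (0.0, 300.0),
    "DBP": (0.0, 250.0),
    "MAP": (20.0, 261.0),
    "HR": (0.0, 200.0),
    "TEMP": (30.0, 42.2),
    "RR": (0.0, 60.0),
    "SPO2": (50.0, 100.0),
    "O2FLOW": (0.0, 60.0),
}


@dataclass(frozen=True)
class ValidityRanges:
    """Per-vital closed plausibility intervals ``[lo, hi]``."""

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VALIDITY_RANGES)
    )

    def __post_init__(self) -> None:
        for vital, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"validity range for {vital} must have lo < hi, got [{lo}, {hi}]")

    def contains(self, vital: str, value: float) -> bool:
        lo, hi = self.ranges[vital]
        return lo <= value <= hi

    def clip(self, vital: str, value):
        lo, hi = self.ranges[vital]
        import numpy as np

        return np.clip(value, lo, hi)


@dataclass(frozen=True)
class ThresholdProtocol:
    """Red-zone predicates of the track-and-trigger chart.

    A numeric vital triggers a red flag when ``value < red_lo`` or
    ``value > red_hi`` (either bound may be ``None``).  AVPU triggers on the
    configured red levels.  The shipped defaults are illustrative chart values
    and are fully overridable — institutions publish their own charts.
    """

    red_zones: dict[str, tuple[float | None, float | None]] = field(
        default_factory=lambda: {
            "RR": (5.0, 30.0),
            "SPO2": (90.0, None),
            "SBP": (90.0, 200.0),
            "HR": (40.0, 140.0),
            "TEMP": (35.5, 38.5),
            "MAP": (60.0, None),
        }
    )
    avpu_red: frozenset[str] = frozenset({"Pain", "Unresponsive"})

    def __post_init__(self) -> None:
        for vital, (lo, hi) in self.red_zones.items():
            if lo is not None and hi is not None and not lo < hi:
                raise ValueError(f"red zone for {vital}: red_lo must be < red_hi")

    def is_red(self, vital: str, value: float) -> bool:
        if vital == "AVPU":
            return value in self.avpu_red
        if vital not in self.red_zones:
            return False
        lo, hi = self.red_zones[vital]
        return (lo is not None and value < lo) or (hi is not None and value > hi)

    @classmethod
    def from_yaml(cls, path) -> "ThresholdProtocol":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        zones = {
            v: (pair[0], pair[1]) for v, pair in (d.get("red_zones") or {}).items()
        }
        return cls(
            red_zones=zones or cls().red_zones,
            avpu_red=frozenset(d.get("avpu_red", ("Pain", "Unresponsive"))),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "red_zones": {v: list(pair) for v, pair in self.red_zones.items()},
                    "avpu_red": sorted(self.avpu_red),
                },
                fh,
                sort_keys=True,
            )


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run configuration.

    Parameters
    ----------
    historical_window_h
        Lookback H over which per-vital aggregates are computed (hours).
    prediction_windows_h
        Lookahead horizons W; a prediction point is positive for horizon W
        when a red flag occurs in ``(t, t+W]``.
    n_bootstrap
        Ensemble size B: number of encounter-level bootstrap sub-samples,
        one decision tree fitted per sub-sample.
    n_bootstrap_tune
        Smaller ensemble size used while scanning the hyperparameter grid.
    risk_thresholds
        Strictly decreasing probabilities mapping predictions to
        deterioration risk indices 1/2/3 (strict ``p > threshold``).
    n_calibration_bins
        Number of probability quantile bins in the calibration curve.
    balance
        Sub-sample class balancing mode: ``"pool"`` (inverse-probability
        re-sampling of the one-per-encounter pool, the default), ``"off"``.
    censor_after_first_flag
        If true, prediction points at or after an encounter's first red flag
        are dropped; by default later points are retained.
    """

    historical_window_h: float = 24.0
    prediction_windows_h: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0)
    n_bootstrap: int = 1000
    n_bootstrap_tune: int = 50
    risk_thresholds: tuple[float, float, float] = (0.95, 0.85, 0.70)
    n_calibration_bins: int = 10
    min_los_h: float = 24.0
    balance: str = "pool"
    censor_after_first_flag: bool = False
    leaf_smoothing: float = 0.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        t1, t2, t3 = self.risk_thresholds
        if not (t1 > t2 > t3):
            raise ValueError("risk_thresholds must be strictly decreasing")
        if any(w <= 0 for w in self.prediction_windows_h) or self.historical_window_h <= 0:
            raise ValueError("all windows must be positive")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.balance not in {"off", "pool"}:
            raise ValueError(f"unknown balance mode {self.balance!r}")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["prediction_windows_h"] = list(self.prediction_windows_h)
        d["risk_thresholds"] = list(self.risk_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "prediction_windows_h" in d:
            d["prediction_windows_h"] = tuple(d["prediction_windows_h"])
        if "risk_thresholds" in d:
            d["risk_thresholds"] = tuple(d["risk_thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw)
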