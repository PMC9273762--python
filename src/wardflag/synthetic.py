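"""Synthetic ward-EHR generator with known deterioration mechanisms.

Real ward extracts behind track-and-trigger protocols are not
redistributable, so the package ships a generator that emulates the
statistical structure the method assumes:

* irregularly sampled observations of the seven numeric vitals plus AVPU and
  supplemental O2 flow, with cohort-level means matching published ward
  summaries (e.g. SBP 126.69 mmHg, SpO2 96.52%);
* acute-care encounters with a heavy-tailed length-of-stay distribution and
  a small admixture of non-acute admissions to exercise cohort filtering;
* denser observation schedules for at-risk encounters (sicker patients are
  measured more often);
* ground-truth deterioration episodes: a per-hour onset hazard followed by
  piecewise-linear drift of the phenotype's driver vitals into the red zone
  and back (treatment-response style recovery), so that the red-flag event
  prevalence per prediction window is tunable into the observed 5–8% band.

Vital trajectories are mean-reverting (Ornstein–Uhlenbeck) noise around a
per-encounter baseline plus the episode drift, clipped to the validity
ranges.  Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import AGG_VITALS, RunConfig, ThresholdProtocol, ValidityRanges

MINUTE = pd.Timedelta(minutes=1)


@dataclass(frozen=True)
class PhenotypeSpec:
    """A deterioration mechanism: which vitals drift, how fast, how often.

    ``drift`` maps driver vitals to linear rates (units/hour) applied over a
    deterioration episode; ``episode_hazard`` is the per-hour probability
    that an at-risk encounter begins deteriorating.
    """

    name: str
    drift: dict[str, float] = field(default_factory=dict)
    episode_hazard: float = 0.0
    driver_vitals: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.episode_hazard <= 1.0:
            raise ValueError("episode_hazard must be in [0, 1]")
        extra = set(self.drift) - set(self.driver_vitals)
        if extra:
            raise ValueError(f"drift given for non-driver vitals: {sorted(extra)}")


def default_phenotypes() -> list[PhenotypeSpec]:
    """Stable physiology plus two clinically motivated failure modes."""
    return [
        PhenotypeSpec(name="stable"),
        PhenotypeSpec(
            name="respiratory_failure",
            driver_vitals=("SPO2", "RR"),
            drift={"SPO2": -0.8, "RR": 1.5},
            episode_hazard=0.02,
        ),
        PhenotypeSpec(
            name="sepsis_like",
            driver_vitals=("SBP", "TEMP", "HR"),
            drift={"SBP": -2.5, "TEMP": -0.06, "HR": -1.2},
            episode_hazard=0.02,
        ),
    ]


def phenotypes_from_yaml(path) -> list[PhenotypeSpec]:
    """Load a phenotype library from YAML (a list of PhenotypeSpec fields)."""
    import yaml

    with open(path) as fh:
        entries = yaml.safe_load(fh) or []
    return [
        PhenotypeSpec(
            name=e["name"],
            drift=dict(e.get("drift", {})),
            episode_hazard=float(e.get("episode_hazard", 0.0)),
            driver_vitals=tuple(e.get("driver_vitals", ())),
        )
        for e in entries
    ]


def phenotypes_to_yaml(path, phenotypes: list[PhenotypeSpec]) -> None:
    import yaml

    entries = [
        {
            "name": p.name,
            "drift": dict(p.drift),
            "episode_hazard": p.episode_hazard,
            "driver_vitals": list(p.driver_vitals),
        }
        for p in phenotypes
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


#: Cohort-level baseline means/SDs for the numeric vitals (ward summary
#: values); O2 flow is an invented low-flow baseline.
DEFAULT_VITAL_MEANS = {
    "SBP": 126.69,
    "DBP": 73.14,
    "MAP": 91.08,
    "HR": 79.31,
    "TEMP": 36.70,
    "RR": 17.37,
    "SPO2": 96.52,
    "O2FLOW": 1.5,
}
DEFAULT_VITAL_SDS = {
    "SBP": 21.16,
    "DBP": 11.12,
    "MAP": 12.98,
    "HR": 15.92,
    "TEMP": 0.40,
    "RR": 2.70,
    "SPO2": 2.33,
    "O2FLOW": 1.2,
}


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for the synthetic ward.

    The stable-phenotype dispersion is ``stable_sd_fraction`` of the cohort
    SD: cohort summaries mix stable and deteriorating physiology, and a pure
    Gaussian with the full cohort SD would breach red-zone thresholds several
    percent of the time from noise alone, which would swamp the episode
    mechanism the labels are meant to reflect.
    """

    n_encounters: int = 500
    fraction_at_risk: float = 0.5
    vital_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VITAL_MEANS))
    vital_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VITAL_SDS))
    stable_sd_fraction: float = 0.55
    within_var_fraction: float = 0.4  # share of stable variance inside an encounter
    ou_tau_h: float = 12.0  # mean-reversion time constant
    interval_mean_h: float = 8.0  # per-vital mean inter-observation gap
    sicker_interval_multiplier: float = 0.5
    los_mean_min: float = 13468.9
    los_sd_min: float = 27828.5
    los_min_min: float = 240.0
    los_max_min: float = 21.0 * 1440.0
    age_mean: float = 59.89
    age_sd: float = 17.23
    male_fraction: float = 0.62
    o2flow_coverage: float = 0.36
    avpu_coverage: float = 0.6
    non_acute_fraction: float = 0.05
    episode_duration_h: float = 24.0
    hazard_scale: float = 1.0
    calendar_start: str = "2021-01-01"
    calendar_days: int = 360
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_at_risk <= 1.0:
            raise ValueError("fraction_at_risk must be in [0, 1]")
        if any(sd <= 0 for sd in self.vital_sds.values()):
            raise ValueError("all vital SDs must be > 0")

    def with_(self, **kw) -> "GeneratorParams":
        return replace(self, **kw)


NON_ACUTE_TYPES = ("Mental health care", "Rehabilitation care", "Maintenance Care")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _ou_series(rng, times_h: np.ndarray, sd: float, tau_h: float) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck noise sampled at irregular times."""
    x = np.empty(len(times_h))
    if len(x) == 0:
        return x
    x[0] = rng.normal(0.0, sd)
    for k in range(1, len(x)):
        a = np.exp(-(times_h[k] - times_h[k - 1]) / tau_h)
        x[k] = a * x[k - 1] + rng.normal(0.0, sd * np.sqrt(max(1.0 - a * a, 0.0)))
    return x


def _episode_depth(t_h: np.ndarray, onset_h: float, duration_h: float) -> np.ndarray:
    """Hours of accumulated drift: ramps up over the episode, then recovers."""
    rel = t_h - onset_h
    depth = np.where(rel <= duration_h, rel, 2.0 * duration_h - rel)
    return np.clip(depth, 0.0, None)


def _obs_times(rng, los_h: float, mean_gap_h: float) -> np.ndarray:
    gaps = []
    t = rng.exponential(mean_gap_h)
    total = t
    while total < los_h:
        gaps.append(total)
        total += rng.exponential(mean_gap_h)
    return np.asarray(gaps)


def generate(
    params: GeneratorParams,
    phenotypes: list[PhenotypeSpec] | None = None,
    ranges: ValidityRanges | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate ``(encounters, observations, ground_truth)``.

    Ground truth records each encounter's phenotype, episode onset time (NaT
    when no episode fired) and the episode duration, so explainability and
    discrimination can be verified against a known mechanism.
    """
    phenotypes = phenotypes if phenotypes is not None else default_phenotypes()
    ranges = ranges or ValidityRanges()
    stable = [p for p in phenotypes if p.name == "stable"]
    if not stable:
        raise ValueError("at least one 'stable' phenotype is required")
    at_risk = [p for p in phenotypes if p.name != "stable"]
    if params.fraction_at_risk > 0 and not at_risk:
        raise ValueError("fraction_at_risk > 0 but no non-stable phenotype supplied")

    rng = np.random.default_rng(params.random_seed)
    start = pd.Timestamp(params.calendar_start)
    mu_los, sig_los = _lognormal_params(params.los_mean_min, params.los_sd_min)

    enc_rows, obs_rows, truth_rows = [], [], []
    for i in range(params.n_encounters):
        eid = f"E{i:05d}"
        pid = f"P{i:05d}"
        admission = start + pd.Timedelta(minutes=float(rng.uniform(0, params.calendar_days * 1440))).floor("min")
        los_min = float(np.clip(rng.lognormal(mu_los, sig_los), params.los_min_min, params.los_max_min))
        los_h = los_min / 60.0
        discharge = admission + pd.Timedelta(minutes=round(los_min))
        age = float(np.clip(rng.normal(params.age_mean, params.age_sd), 1.0, 106.0))
        sex = "male" if rng.uniform() < params.male_fraction else "female"
        care = (
            str(rng.choice(NON_ACUTE_TYPES))
            if rng.uniform() < params.non_acute_fraction
            else "Acute Care"
        )

        if at_risk and rng.uniform() < params.fraction_at_risk:
            phen = at_risk[int(rng.integers(len(at_risk)))]
        else:
            phen = stable[0]

        onset_h = np.nan
        duration_h = params.episode_duration_h
        if phen.episode_hazard > 0:
            hazard = min(phen.episode_hazard * params.hazard_scale, 1.0)
            cand = float(rng.exponential(1.0 / max(hazard, 1e-12)))
            # an episode needs some room before discharge to be observable
            if cand + 2.0 < los_h:
                onset_h = cand
        sicker = phen.name != "stable"
        gap_mult = params.sicker_interval_multiplier if sicker else 1.0

        has_o2 = rng.uniform() < params.o2flow_coverage
        has_avpu = rng.uniform() < params.avpu_coverage

        for vital in AGG_VITALS + ("O2FLOW", "AVPU"):
            if vital == "O2FLOW" and not has_o2:
                continue
            if vital == "AVPU" and not has_avpu:
                continue
            t_h = _obs_times(rng, los_h, params.interval_mean_h * gap_mult)
            if len(t_h) == 0:
                continue
            depth = (
                _episode_depth(t_h, onset_h, duration_h)
                if np.isfinite(onset_h)
                else np.zeros(len(t_h))
            )
            if vital == "AVPU":
                frac = depth / duration_h
                levels = np.full(len(t_h), "Alert", dtype=object)
                levels[frac > 0.35] = "Verbal"
                levels[frac > 0.7] = "Pain"
                levels[frac > 0.95] = "Unresponsive"
                for t, lev in zip(t_h, levels):
                    obs_rows.append(
                        (eid, pid, admission + pd.Timedelta(minutes=round(t * 60)), "AVPU", np.nan, lev)
                    )
                continue

            sd_stable = params.stable_sd_fraction * params.vital_sds[vital]
            sd_base = sd_stable * np.sqrt(1.0 - params.within_var_fraction)
            sd_within = sd_stable * np.sqrt(params.within_var_fraction)
            baseline = params.vital_means[vital] + rng.normal(0.0, sd_base)
            noise = _ou_series(rng, t_h, sd_within, params.ou_tau_h)
            drift_rate = phen.drift.get(vital, 0.0)
            vals = baseline + noise + drift_rate * depth
            if vital == "O2FLOW" and np.isfinite(onset_h):
                vals = vals + 0.25 * depth  # supplemental oxygen titrated up
            vals = ranges.clip(vital, vals)
            for t, v in zip(t_h, vals):
                obs_rows.append(
                    (eid, pid, admission + pd.Timedelta(minutes=round(t * 60)), vital, float(v), pd.NA)
                )

        enc_rows.append((eid, pid, admission, discharge, age, sex, care))
        truth_rows.append(
            (
                eid,
                phen.name,
                admission + pd.Timedelta(minutes=round(onset_h * 60)) if np.isfinite(onset_h) else pd.NaT,
                duration_h if np.isfinite(onset_h) else np.nan,
            )
        )

    encounters = pd.DataFrame(
        enc_rows,
        columns=[
            "encounter_id",
            "patient_id",
            "admission_time",
            "discharge_time",
            "age",
            "sex",
            "care_type",
        ],
    )
    observations = pd.DataFrame(
        obs_rows,
        columns=["encounter_id", "patient_id", "timestamp", "vital", "value", "level"],
    )
    observations = observations.sort_values(
        ["encounter_id", "timestamp"], kind="mergesort"
    ).reset_index(drop=True)
    truth = pd.DataFrame(
        truth_rows, columns=["encounter_id", "phenotype", "onset_time", "episode_duration_h"]
    )
    return encounters, observations, truth


def window_prevalence(
    encounters: pd.DataFrame,
    observations: pd.DataFrame,
    window_h: float,
    protocol: ThresholdProtocol | None = None,
    config: RunConfig | None = None,
) -> float:
    """Fraction of retained prediction points labelled positive at horizon W."""
    from . import cohort

    protocol = protocol or ThresholdProtocol()
    config = config or RunConfig()
    kept, _ = cohort.filter_cohort(encounters, observations, config.min_los_h, protocol)
    obs = observations[observations["encounter_id"].isin(kept)]
    flags = cohort.detect_red_flags(obs, protocol)
    points = cohort.prediction_points(obs, flags, config.censor_after_first_flag)
    if len(points) == 0:
        return float("nan")
    labels = cohort.label_windows(points, flags, window_h)
    return float(np.mean(labels))


def tune_prevalence(
    params: GeneratorParams,
    phenotypes: list[PhenotypeSpec] | None = None,
    target_prevalence: float = 0.08,
    window_h: float = 8.0,
    protocol: ThresholdProtocol | None = None,
    config: RunConfig | None = None,
    tol: float = 0.01,
    max_iter: int = 14,
    n_encounters_search: int | None = None,
) -> GeneratorParams:
    """Bisect the episode-hazard scale so labelled prevalence hits the target.

    Prevalence is monotone non-decreasing in the hazard, so plain bisection on
    ``hazard_scale`` converges; the search generates smaller cohorts
    (``n_encounters_search``) for speed and returns ``params`` with the tuned
    scale.  Raises if the closest achievable prevalence misses the target by
    more than ``2 * tol``.
    """
    if not 0.0 < target_prevalence < 0.5:
        raise ValueError("target_prevalence must be in (0, 0.5)")
    phenotypes = phenotypes if phenotypes is not None else default_phenotypes()
    n_search = n_encounters_search or min(params.n_encounters, 250)
    search_params = params.with_(n_encounters=n_search)

    def prev_at(scale: float) -> float:
        enc, obs, _ = generate(search_params.with_(hazard_scale=scale), phenotypes)
        p = window_prevalence(enc, obs, window_h, protocol, config)
        return 0.0 if np.isnan(p) else p

    lo, hi = 1e-3, 8.0
    p_hi = prev_at(hi)
    tries = 0
    while p_hi < target_prevalence and hi < 512 and tries < 6:
        hi *= 2.0
        p_hi = prev_at(hi)
        tries += 1
    best_scale, best_p = hi, p_hi
    p_lo = prev_at(lo)
    if abs(p_lo - target_prevalence) < abs(best_p - target_prevalence):
        best_scale, best_p = lo, p_lo
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # geometric: hazard acts multiplicatively
        p_mid = prev_at(mid)
        if abs(p_mid - target_prevalence) < abs(best_p - target_prevalence):
            best_scale, best_p = mid, p_mid
        if abs(p_mid - target_prevalence) <= tol:
            break
        if p_mid < target_prevalence:
            lo = mid
        else:
            hi = mid
    if abs(best_p - target_prevalence) > 2 * tol:
        raise RuntimeError(
            f"target prevalence {target_prevalence:.3f} unattainable; "
            f"closest achieved {best_p:.3f} at hazard_scale {best_scale:.3g}"
        )
    return params.with_(hazard_scale=float(best_scale))
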