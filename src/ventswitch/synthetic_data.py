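"""Multi-center synthetic ICU event-log generator with known switch ground truth.

The generator emulates the *structure* of merged multi-center ICU databases
so that every downstream stage — mode harmonization, switch detection,
outcome labeling, feature extraction, group comparison, prediction — can be
tested against a known ground truth without access to restricted data:

* three "centers", each with its own raw ventilator-mode label dialect and
  its own per-variable logging frequencies;
* per-variable missingness (records thinned at random);
* a latent switch-readiness process: each patient is switched from
  controlled to assisted mode at readiness plus noise, occasionally
  prematurely; patients whose readiness exceeds their controlled course
  never attempt (the "no switch" group);
* a logistic switch-failure mechanism on the patient's true (noise-free)
  pre-switch PaO2/FiO2, PEEP, base excess, lactate and driving pressure,
  so a Bayes-optimal AUC is computable from the true probabilities;
* lognormal time-to-failure with configurable median (default 8 h,
  truncated to at most 72 h), realized as a return to controlled mode or,
  with small probability, death in assisted mode;
* 28-day mortality with a failure-associated log-odds shift, reproducing
  the outcome association without hard-coding causality.

Times are hours since ICU admission; intervals are half-open.  Identical
``(config, seed)`` produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .mode_timeline import ASSISTED, COMBINED, CONTROLLED, CPAP, NONINVASIVE_OR_NONE, ModeDialect


class ConfigurationError(ValueError):
    """Raised for invalid cohort configurations."""


# ---------------------------------------------------------------------------
# default center dialects: three label inventories in the style of different
# ventilator fleets / charting systems, each exercising every mapping branch

DEFAULT_DIALECTS = {
    0: ModeDialect(
        "center_a",
        {
            "PC-CMV": CONTROLLED,
            "VC-CMV": CONTROLLED,
            "PRVC": CONTROLLED,
            "APRV": CONTROLLED,
            "SIMV-PC": COMBINED,
            "SIMV-VC": COMBINED,
            "BiLevel": COMBINED,
            "PSV": ASSISTED,
            "PAV+": ASSISTED,
            "NAVA": ASSISTED,
            "CPAP": CPAP,
            "CPAP/PS": CPAP,
            "NIV": NONINVASIVE_OR_NONE,
            "Standby": NONINVASIVE_OR_NONE,
        },
    ),
    1: ModeDialect(
        "center_b",
        {
            "CMV": CONTROLLED,
            "PCV+": CONTROLLED,
            "APRV": CONTROLLED,
            "CMV/ASSIST": COMBINED,
            "Assist Control": COMBINED,
            "SIMV": COMBINED,
            "SIMV/PSV": COMBINED,
            "PSV/SBT": ASSISTED,
            "PSV": ASSISTED,
            "MMV": ASSISTED,
            "CPAP": CPAP,
            "CPAP/PSV": CPAP,
            "NIV/Mask": NONINVASIVE_OR_NONE,
            "Standby": NONINVASIVE_OR_NONE,
        },
    ),
    2: ModeDialect(
        "center_c",
        {
            "Beademen": CONTROLLED,
            "PC (No trig)": CONTROLLED,
            "VC (No trig)": CONTROLLED,
            "Bi Vent": COMBINED,
            "SIMV(PC)+PS": COMBINED,
            "SIMV(VC)+PS": COMBINED,
            "PS/CPAP (trig)": ASSISTED,
            "Drukondersteuning": ASSISTED,
            "NAVA": ASSISTED,
            "CPAP": CPAP,
            "CPAP/PS": CPAP,
            "NIV CPAP": NONINVASIVE_OR_NONE,
            "Geen": NONINVASIVE_OR_NONE,
        },
    ),
}

#: measured variables and per-center logging intervals (hours).  Center 2 is
#: the densely-logged one; centers 0 and 1 log ventilator data more sparsely.
DEFAULT_LOGGING_INTERVALS = {
    0: {
        "pao2": 4.0, "paco2": 4.0, "ph": 4.0, "base_excess": 4.0, "lactate": 6.0,
        "fio2": 2.0, "spo2": 1.0, "peep": 2.0, "pplat": 6.0, "ppeak": 2.0,
        "tidal_volume": 2.0, "minute_volume": 2.0, "resp_rate_total": 1.0,
        "spont_rr": 1.0, "heart_rate": 1.0, "mean_arterial_pressure": 1.0,
        "temperature": 4.0, "wbc": 24.0,
    },
    1: {
        "pao2": 6.0, "paco2": 6.0, "ph": 6.0, "base_excess": 6.0, "lactate": 8.0,
        "fio2": 4.0, "spo2": 1.0, "peep": 4.0, "pplat": 8.0, "ppeak": 4.0,
        "tidal_volume": 4.0, "minute_volume": 4.0, "resp_rate_total": 1.0,
        "spont_rr": 2.0, "heart_rate": 1.0, "mean_arterial_pressure": 1.0,
        "temperature": 4.0, "wbc": 24.0,
    },
    2: {
        "pao2": 3.0, "paco2": 3.0, "ph": 3.0, "base_excess": 3.0, "lactate": 4.0,
        "fio2": 1.0, "spo2": 1.0, "peep": 1.0, "pplat": 4.0, "ppeak": 1.0,
        "tidal_volume": 1.0, "minute_volume": 1.0, "resp_rate_total": 1.0,
        "spont_rr": 1.0, "heart_rate": 1.0, "mean_arterial_pressure": 1.0,
        "temperature": 2.0, "wbc": 24.0,
    },
}

#: how often each center re-logs the current ventilator mode between changes
DEFAULT_MODE_LOG_INTERVALS = {0: 4.0, 1: 4.0, 2: 1.0}

DEFAULT_MISSINGNESS = {
    "pao2": 0.05, "paco2": 0.05, "ph": 0.10, "base_excess": 0.08, "lactate": 0.25,
    "fio2": 0.0, "spo2": 0.0, "peep": 0.01, "pplat": 0.35, "ppeak": 0.05,
    "tidal_volume": 0.05, "minute_volume": 0.10, "resp_rate_total": 0.0,
    "spont_rr": 0.02, "heart_rate": 0.05, "mean_arterial_pressure": 0.10,
    "temperature": 0.15, "wbc": 0.15,
}

#: measurement noise SD per variable (added on top of the patient's latent
#: value; small relative to between-patient spread, as for calibrated
#: clinical instruments)
DEFAULT_NOISE_SD = {
    "pao2": 6.0, "paco2": 1.5, "ph": 0.01, "base_excess": 0.5, "lactate": 0.15,
    "fio2": 0.0, "spo2": 1.0, "peep": 0.0, "pplat": 1.0, "ppeak": 1.0,
    "tidal_volume": 15.0, "minute_volume": 0.5, "resp_rate_total": 1.5,
    "spont_rr": 0.0, "heart_rate": 5.0, "mean_arterial_pressure": 5.0,
    "temperature": 0.2, "wbc": 1.0,
}

#: deterministic shift applied to ventilatory variables while the patient is
#: in assisted mode (pressure support lowers peak pressures, raises tidal
#: volume and rate slightly)
ASSISTED_SHIFT = {
    "ppeak": -3.0, "peep": -0.5, "tidal_volume": 25.0, "resp_rate_total": 2.0,
    "minute_volume": 0.3,
}

#: standardization constants of the latent pre-switch features entering the
#: logistic failure mechanism: variable -> (center, scale)
FEATURE_SCALES = {
    "pf": (220.0, 70.0),
    "peep": (8.0, 2.5),
    "base_excess": (0.0, 3.0),
    "lactate": (1.7, 0.8),
    "dp": (12.0, 2.5),
}

DEFAULT_FAILURE_COEFFICIENTS = {
    "intercept": 0.78,
    "pf": -0.50,
    "peep": 0.35,
    "base_excess": -0.30,
    "lactate": 0.45,
    "dp": 0.30,
}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Distribution parameters are ``(median, sigma)`` pairs of lognormal laws
    (median in the stated unit, sigma on the log scale).
    """

    n_patients: int = 1000
    n_centers: int = 3
    seed: int = 0
    mode_dialects: dict = field(default_factory=lambda: dict(DEFAULT_DIALECTS))
    logging_interval_hours: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LOGGING_INTERVALS.items()})
    mode_log_interval_hours: dict = field(default_factory=lambda: dict(DEFAULT_MODE_LOG_INTERVALS))
    missingness_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    readiness_dist: tuple = (1.5, 0.7)  # days, lognormal (median, sigma)
    readiness_noise_sd: float = 0.15  # multiplicative log-noise on the attempt time
    premature_attempt_prob: float = 0.10
    controlled_course_dist: tuple = (120.0, 0.5)  # hours; no attempt if readiness exceeds it
    failure_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_FAILURE_COEFFICIENTS))
    ttf_dist: tuple = (8.0, 1.15)  # hours, lognormal (median, sigma), truncated to (1, 72)
    death_failure_prob: float = 0.10  # failure realized as death in assisted mode
    mortality_model: dict = field(
        default_factory=lambda: {"baseline_prob": 0.145, "failure_log_odds": 0.75, "no_switch_log_odds": 2.0}
    )
    combined_fraction: float = 0.18  # mode records rewritten to combined labels
    success_assisted_dist: tuple = (48.0, 0.6)  # hours on assisted before extubation
    n_secondary_mean: float = 2.2  # Poisson mean of secondary attempts after a failure
    secondary_gap_dist: tuple = (8.0, 0.8)  # hours back in controlled mode
    secondary_duration_dist: tuple = (10.0, 0.9)  # hours per secondary assisted episode
    post_mv_icu_dist: tuple = (48.0, 0.6)  # hours in ICU after extubation
    min_segment_hours: float = 1.05  # keeps every generated episode past the 1 h persistence rule

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.n_centers < 1:
            raise ConfigurationError("n_centers must be >= 1")
        for name in ("premature_attempt_prob", "death_failure_prob", "combined_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for var, r in self.missingness_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"missingness rate for {var} must be in [0, 1], got {r}")
        for center, table in self.logging_interval_hours.items():
            for var, dt in table.items():
                if dt <= 0:
                    raise ConfigurationError(f"logging interval for {var} (center {center}) must be > 0")
        if self.ttf_dist[0] <= 0 or self.ttf_dist[1] <= 0:
            raise ConfigurationError("ttf_dist must have positive median and sigma")

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def dense(cls, n_patients: int, seed: int = 0, **kw) -> "CohortConfig":
        """Idealized logging: everything every 30 min, no missingness."""
        intervals = {c: {v: 0.5 for v in DEFAULT_LOGGING_INTERVALS[0]} for c in range(3)}
        missing = {v: 0.0 for v in DEFAULT_MISSINGNESS}
        return cls(
            n_patients=n_patients,
            seed=seed,
            logging_interval_hours=intervals,
            mode_log_interval_hours={0: 1.0, 1: 1.0, 2: 1.0},
            missingness_rates=missing,
            **kw,
        )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["mode_dialects"] = {
            c: {"name": dia.name, "mapping": dia.mapping} for c, dia in self.mode_dialects.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "mode_dialects" in d:
            d["mode_dialects"] = {
                int(c): ModeDialect(v["name"], dict(v["mapping"])) for c, v in d["mode_dialects"].items()
            }
        for key in (
            "readiness_dist", "controlled_course_dist", "ttf_dist", "success_assisted_dist",
            "secondary_gap_dist", "secondary_duration_dist", "post_mv_icu_dist",
        ):
            if key in d:
                d[key] = tuple(d[key])
        d["logging_interval_hours"] = {int(c): v for c, v in d.get("logging_interval_hours", {}).items()} or None
        d["mode_log_interval_hours"] = {int(c): v for c, v in d.get("mode_log_interval_hours", {}).items()} or None
        d = {k: v for k, v in d.items() if v is not None}
        return cls(**d)


STAY_COLUMNS = ["stay_id", "center", "admission_time", "discharge_time", "death_time", "age", "sex", "apache2", "first_stay"]
MODE_COLUMNS = ["stay_id", "center", "time", "raw_label"]
AIRWAY_COLUMNS = ["stay_id", "time", "event"]
MEAS_COLUMNS = ["stay_id", "center", "time", "variable", "value"]
TRUTH_COLUMNS = [
    "stay_id", "center", "true_first_attempt_time", "true_outcome", "true_failure_cause",
    "true_failure_time", "true_failure_probability",
    "true_pf", "true_peep", "true_base_excess", "true_lactate", "true_dp",
]


def _lognormal(rng: np.random.Generator, median: float, sigma: float, size=None):
    return np.exp(rng.normal(np.log(median), sigma, size=size))


def _truncated_lognormal(rng: np.random.Generator, median: float, sigma: float, lo: float, hi: float, size: int):
    """Lognormal conditioned on (lo, hi) via inverse-CDF sampling."""
    from scipy import stats as sps

    dist = sps.lognorm(s=sigma, scale=median)
    a, b = dist.cdf(lo), dist.cdf(hi)
    u = rng.uniform(a, b, size=size)
    return dist.ppf(u)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: CohortConfig):
    """Generate one cohort; returns (stays, mode_events, airway_events, measurements, ground_truth).

    All tables are sorted by (stay_id, time) and deterministic given the
    config (which includes the seed).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        return (
            pd.DataFrame(columns=STAY_COLUMNS),
            pd.DataFrame(columns=MODE_COLUMNS),
            pd.DataFrame(columns=AIRWAY_COLUMNS),
            pd.DataFrame(columns=MEAS_COLUMNS),
            pd.DataFrame(columns=TRUTH_COLUMNS),
        )

    center = rng.integers(0, config.n_centers, size=n)

    # latent patient-level physiology (noise-free); the failure mechanism
    # operates on these values, measurement noise is added afterwards
    lat = {
        "pf": np.clip(_lognormal(rng, 220.0, 0.30, n), 60.0, 500.0),
        "fio2": np.round(np.clip(rng.normal(45.0, 8.0, n), 25.0, 100.0)),
        "peep": np.round(np.clip(rng.normal(8.0, 2.5, n), 0.0, 18.0)),
        "dp": np.clip(rng.normal(12.0, 2.5, n), 4.0, 25.0),
        "tidal_volume": np.clip(rng.normal(450.0, 60.0, n), 200.0, 800.0),
        "base_excess": rng.normal(0.0, 3.0, n),
        "lactate": _lognormal(rng, 1.7, 0.45, n),
        "ph": rng.normal(7.36, 0.05, n),
        "paco2": rng.normal(41.0, 5.0, n),
        "spo2": np.clip(rng.normal(97.0, 1.5, n), 80.0, 100.0),
        "heart_rate": rng.normal(85.0, 15.0, n),
        "mean_arterial_pressure": rng.normal(75.0, 10.0, n),
        "temperature": rng.normal(37.0, 0.5, n),
        "wbc": _lognormal(rng, 12.0, 0.4, n),
        "resp_rate_total": np.clip(rng.normal(18.0, 4.0, n), 8.0, 35.0),
    }
    lat["pao2"] = lat["pf"] * lat["fio2"] / 100.0
    lat["pplat"] = lat["dp"] + lat["peep"]
    lat["ppeak"] = lat["pplat"] + np.clip(rng.normal(4.0, 1.0, n), 1.0, 8.0)
    lat["minute_volume"] = lat["tidal_volume"] * lat["resp_rate_total"] / 1000.0

    # logistic failure mechanism on standardized latent features
    coefs = config.failure_coefficients
    eta = np.full(n, float(coefs.get("intercept", 0.0)))
    for name, (c0, sc) in FEATURE_SCALES.items():
        eta += coefs.get(name, 0.0) * (lat[name] - c0) / sc
    p_fail = _sigmoid(eta)
    fails = rng.random(n) < p_fail

    # switch-readiness process
    readiness = _lognormal(rng, config.readiness_dist[0] * 24.0, config.readiness_dist[1], n)
    attempt_time = readiness * np.exp(rng.normal(0.0, config.readiness_noise_sd, n))
    premature = rng.random(n) < config.premature_attempt_prob
    attempt_time = np.where(premature, attempt_time * rng.uniform(0.2, 0.6, n), attempt_time)
    attempt_time = np.maximum(attempt_time, 1.5)
    course_cap = np.maximum(_lognormal(rng, config.controlled_course_dist[0], config.controlled_course_dist[1], n), 49.0)
    no_attempt = attempt_time > course_cap

    ttf = _truncated_lognormal(
        rng, config.ttf_dist[0], config.ttf_dist[1], config.min_segment_hours, 71.9, n
    )
    death_as_failure = rng.random(n) < config.death_failure_prob

    mm = config.mortality_model
    base_logit = np.log(mm["baseline_prob"] / (1.0 - mm["baseline_prob"]))

    min_seg = config.min_segment_hours
    stays_rows = []
    mode_rows: list[tuple] = []
    airway_rows: list[tuple] = []
    truth_rows = []
    per_patient_changes: list[list[tuple[float, str]]] = []

    for i in range(n):
        changes = [(0.0, CONTROLLED)]
        death = np.nan
        cause = "none"
        fail_time = np.nan
        if no_attempt[i]:
            ext = course_cap[i]
            t_att = np.nan
            outcome = "none"
            if rng.random() < _sigmoid(base_logit + mm.get("no_switch_log_odds", 0.0)):
                death = ext + 0.5 + _lognormal(rng, 48.0, 0.8)
        else:
            t_att = attempt_time[i]
            changes.append((t_att, ASSISTED))
            if not fails[i]:
                outcome = "success"
                dur = max(min_seg, _lognormal(rng, *config.success_assisted_dist))
                ext = t_att + dur
                if rng.random() < mm["baseline_prob"]:
                    death = max(ext, t_att + 72.0) + 0.5 + _lognormal(rng, 96.0, 1.0)
            else:
                outcome = "failure"
                fail_time = t_att + ttf[i]
                if death_as_failure[i]:
                    cause = "death"
                    death = fail_time
                    ext = fail_time
                else:
                    cause = "return_to_controlled"
                    changes.append((fail_time, CONTROLLED))
                    cur = fail_time
                    n_sec = int(rng.poisson(config.n_secondary_mean))
                    for j in range(n_sec):
                        gap = min_seg + _lognormal(rng, *config.secondary_gap_dist)
                        dur = min_seg + _lognormal(rng, *config.secondary_duration_dist)
                        t_a = cur + gap
                        changes.append((t_a, ASSISTED))
                        if j < n_sec - 1:
                            changes.append((t_a + dur, CONTROLLED))
                        cur = t_a + dur
                    ext = cur if n_sec else cur + min_seg + _lognormal(rng, 24.0, 0.6)
                    if rng.random() < _sigmoid(base_logit + mm["failure_log_odds"]):
                        death = ext + 0.5 + _lognormal(rng, 72.0, 1.0)

        discharge = ext + _lognormal(rng, *config.post_mv_icu_dist)
        if not np.isnan(death):
            discharge = min(discharge, death)
        # death can never precede the end of invasive ventilation here
        stays_rows.append(
            {
                "stay_id": i,
                "center": int(center[i]),
                "admission_time": 0.0,
                "discharge_time": float(discharge),
                "death_time": float(death) if not np.isnan(death) else np.nan,
                "age": int(np.clip(rng.normal(63.0, 14.0), 18, 95)),
                "sex": "F" if rng.random() < 0.37 else "M",
                "apache2": int(np.clip(rng.normal(26.0, 7.0), 4, 50)),
                "first_stay": True,
            }
        )
        airway_rows.append((i, 0.0, "intubation"))
        airway_rows.append((i, float(ext), "extubation"))
        per_patient_changes.append(changes)
        truth_rows.append(
            {
                "stay_id": i,
                "center": int(center[i]),
                "true_first_attempt_time": float(t_att) if not np.isnan(t_att) else np.nan,
                "true_outcome": outcome,
                "true_failure_cause": cause,
                "true_failure_time": float(fail_time) if not np.isnan(fail_time) else np.nan,
                "true_failure_probability": float(p_fail[i]),
                "true_pf": float(lat["pf"][i]),
                "true_peep": float(lat["peep"][i]),
                "true_base_excess": float(lat["base_excess"][i]),
                "true_lactate": float(lat["lactate"][i]),
                "true_dp": float(lat["dp"][i]),
            }
        )

        # raw mode log: a record at every change plus periodic re-logs
        dialect = config.mode_dialects[int(center[i]) % len(config.mode_dialects)]
        log_dt = config.mode_log_interval_hours.get(int(center[i]), 4.0)
        chg_t = np.array([t for t, _ in changes])
        chg_c = [c for _, c in changes]
        grid = np.arange(log_dt, ext, log_dt)
        all_t = np.concatenate([chg_t, grid])
        idx = np.searchsorted(chg_t, all_t, side="right") - 1
        order = np.argsort(all_t, kind="stable")
        for k in order:
            cat = chg_c[idx[k]]
            labels = dialect.labels_for(cat)
            mode_rows.append((i, int(center[i]), float(all_t[k]), labels[int(rng.integers(len(labels)))]))

    stays = pd.DataFrame(stays_rows, columns=STAY_COLUMNS)
    airway = pd.DataFrame(airway_rows, columns=AIRWAY_COLUMNS)
    mode_events = pd.DataFrame(mode_rows, columns=MODE_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    measurements = _generate_measurements(config, rng, stays, lat, per_patient_changes, airway)

    if config.combined_fraction > 0:
        mode_events, extra_rr = inject_combined_modes(
            mode_events, config.combined_fraction, config, rng=np.random.default_rng(config.seed + 1)
        )
        measurements = pd.concat([measurements, extra_rr], ignore_index=True)

    mode_events = mode_events.sort_values(["stay_id", "time"], kind="stable").reset_index(drop=True)
    measurements = (
        measurements.sort_values(["stay_id", "time", "variable"], kind="stable").reset_index(drop=True)
    )
    airway = airway.sort_values(["stay_id", "time"], kind="stable").reset_index(drop=True)
    return stays, mode_events, airway, measurements, truth


def _generate_measurements(config, rng, stays, lat, per_patient_changes, airway) -> pd.DataFrame:
    """Sample each variable on its center's logging grid, thinned by missingness."""
    ext_by_stay = (
        airway[airway["event"] == "extubation"].set_index("stay_id")["time"].to_dict()
    )
    sid_col, ctr_col, t_col, var_col, val_col = [], [], [], [], []
    for i, row in enumerate(stays.itertuples(index=False)):
        c = int(row.center)
        end = float(ext_by_stay[row.stay_id])
        intervals = config.logging_interval_hours.get(c, DEFAULT_LOGGING_INTERVALS[c % 3])
        changes = per_patient_changes[i]
        chg_t = np.array([t for t, _ in changes])
        chg_assisted = np.array([cat == ASSISTED for _, cat in changes])
        for var, dt in intervals.items():
            times = np.arange(0.0, end, dt)
            if times.size == 0:
                continue
            miss = config.missingness_rates.get(var, 0.0)
            if miss > 0:
                times = times[rng.random(times.size) > miss]
            if times.size == 0:
                continue
            assisted_at = chg_assisted[np.searchsorted(chg_t, times, side="right") - 1]
            if var == "spont_rr":
                vals = np.where(
                    assisted_at,
                    rng.uniform(15.0, 28.0, times.size),
                    rng.uniform(0.0, 8.0, times.size),
                )
            else:
                sd = config.noise_sd.get(var, 0.0)
                vals = np.full(times.size, lat[var][i])
                if sd > 0:
                    vals = vals + rng.normal(0.0, sd, times.size)
                shift = ASSISTED_SHIFT.get(var, 0.0)
                if shift:
                    vals = vals + shift * assisted_at
                if var in ("peep", "fio2", "tidal_volume"):
                    vals = np.round(np.clip(vals, 0.0, None))
            sid_col.append(np.full(times.size, row.stay_id))
            ctr_col.append(np.full(times.size, c))
            t_col.append(times)
            var_col.append(np.full(times.size, var, dtype=object))
            val_col.append(vals)
    if not sid_col:
        return pd.DataFrame(columns=MEAS_COLUMNS)
    return pd.DataFrame(
        {
            "stay_id": np.concatenate(sid_col),
            "center": np.concatenate(ctr_col),
            "time": np.concatenate(t_col),
            "variable": np.concatenate(var_col),
            "value": np.concatenate(val_col),
        }
    )


def inject_combined_modes(
    mode_events: pd.DataFrame,
    fraction: float,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
):
    """Rewrite a fraction of controlled/assisted mode records as combined labels.

    Each rewritten record gets a spontaneous-respiratory-rate measurement at
    the same timestamp that is consistent with the underlying truth (> 10
    breaths/min where the original category was assisted, ≤ 10 where
    controlled), so that combined-mode reassignment can recover the original
    categories.  Returns the rewritten table and the extra measurements.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError(f"fraction must be in [0, 1], got {fraction}")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    events = mode_events.copy().reset_index(drop=True)
    if fraction == 0.0 or not len(events):
        return events, pd.DataFrame(columns=MEAS_COLUMNS)

    dialects = config.mode_dialects
    cats = np.array(
        [
            dialects[int(c) % len(dialects)].mapping.get(lbl, NONINVASIVE_OR_NONE)
            for c, lbl in zip(events["center"], events["raw_label"])
        ],
        dtype=object,
    )
    eligible = np.isin(cats, [CONTROLLED, ASSISTED])
    pick = eligible & (rng.random(len(events)) < fraction)

    rr_rows = []
    labels = events["raw_label"].to_numpy(dtype=object).copy()
    for k in np.flatnonzero(pick):
        c = int(events.at[k, "center"])
        dialect = dialects[c % len(dialects)]
        combined_labels = dialect.labels_for(COMBINED)
        labels[k] = combined_labels[int(rng.integers(len(combined_labels)))]
        truth_assisted = cats[k] == ASSISTED
        rr = rng.uniform(14.0, 28.0) if truth_assisted else rng.uniform(0.0, 8.0)
        rr_rows.append((events.at[k, "stay_id"], c, float(events.at[k, "time"]), "spont_rr", rr))
    events["raw_label"] = labels
    extra = pd.DataFrame(rr_rows, columns=MEAS_COLUMNS)
    return events, extra


def write_cohort(tables, out_dir) -> None:
    """Write the five cohort tables as CSV files with documented column names."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    names = ["stays", "mode_events", "airway_events", "measurements", "ground_truth"]
    for name, df in zip(names, tables):
        df.to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)


def read_cohort(in_dir):
    """Read the five cohort tables back from CSV."""
    import os

    names = ["stays", "mode_events", "airway_events", "measurements", "ground_truth"]
    return tuple(pd.read_csv(os.path.join(in_dir, f"{name}.csv")) for name in names)
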