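"""End-to-end orchestration: tables in → harmonize → detect → label → analyze.

The pipeline consumes five tidy CSV tables (stays, mode_events,
airway_events, measurements, ground_truth is optional) — either synthetic or
user-supplied in the same generic schema — and produces the cohort-flow
counts, the baseline / before-switch / after-switch comparison tables, the
still-assisted follow-up curve, the PEEP-interaction results and the two
failure-prediction models.  Every threshold (persistence hours, outcome
horizon, LOCF window, Δ horizon, spontaneous-RR cutoff, missingness
fractions, PEEP strata) is a config field with the study default, never a
hard-coded constant.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import endpoints as ep
from . import feature_extraction as fx
from . import prediction as pred
from . import stats_compare as sc
from . import switch_detection as sd
from .mode_timeline import CONTROLLED, ModeTimeline, harmonize
from .synthetic_data import CohortConfig, generate_cohort, read_cohort, write_cohort

logger = logging.getLogger(__name__)

#: variables described before/after the switch (plus derived pf/dp/crs)
TIME_VARYING = [
    "pao2", "paco2", "ph", "base_excess", "lactate", "fio2", "spo2",
    "peep", "pplat", "ppeak", "tidal_volume", "minute_volume",
    "resp_rate_total", "heart_rate", "mean_arterial_pressure", "temperature", "wbc",
]
DERIVED = ["pf", "dp", "crs"]

#: variable groups for prediction attribution, following the comparison
#: tables' section headers
VARIABLE_GROUPS = {
    "gas_exchange": ["pao2", "paco2", "ph", "base_excess", "lactate", "fio2", "spo2", "pf"],
    "ventilatory": ["peep", "pplat", "ppeak", "tidal_volume", "minute_volume", "resp_rate_total", "dp", "crs"],
    "inflammatory": ["wbc"],
    "other": ["heart_rate", "mean_arterial_pressure", "temperature"],
}


@dataclass
class RunConfig:
    """Thresholds, toggles and I/O for one pipeline run."""

    cohort: CohortConfig | None = None  # simulate when set …
    input_dir: str | None = None  # … or read tables from here
    out_dir: str = "ventswitch_run"
    seed: int = 0
    persistence_hours: float = 1.0
    horizon_hours: float = 72.0
    locf_window_hours: float = 12.0
    delta_horizon_hours: float = 3.0
    delta_sweep_hours: tuple = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
    rr_threshold: float = 10.0
    nearest_tolerance_hours: float = 1.0
    before_exclude_missing_frac: float = 2.0 / 3.0
    after_include_frac: float = 1.0 / 3.0
    peep_bounds: tuple = (5.0, 10.0)
    pf_threshold: float = 300.0
    pf_window_hours: float = 48.0
    min_mv_hours: float = 48.0
    run_baseline: bool = True
    run_before: bool = True
    run_after: bool = True
    run_predict: bool = True

    def __post_init__(self) -> None:
        for name in (
            "persistence_hours", "horizon_hours", "locf_window_hours",
            "delta_horizon_hours", "nearest_tolerance_hours",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if list(self.delta_sweep_hours) != sorted(self.delta_sweep_hours):
            raise ValueError("delta_sweep_hours must be sorted ascending")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"] = {"n_patients": self.cohort.n_patients, "seed": self.cohort.seed}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# cohort-level helpers


def stay_end_times(stays: pd.DataFrame) -> dict:
    """End of follow-up per stay: death or ICU discharge, whichever is first."""
    out = {}
    for row in stays.itertuples(index=False):
        end = row.discharge_time
        if not pd.isna(row.death_time):
            end = min(end, row.death_time)
        out[row.stay_id] = float(end)
    return out


def harmonize_cohort(
    stays: pd.DataFrame,
    mode_events: pd.DataFrame,
    airway_events: pd.DataFrame,
    measurements: pd.DataFrame,
    dialects: dict,
    config: RunConfig,
) -> dict[object, ModeTimeline]:
    """Build a persistence-filtered functional timeline for every stay."""
    ends = stay_end_times(stays)
    rr = measurements[measurements["variable"] == "spont_rr"]
    rr_by_stay = {k: v for k, v in rr.groupby("stay_id")}
    modes_by_stay = {k: v for k, v in mode_events.groupby("stay_id")}
    airway_by_stay = {k: v for k, v in airway_events.groupby("stay_id")}
    timelines = {}
    for row in stays.itertuples(index=False):
        sid = row.stay_id
        if sid not in modes_by_stay or sid not in airway_by_stay:
            logger.warning("stay %r: missing mode or airway events; skipped", sid)
            continue
        dialect = dialects[int(row.center) % len(dialects)]
        timelines[sid] = harmonize(
            modes_by_stay[sid],
            airway_by_stay[sid],
            dialect,
            stay_end=ends[sid],
            spont_rr=rr_by_stay.get(sid),
            rr_threshold=config.rr_threshold,
            nearest_tolerance=config.nearest_tolerance_hours,
            min_persistence=config.persistence_hours,
        )
    return timelines


def derived_measurements(measurements: pd.DataFrame, tolerance: float = 1.0) -> pd.DataFrame:
    """Append derived pf / dp / crs series to the long measurement table."""
    def series(var):
        return measurements[measurements["variable"] == var][["stay_id", "time", "value"]]

    out = [measurements]
    pf = fx.derive_pf(series("pao2"), series("fio2"), tolerance)
    dp = fx.derive_dp(series("pplat"), series("peep"), tolerance)
    crs = fx.derive_crs(dp, series("tidal_volume"), tolerance)
    for name, df in (("pf", pf), ("dp", dp), ("crs", crs)):
        if len(df):
            add = df.copy()
            add["variable"] = name
            out.append(add[["stay_id", "time", "variable", "value"]])
    return pd.concat(out, ignore_index=True).sort_values(
        ["stay_id", "time", "variable"], kind="stable"
    ).reset_index(drop=True)


def screen_and_detect(
    stays: pd.DataFrame,
    timelines: dict,
    measurements_with_derived: pd.DataFrame,
    config: RunConfig,
):
    """Eligibility screening plus first-attempt detection and labeling.

    Returns (eligibility table, labeled first-attempt table with secondary
    counts and liberation times, flow counts dict).
    """
    pf = measurements_with_derived[measurements_with_derived["variable"] == "pf"]
    pf_by_stay = {k: v for k, v in pf.groupby("stay_id")}
    death = stays.set_index("stay_id")["death_time"].to_dict()

    elig_rows, attempt_rows = [], []
    for row in stays.itertuples(index=False):
        sid = row.stay_id
        tl = timelines.get(sid)
        if tl is None:
            continue
        res = sd.check_eligibility(
            {"first_stay": row.first_stay},
            tl,
            pf_by_stay.get(sid),
            pf_threshold=config.pf_threshold,
            pf_window=config.pf_window_hours,
            min_mv_hours=config.min_mv_hours,
        )
        elig_rows.append({"stay_id": sid, "eligible": res.eligible, "reasons": ";".join(res.reasons)})
        if not res.eligible:
            continue
        d = death.get(sid)
        d = None if d is None or pd.isna(d) else float(d)
        attempts = sd.detect_and_label(tl, d, horizon=config.horizon_hours)
        if not attempts:
            attempt_rows.append({"stay_id": sid, "time": np.nan, "attempt_type": None, "outcome": "no_switch",
                                 "failure_cause": None, "failure_time": np.nan, "n_secondary": 0,
                                 "liberation_time": np.nan})
            continue
        first = attempts[0]
        # liberation: end of the invasive interval containing the attempt
        lib = np.nan
        for a, b in tl.invasive_intervals:
            if a <= first.time < b:
                lib = b
                break
        attempt_rows.append(
            {
                "stay_id": sid,
                "time": first.time,
                "attempt_type": first.attempt_type,
                "outcome": first.outcome,
                "failure_cause": first.failure_cause,
                "failure_time": first.failure_time if first.failure_time is not None else np.nan,
                "n_secondary": len(attempts) - 1,
                "liberation_time": lib,
            }
        )

    eligibility = pd.DataFrame(elig_rows)
    attempts_df = pd.DataFrame(attempt_rows)
    flow = flow_counts(attempts_df)
    return eligibility, attempts_df, flow


def flow_counts(attempts_df: pd.DataFrame) -> dict:
    """Cohort-flow counts over eligible stays; satisfies the partition identities
    eligible = attempted + no_switch and attempted = success + failure."""
    if not len(attempts_df):
        return {k: 0 for k in ("eligible", "attempted", "success", "failure", "no_switch", "mode_change", "rr_change")}
    out = {
        "eligible": int(len(attempts_df)),
        "attempted": int((attempts_df["outcome"] != "no_switch").sum()),
        "success": int((attempts_df["outcome"] == "success").sum()),
        "failure": int((attempts_df["outcome"] == "failure").sum()),
        "no_switch": int((attempts_df["outcome"] == "no_switch").sum()),
        "mode_change": int((attempts_df["attempt_type"] == "mode_change").sum()),
        "rr_change": int((attempts_df["attempt_type"] == "rr_change").sum()),
    }
    return out


def flow_percentages(counts: dict) -> dict:
    """Flow fractions in percent: attempted and no-switch relative to the
    eligible cohort, success/failure/mode-change relative to attempts."""
    eligible = counts["eligible"]
    attempted = counts["attempted"]
    out = {}
    if eligible:
        out["attempted_pct"] = 100.0 * attempted / eligible
        out["no_switch_pct"] = 100.0 * counts["no_switch"] / eligible
    if attempted:
        out["success_pct"] = 100.0 * counts["success"] / attempted
        out["failure_pct"] = 100.0 * counts["failure"] / attempted
        out["mode_change_pct"] = 100.0 * counts["mode_change"] / attempted
    return out


# ---------------------------------------------------------------------------
# analysis stages


def baseline_analysis(stays: pd.DataFrame, attempts_df: pd.DataFrame, timelines: dict) -> dict:
    """Endpoints and attempt-timing summaries by first-attempt outcome."""
    ends = stay_end_times(stays)
    death = stays.set_index("stay_id")["death_time"].to_dict()
    rows = []
    for sid in attempts_df["stay_id"]:
        tl = timelines[sid]
        e = ep.compute_endpoints(sid, tl.invasive_intervals, death.get(sid), ends[sid])
        rows.append({"stay_id": sid, "mort28": e.mort28, "vfd28": e.vfd28,
                     "mv_days": e.mv_days, "icu_los_days": e.icu_los_days})
    endpoints_df = pd.DataFrame(rows).merge(
        attempts_df[["stay_id", "outcome", "time", "failure_time", "n_secondary"]], on="stay_id"
    )
    att = endpoints_df[endpoints_df["outcome"].isin(["success", "failure"])]
    succ = att[att["outcome"] == "success"]
    fail = att[att["outcome"] == "failure"]
    comparisons = []
    if len(succ) and len(fail):
        comparisons.append(sc.compare_groups(succ["mort28"].astype(float), fail["mort28"].astype(float),
                                             "mort28", var_type="binary"))
        for var in ("vfd28", "mv_days", "icu_los_days"):
            comparisons.append(sc.compare_groups(succ[var], fail[var], var))
        comparisons.append(sc.compare_groups(succ["time"] / 24.0, fail["time"] / 24.0, "days_to_first_attempt"))
    table = pd.DataFrame(
        {
            "variable": [c.variable for c in comparisons],
            "summary_success": [c.summary_success for c in comparisons],
            "summary_failure": [c.summary_failure for c in comparisons],
            "test": [c.test for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
        }
    )
    curve = None
    ttf = (fail["failure_time"] - fail["time"]).dropna().to_numpy()
    if ttf.size:
        curve = ep.assisted_survival_curve(ttf)
    return {"endpoints": endpoints_df, "table": table, "curve": curve, "time_to_failure": ttf}


def before_switch_analysis(
    measurements_with_derived: pd.DataFrame,
    attempts_df: pd.DataFrame,
    stays: pd.DataFrame,
    config: RunConfig,
) -> dict:
    """Windowed-LOCF pre-switch comparison with PEEP-interaction testing."""
    att = attempts_df[attempts_df["outcome"].isin(["success", "failure"])].reset_index(drop=True)
    variables = TIME_VARYING + DERIVED
    matrix = fx.extract_features(measurements_with_derived, att, variables, window=config.locf_window_hours)
    matrix = matrix.merge(att[["stay_id", "outcome"]], on="stay_id")

    avail = {v: int(matrix[v].notna().sum()) for v in variables}
    included = fx.select_variables(
        avail, len(matrix), "before", before_exclude_missing_frac=config.before_exclude_missing_frac
    )
    missing = fx.missingness_report(matrix, matrix["outcome"], included)

    succ = matrix[matrix["outcome"] == "success"]
    fail = matrix[matrix["outcome"] == "failure"]
    comparisons = []
    for var in included:
        a, b = succ[var].dropna(), fail[var].dropna()
        if len(a) and len(b):
            comparisons.append(sc.compare_groups(a, b, var))
    table = pd.DataFrame(
        {
            "variable": [c.variable for c in comparisons],
            "summary_success": [c.summary_success for c in comparisons],
            "summary_failure": [c.summary_failure for c in comparisons],
            "test": [c.test for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
        }
    ).merge(missing, on="variable", how="left")

    # PEEP-stratified interaction analysis for pf and crs, pairing each
    # measurement with its nearest prior PEEP
    centers = stays.set_index("stay_id")["center"].to_dict()
    interactions = {}
    for var in ("pf", "crs"):
        if var not in included or f"{var}__time" not in matrix.columns:
            continue
        paired = _paired_peep(measurements_with_derived, matrix, var, config.nearest_tolerance_hours)
        ok = matrix[var].notna() & ~np.isnan(paired)
        if ok.sum() < 50:
            continue
        y = (matrix.loc[ok, "outcome"] == "success").to_numpy(dtype=float)
        try:
            interactions[var] = sc.interaction_test(
                y,
                matrix.loc[ok, var].to_numpy(),
                paired[ok.to_numpy()],
                np.array([centers[s] for s in matrix.loc[ok, "stay_id"]]),
                variable=var,
            )
        except ValueError as exc:
            logger.warning("interaction test for %s skipped: %s", var, exc)
    return {"matrix": matrix, "included": included, "table": table, "interactions": interactions}


def _paired_peep(measurements, matrix, var, tolerance) -> np.ndarray:
    """Nearest prior PEEP for each stay's pre-switch measurement of ``var``."""
    peep = measurements[measurements["variable"] == "peep"][["stay_id", "time", "value"]]
    left = matrix[["stay_id", f"{var}__time"]].rename(columns={f"{var}__time": "time"}).copy()
    left["_row"] = np.arange(len(left))
    left_valid = left.dropna(subset=["time"]).sort_values("time", kind="stable")
    merged = pd.merge_asof(
        left_valid,
        peep.rename(columns={"value": "peep", "time": "peep_time"}).sort_values("peep_time", kind="stable"),
        left_on="time",
        right_on="peep_time",
        by="stay_id",
        direction="backward",
        tolerance=tolerance + 1e-9,
        allow_exact_matches=True,
    )
    out = np.full(len(left), np.nan)
    out[merged["_row"].to_numpy()] = merged["peep"].to_numpy()
    return out


def after_switch_analysis(
    measurements_with_derived: pd.DataFrame,
    attempts_df: pd.DataFrame,
    config: RunConfig,
    horizon: float | None = None,
) -> dict:
    """Δ-horizon change comparison restricted to in-mode survivors."""
    h = horizon if horizon is not None else config.delta_horizon_hours
    att = attempts_df[attempts_df["outcome"].isin(["success", "failure"])].reset_index(drop=True)
    retained = fx.exclusion_for_delta(att, horizon=h)
    variables = TIME_VARYING + DERIVED
    deltas = fx.extract_deltas(
        measurements_with_derived, retained, variables, horizon=h, window=config.locf_window_hours
    )
    deltas = deltas.merge(retained[["stay_id", "outcome"]], on="stay_id")
    avail = {f"delta_{v}": int(deltas[f"delta_{v}"].notna().sum()) for v in variables}
    included = fx.select_variables(avail, len(deltas), "after", after_include_frac=config.after_include_frac)
    missing = fx.missingness_report(deltas, deltas["outcome"], included)
    succ = deltas[deltas["outcome"] == "success"]
    fail = deltas[deltas["outcome"] == "failure"]
    comparisons = []
    for var in included:
        a, b = succ[var].dropna(), fail[var].dropna()
        if len(a) and len(b):
            comparisons.append(sc.compare_groups(a, b, var, continuous_test="t"))
    table = pd.DataFrame(
        {
            "variable": [c.variable for c in comparisons],
            "summary_success": [f"{succ[c.variable].mean():.2f} ({succ[c.variable].std():.2f})" for c in comparisons],
            "summary_failure": [f"{fail[c.variable].mean():.2f} ({fail[c.variable].std():.2f})" for c in comparisons],
            "test": [c.test for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
        }
    ).merge(missing, on="variable", how="left")
    return {"deltas": deltas, "retained": retained, "included": included, "table": table}


def predictive_analysis(
    before: dict, after: dict, attempts_df: pd.DataFrame, config: RunConfig
) -> dict:
    """Fit models 1 and 2 with nested cross-validation."""
    matrix = before["matrix"]
    outcomes = matrix.set_index("stay_id")["outcome"]
    feat = matrix.drop(columns=["outcome"])
    out = {}
    d1 = pred.build_design(feat, outcomes, model_id=1)
    out["model1"] = pred.fit_lasso_cv(d1, seed=config.seed)
    deltas = after["deltas"].drop(columns=["outcome"])
    d2 = pred.build_design(
        feat, outcomes, deltas=deltas, model_id=2, retained_stays=after["retained"]["stay_id"].to_numpy()
    )
    out["model2"] = pred.fit_lasso_cv(d2, seed=config.seed)
    groups = {g: [c for c in cols if c in d1.feature_names] for g, cols in VARIABLE_GROUPS.items()}
    groups = {g: cols for g, cols in groups.items() if cols}
    out["group_contribution"] = pred.group_contribution(d1, groups, seed=config.seed)
    return out


# ---------------------------------------------------------------------------
# top-level runs


def _load_tables(config: RunConfig):
    if config.input_dir:
        return read_cohort(config.input_dir)
    cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
    return generate_cohort(cohort_cfg)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; write outputs under ``config.out_dir``.

    Always produces the cohort-flow counts; the analysis stages honor their
    toggles.  Re-running with the same config reproduces every output file.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    log_path = os.path.join(config.out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("ventswitch")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("run config: %s", {k: v for k, v in dataclasses.asdict(config).items() if k != "cohort"})
        stays, mode_events, airway, measurements, truth = _load_tables(config)
        from .synthetic_data import DEFAULT_DIALECTS

        dialects = (config.cohort.mode_dialects if config.cohort else DEFAULT_DIALECTS)
        timelines = harmonize_cohort(stays, mode_events, airway, measurements, dialects, config)
        meas = derived_measurements(measurements, tolerance=config.nearest_tolerance_hours)
        eligibility, attempts_df, flow = screen_and_detect(stays, timelines, meas, config)

        results: dict = {"flow_counts": flow, "flow_percentages": flow_percentages(flow),
                         "eligibility": eligibility, "attempts": attempts_df, "timelines": timelines,
                         "measurements": meas, "stays": stays, "ground_truth": truth}
        eligibility.to_csv(os.path.join(config.out_dir, "eligibility.csv"), index=False)
        attempts_df.to_csv(os.path.join(config.out_dir, "attempts.csv"), index=False)
        with open(os.path.join(config.out_dir, "cohort_flow.json"), "w") as fh:
            json.dump({"counts": flow, "percentages": results["flow_percentages"]}, fh, indent=2)

        if config.run_baseline and len(attempts_df):
            base = baseline_analysis(stays, attempts_df, timelines)
            results["baseline"] = base
            base["table"].to_csv(os.path.join(config.out_dir, "table1_baseline.csv"), index=False)
            if base["curve"] is not None:
                base["curve"].to_csv(os.path.join(config.out_dir, "assisted_survival_curve.csv"), index=False)
        if config.run_before and len(attempts_df):
            before = before_switch_analysis(meas, attempts_df, stays, config)
            results["before"] = before
            before["table"].to_csv(os.path.join(config.out_dir, "table2_before_switch.csv"), index=False)
            inter_rows = [
                {"variable": k, "p_interaction": v.p_interaction, "sigma": v.sigma, "n": v.n}
                for k, v in before["interactions"].items()
            ]
            pd.DataFrame(inter_rows).to_csv(os.path.join(config.out_dir, "peep_interaction.csv"), index=False)
        if config.run_after and len(attempts_df):
            after = after_switch_analysis(meas, attempts_df, config)
            results["after"] = after
            after["table"].to_csv(os.path.join(config.out_dir, "table3_after_switch.csv"), index=False)
        if config.run_predict and config.run_before and config.run_after and len(attempts_df):
            try:
                pr = predictive_analysis(results["before"], results["after"], attempts_df, config)
                results["prediction"] = pr
                payload = {
                    "model1": pr["model1"].to_dict(),
                    "model2": pr["model2"].to_dict(),
                    "group_contribution": pr["group_contribution"].to_dict(orient="records"),
                    "full_auc": pr["group_contribution"].attrs.get("full_auc"),
                }
                with open(os.path.join(config.out_dir, "prediction.json"), "w") as fh:
                    json.dump(payload, fh, indent=2)
            except ValueError as exc:
                logger.warning("predictive analysis skipped: %s", exc)
        return results
    finally:
        root.removeHandler(handler)
        handler.close()


def sensitivity_suite(config: RunConfig, results: dict | None = None) -> dict:
    """Sensitivity re-analyses: 72 h survivors, per-center, attempt type,
    early/late failures, and the Δ1h–Δ8h horizon sweep."""
    if results is None:
        results = run_pipeline(config)
    stays = results["stays"]
    attempts = results["attempts"]
    timelines = results["timelines"]
    meas = results["measurements"]
    out: dict = {}

    death = stays.set_index("stay_id")["death_time"].to_dict()
    att = attempts[attempts["outcome"].isin(["success", "failure"])]

    # 1. baseline restricted to patients surviving >= 72 h post-attempt
    surv_ids = [
        r.stay_id
        for r in att.itertuples(index=False)
        if pd.isna(death.get(r.stay_id)) or death[r.stay_id] > r.time + config.horizon_hours
    ]
    surv = attempts[attempts["stay_id"].isin(surv_ids)]
    out["survivor_baseline"] = baseline_analysis(stays, surv, timelines)["table"]

    # 2. per-center tables
    centers = stays.set_index("stay_id")["center"].to_dict()
    out["per_center"] = {}
    for c in sorted(set(centers.values())):
        sub = attempts[[centers[s] == c for s in attempts["stay_id"]]]
        if len(sub) and (sub["outcome"].isin(["success", "failure"])).sum() > 10:
            out["per_center"][c] = baseline_analysis(stays, sub, timelines)["table"]

    # 3. attempt-type stratification
    out["attempt_type"] = {}
    for t in ("mode_change", "rr_change"):
        sub = attempts[attempts["attempt_type"] == t]
        if len(sub) > 10:
            res = baseline_analysis(stays, sub, timelines)
            out["attempt_type"][t] = {
                "table": res["table"],
                "median_ttf": float(np.median(res["time_to_failure"])) if len(res["time_to_failure"]) else np.nan,
            }

    # 4. early vs late failures at the median time to failure
    fails = att[att["outcome"] == "failure"]
    ttf = (fails["failure_time"] - fails["time"]).to_numpy()
    if ttf.size:
        early, med = ep.split_early_late(ttf)
        out["early_late"] = {
            "median": med,
            "early": baseline_analysis(stays, fails[early], timelines)["table"],
            "late": baseline_analysis(stays, fails[~early], timelines)["table"] if (~early).any() else None,
        }

    # 5. Δ-horizon sweep
    sweep = {}
    for h in config.delta_sweep_hours:
        res = after_switch_analysis(meas, attempts, config, horizon=h)
        sweep[h] = {"n_retained": len(res["retained"]), "table": res["table"]}
    out["delta_sweep"] = sweep
    return out
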