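"""Derived respiratory parameters and windowed pre/post-switch feature sampling.

Derived parameters pair a primary measurement with the *nearest prior*
partner measurement, where "nearest prior" means at or before the primary
timestamp and within a one-hour tolerance — no silent extrapolation:

* PaO2/FiO2 (mmHg) from arterial PaO2 and the nearest prior FiO2;
* driving pressure ΔP (cmH2O) = plateau pressure − nearest prior PEEP;
* respiratory-system compliance C_RS (mL/cmH2O) = nearest prior tidal
  volume / ΔP.

Pre-switch feature vectors use windowed last-observation-carried-forward
(LOCF): the most recent measurement up to 12 h before the attempt, the
window closed at both ends.  Post-switch change vectors Δ_h subtract the
pre-switch LOCF value from the most recent measurement in ``(anchor,
anchor + h]`` (positive Δ = increase after the switch).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_EPS = 1e-9


def normalize_fio2(series: pd.DataFrame) -> pd.DataFrame:
    """Return FiO2 in percent; values ≤ 1.0 are treated as fractions.

    Some charting systems log inspired-oxygen fraction on [0.21, 1.0] rather
    than percent; those values are multiplied by 100 with a logged warning.
    """
    out = series.copy()
    frac = out["value"] <= 1.0
    if frac.any():
        logger.warning("FiO2: %d values <= 1.0 interpreted as fractions and scaled to percent", int(frac.sum()))
        out.loc[frac, "value"] = out.loc[frac, "value"] * 100.0
    return out


def _nearest_prior_merge(
    primary: pd.DataFrame, partner: pd.DataFrame, tolerance: float
) -> pd.DataFrame:
    """For each primary point, attach the latest partner value at or before it
    within ``tolerance`` hours (per stay).  Rows without a partner are dropped."""
    by = ["stay_id"] if "stay_id" in primary.columns and "stay_id" in partner.columns else None
    left = primary.sort_values("time", kind="stable").reset_index(drop=True)
    right = partner.sort_values("time", kind="stable").reset_index(drop=True)
    merged = pd.merge_asof(
        left,
        right.rename(columns={"value": "partner_value", "time": "partner_time"}).sort_values(
            "partner_time", kind="stable"
        ),
        left_on="time",
        right_on="partner_time",
        by=by,
        direction="backward",
        tolerance=tolerance,
        allow_exact_matches=True,  # "nearest prior" includes a simultaneous timestamp
    )
    return merged.dropna(subset=["partner_value"])


def derive_pf(pao2: pd.DataFrame, fio2: pd.DataFrame, tolerance: float = 1.0) -> pd.DataFrame:
    """PaO2/FiO2 series (mmHg): one point per PaO2 with a prior FiO2 within tolerance."""
    fio2 = normalize_fio2(fio2)
    merged = _nearest_prior_merge(pao2, fio2, tolerance)
    bad = merged["partner_value"] <= 0
    if bad.any():
        logger.warning("derive_pf: skipping %d points with FiO2 <= 0", int(bad.sum()))
        merged = merged[~bad]
    out = merged[[c for c in ("stay_id", "time") if c in merged.columns]].copy()
    out["value"] = merged["value"].to_numpy() / (merged["partner_value"].to_numpy() / 100.0)
    return out.reset_index(drop=True)


def derive_dp(pplat: pd.DataFrame, peep: pd.DataFrame, tolerance: float = 1.0) -> pd.DataFrame:
    """Driving-pressure series (cmH2O): Pplat − nearest prior PEEP; negatives dropped."""
    merged = _nearest_prior_merge(pplat, peep, tolerance)
    dp = merged["value"].to_numpy() - merged["partner_value"].to_numpy()
    bad = dp < 0
    if bad.any():
        logger.warning("derive_dp: skipping %d points with Pplat < PEEP", int(bad.sum()))
    out = merged[[c for c in ("stay_id", "time") if c in merged.columns]].copy()
    out["value"] = dp
    return out[~bad].reset_index(drop=True)


def derive_crs(dp: pd.DataFrame, tidal_volume: pd.DataFrame, tolerance: float = 1.0) -> pd.DataFrame:
    """Compliance series (mL/cmH2O): nearest prior tidal volume / ΔP; requires ΔP > 0."""
    merged = _nearest_prior_merge(dp, tidal_volume, tolerance)
    bad = merged["value"] <= 0
    if bad.any():
        logger.warning("derive_crs: skipping %d points with non-positive driving pressure", int(bad.sum()))
        merged = merged[~bad]
    out = merged[[c for c in ("stay_id", "time") if c in merged.columns]].copy()
    out["value"] = merged["partner_value"].to_numpy() / merged["value"].to_numpy()
    return out.reset_index(drop=True)


def locf_sample(series: pd.DataFrame, anchor: float, window: float = 12.0) -> tuple[float, float] | None:
    """Latest (value, time) with time in the closed window [anchor − window, anchor]."""
    if series is None or not len(series):
        return None
    t = series["time"].to_numpy(dtype=float)
    mask = (t >= anchor - window - _EPS) & (t <= anchor + _EPS)
    if not mask.any():
        return None
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(t[idx])]
    return float(series["value"].to_numpy()[best]), float(t[best])


def post_sample(series: pd.DataFrame, anchor: float, horizon: float = 3.0) -> tuple[float, float] | None:
    """Latest (value, time) with time in (anchor, anchor + horizon]."""
    if series is None or not len(series):
        return None
    t = series["time"].to_numpy(dtype=float)
    mask = (t > anchor + _EPS) & (t <= anchor + horizon + _EPS)
    if not mask.any():
        return None
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(t[idx])]
    return float(series["value"].to_numpy()[best]), float(t[best])


def delta_sample(
    series: pd.DataFrame, anchor: float, horizon: float = 3.0, window: float = 12.0
) -> float | None:
    """Δ_h = post − pre; present only when both sides exist (no imputation)."""
    pre = locf_sample(series, anchor, window)
    post = post_sample(series, anchor, horizon)
    if pre is None or post is None:
        return None
    return post[0] - pre[0]


def _anchor_frame(anchors: pd.DataFrame) -> pd.DataFrame:
    out = anchors[["stay_id", "time"]].rename(columns={"time": "anchor_time"}).copy()
    return out


def extract_features(
    measurements: pd.DataFrame,
    anchors: pd.DataFrame,
    variables: list[str],
    window: float = 12.0,
) -> pd.DataFrame:
    """Windowed-LOCF feature matrix: one row per anchor, one column pair per variable.

    ``anchors`` needs columns ``stay_id`` and ``time`` (the switch-attempt
    time).  Output columns are ``<var>`` (value) and ``<var>__time``
    (measurement timestamp); missing cells are NaN.
    """
    base = _anchor_frame(anchors).sort_values("anchor_time", kind="stable")
    out = base.copy()
    for var in variables:
        sub = measurements[measurements["variable"] == var]
        sub = sub.sort_values("time", kind="stable")[["stay_id", "time", "value"]]
        merged = pd.merge_asof(
            base,
            sub.rename(columns={"time": f"{var}__time", "value": var}),
            left_on="anchor_time",
            right_on=f"{var}__time",
            by="stay_id",
            direction="backward",
            tolerance=window + _EPS,
            allow_exact_matches=True,
        )
        out[var] = merged[var].to_numpy()
        out[f"{var}__time"] = merged[f"{var}__time"].to_numpy()
    return out.sort_values("stay_id", kind="stable").reset_index(drop=True)


def extract_deltas(
    measurements: pd.DataFrame,
    anchors: pd.DataFrame,
    variables: list[str],
    horizon: float = 3.0,
    window: float = 12.0,
) -> pd.DataFrame:
    """Δ_h matrix: one row per anchor, column ``delta_<var>`` per variable."""
    base = _anchor_frame(anchors).sort_values("anchor_time", kind="stable")
    base = base.assign(_post_edge=base["anchor_time"] + horizon)
    pre = extract_features(measurements, anchors, variables, window=window)
    out = _anchor_frame(anchors).sort_values("stay_id", kind="stable").reset_index(drop=True)
    for var in variables:
        sub = measurements[measurements["variable"] == var]
        sub = sub.sort_values("time", kind="stable")[["stay_id", "time", "value"]]
        merged = pd.merge_asof(
            base.sort_values("_post_edge", kind="stable"),
            sub.rename(columns={"time": "post_time", "value": "post_value"}),
            left_on="_post_edge",
            right_on="post_time",
            by="stay_id",
            direction="backward",
            tolerance=horizon,
            allow_exact_matches=True,
        )
        # post side is anchor-exclusive: the latest point at or before the
        # horizon edge must lie strictly after the anchor
        valid = merged["post_time"] > merged["anchor_time"] + _EPS
        merged.loc[~valid, "post_value"] = np.nan
        merged = merged.sort_values("stay_id", kind="stable").reset_index(drop=True)
        out[f"delta_{var}"] = merged["post_value"].to_numpy() - pre[var].to_numpy()
    return out


def select_variables(
    availability: pd.Series | dict,
    n_patients: int,
    stage: str,
    before_exclude_missing_frac: float = 2.0 / 3.0,
    after_include_frac: float = 1.0 / 3.0,
) -> list[str]:
    """Variable inclusion by cohort-level availability.

    ``availability`` maps variable → number of patients with an observed
    value (before stage) or with a Δ value (after stage).  The before stage
    excludes variables missing for at least ``before_exclude_missing_frac``
    of patients; the after stage keeps variables with Δ data for at least
    ``after_include_frac`` of patients (boundary inclusive).
    """
    avail = pd.Series(availability, dtype=float)
    if n_patients <= 0:
        return []
    frac = avail / float(n_patients)
    if stage == "before":
        # exclusion at >= 2/3 missing, i.e. keep strictly more than 1/3 observed
        keep = (1.0 - frac) < before_exclude_missing_frac - _EPS
    elif stage == "after":
        keep = frac >= after_include_frac - _EPS
    else:
        raise ValueError(f"unknown stage {stage!r}")
    return [v for v in avail.index[keep]]


def missingness_report(matrix: pd.DataFrame, outcomes: pd.Series, variables: list[str]) -> pd.DataFrame:
    """Percent missing per variable in the successful and failed groups.

    ``matrix`` is a feature or delta matrix indexed like ``outcomes``
    (one row per stay); output mirrors the "Missingness (% successful,
    % failed)" presentation of the group-comparison tables.
    """
    rows = []
    grp = outcomes.to_numpy()
    for var in variables:
        col = matrix[var].to_numpy(dtype=float)
        rec = {"variable": var}
        for g in ("success", "failure"):
            sel = np.isnan(col[grp == g])
            rec[f"pct_missing_{g}"] = 100.0 * sel.mean() if sel.size else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def exclusion_for_delta(attempts: pd.DataFrame, horizon: float = 3.0) -> pd.DataFrame:
    """Restrict to stays still in assisted mode ``horizon`` hours post-attempt.

    Drops stays whose first attempt failed within the horizon and stays
    liberated from invasive ventilation within the horizon.  ``attempts``
    needs columns ``time``, ``failure_time`` (NaN for successes) and
    ``liberation_time`` (end of the invasive interval containing the
    attempt; NaN if unknown).
    """
    t = attempts["time"].to_numpy(dtype=float)
    fail = attempts["failure_time"].to_numpy(dtype=float)
    failed_early = ~np.isnan(fail) & (fail <= t + horizon + _EPS)
    if "liberation_time" in attempts.columns:
        lib = attempts["liberation_time"].to_numpy(dtype=float)
        liberated_early = ~np.isnan(lib) & (lib <= t + horizon + _EPS)
    else:
        liberated_early = np.zeros_like(failed_early)
    return attempts[~(failed_early | liberated_early)].reset_index(drop=True)
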