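"""Clinical endpoints: 28-day mortality, VFD-28, MV duration, ICU length of stay.

Ventilator-free days by day 28 (VFD-28) use the convention: 0 if the
patient dies before day 28 or is still invasively ventilated at day 28,
otherwise 28 minus the number of days spent on invasive ventilation up to
day 28 (re-intubation gaps count as free days), floored at 0.  The 28-day
clock is anchored at ICU admission (time 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass
class EndpointSet:
    stay_id: object
    mort28: bool
    vfd28: float  # days in [0, 28]
    mv_days: float
    icu_los_days: float


def _union_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    ivs = sorted((float(a), float(b)) for a, b in intervals if b > a)
    out: list[tuple[float, float]] = []
    for a, b in ivs:
        if out and a <= out[-1][1] + _EPS:
            if a < out[-1][1] - _EPS:
                logger.warning("overlapping invasive intervals normalized by union")
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def compute_endpoints(
    stay_id: object,
    invasive_intervals: list[tuple[float, float]],
    death_time: float | None,
    discharge_time: float,
    horizon_days: float = 28.0,
) -> EndpointSet:
    """Endpoint set for one stay; all event times in hours since ICU admission."""
    ivs = _union_intervals(invasive_intervals)
    horizon_h = horizon_days * 24.0
    mort = death_time is not None and not np.isnan(death_time) and death_time <= horizon_h + _EPS

    mv_hours = sum(b - a for a, b in ivs)
    vent_h_to_28 = sum(max(0.0, min(b, horizon_h) - a) for a, b in ivs if a < horizon_h)
    ventilated_at_28 = any(a - _EPS <= horizon_h < b + _EPS for a, b in ivs)

    if mort or ventilated_at_28:
        vfd = 0.0
    else:
        vfd = max(0.0, horizon_days - vent_h_to_28 / 24.0)

    end = discharge_time
    if death_time is not None and not np.isnan(death_time):
        end = min(end, death_time)
    return EndpointSet(
        stay_id=stay_id,
        mort28=bool(mort),
        vfd28=float(vfd),
        mv_days=float(mv_hours / 24.0),
        icu_los_days=float(end / 24.0),
    )


def endpoints_frame(endpoint_sets: list[EndpointSet]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stay_id": [e.stay_id for e in endpoint_sets],
            "mort28": [e.mort28 for e in endpoint_sets],
            "vfd28": [e.vfd28 for e in endpoint_sets],
            "mv_days": [e.mv_days for e in endpoint_sets],
            "icu_los_days": [e.icu_los_days for e in endpoint_sets],
        }
    )


def assisted_survival_curve(time_to_failure: np.ndarray | list[float]) -> pd.DataFrame:
    """Fraction of failed attempts still in assisted mode at each follow-up time.

    A non-increasing step function starting at 1 at t = 0; the time at which
    it first reaches ≤ 0.5 is the median time to failure.  Input is the
    time-to-failure (hours) of every failed first attempt; no censoring is
    involved since every failure has an observed failure time.
    """
    ttf = np.asarray(time_to_failure, dtype=float)
    if ttf.size == 0:
        raise ValueError("assisted_survival_curve requires at least one failed attempt")
    times = np.unique(ttf)
    frac = [(ttf > t).mean() for t in times]
    return pd.DataFrame({"time": np.concatenate([[0.0], times]), "fraction": [1.0] + frac})


def curve_median(curve: pd.DataFrame) -> float:
    """First follow-up time at which the still-assisted fraction drops to ≤ 0.5."""
    below = curve[curve["fraction"] <= 0.5 + _EPS]
    return float(below["time"].iloc[0])


def split_early_late(time_to_failure: np.ndarray | list[float]) -> tuple[np.ndarray, float]:
    """Split failures at the median time to failure.

    Returns a boolean array (True = early, ttf ≤ median) and the median.
    With all values identical everything is "early".
    """
    ttf = np.asarray(time_to_failure, dtype=float)
    med = float(np.median(ttf))
    return ttf <= med + _EPS, med
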