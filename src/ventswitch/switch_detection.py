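"""Eligibility screening, switch-attempt detection and 72-h outcome labeling.

A *switch attempt* is a transition from controlled to assisted ventilation
that survives the persistence filter (the patient stays in assisted mode for
at least one hour).  The attempt is *successful* if the patient does not
return to controlled ventilation for the next 72 h while alive, and *failed*
otherwise — failure is triggered either by a (persistent) return to
controlled mode or by death within the horizon, whichever comes first.

Only the first attempt of a stay receives an outcome label; later attempts
are counted as secondary attempts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .mode_timeline import ASSISTED, CONTROLLED, ModeTimeline, PROV_COMBINED, PROV_COMBINED_FALLBACK

logger = logging.getLogger(__name__)

SUCCESS = "success"
FAILURE = "failure"

CAUSE_RETURN = "return_to_controlled"
CAUSE_DEATH = "death"
CAUSE_NONE = "none"

MODE_CHANGE = "mode_change"
RR_CHANGE = "rr_change"

_EPS = 1e-9

#: ineligibility reasons
R_NO_HYPOXEMIA = "no_hypoxemia_48h"
R_MV_SHORT = "mv_under_48h"
R_NOT_CONTROLLED = "not_starting_controlled"
R_NOT_FIRST = "not_first_stay"


class DataConsistencyError(ValueError):
    """Raised when recorded events contradict each other (e.g. death before attempt)."""


@dataclass
class SwitchAttempt:
    stay_id: object
    attempt_index: int  # 1-based
    time: float  # hours since ICU admission
    attempt_type: str  # mode_change | rr_change
    outcome: str | None = None
    failure_cause: str = CAUSE_NONE
    failure_time: float | None = None

    @property
    def time_to_failure(self) -> float | None:
        if self.failure_time is None:
            return None
        return self.failure_time - self.time


@dataclass
class EligibilityResult:
    stay_id: object
    reasons: list[str]

    @property
    def eligible(self) -> bool:
        return not self.reasons


def check_eligibility(
    stay: pd.Series | dict,
    timeline: ModeTimeline,
    pf_series: pd.DataFrame | None,
    pf_threshold: float = 300.0,
    pf_window: float = 48.0,
    min_mv_hours: float = 48.0,
) -> EligibilityResult:
    """Screen one stay against the cohort inclusion criteria.

    Eligible stays (1) have hypoxemic respiratory failure — at least one
    PaO2/FiO2 below ``pf_threshold`` mmHg within ``pf_window`` hours of
    intubation, (2) received invasive ventilation for at least
    ``min_mv_hours`` in total, (3) started invasive ventilation in a
    controlled mode, and (4) are the first ICU stay of the hospitalization.
    """
    if not timeline.invasive_intervals:
        raise DataConsistencyError(f"stay {timeline.stay_id!r}: no intubation recorded")
    reasons: list[str] = []

    intubation = timeline.invasive_intervals[0][0]
    hypoxemic = False
    if pf_series is not None and len(pf_series):
        sel = pf_series[
            (pf_series["time"] >= intubation - _EPS)
            & (pf_series["time"] <= intubation + pf_window + _EPS)
        ]
        hypoxemic = bool((sel["value"] < pf_threshold).any())
    if not hypoxemic:
        reasons.append(R_NO_HYPOXEMIA)

    total_mv = sum(b - a for a, b in timeline.invasive_intervals)
    if total_mv < min_mv_hours - _EPS:
        reasons.append(R_MV_SHORT)

    first = next(iter(timeline.invasive_segments()), None)
    if first is None or first.category != CONTROLLED:
        reasons.append(R_NOT_CONTROLLED)

    first_stay = stay.get("first_stay", True) if isinstance(stay, dict) else stay.get("first_stay", True)
    if not bool(first_stay):
        reasons.append(R_NOT_FIRST)

    return EligibilityResult(stay_id=timeline.stay_id, reasons=reasons)


def detect_attempts(timeline: ModeTimeline) -> list[SwitchAttempt]:
    """Find every controlled→assisted boundary on a persistence-filtered timeline.

    A boundary produced purely by combined-mode reassignment (the assisted
    segment's provenance) is typed ``rr_change`` — the switch was observed
    as a change in spontaneous respiratory rate during a combined mode
    rather than as an actual mode change.  Returns an empty list for stays
    that never leave controlled mode (the "no switch" group).
    """
    attempts: list[SwitchAttempt] = []
    segs = timeline.invasive_segments()
    for prev, cur in zip(segs[:-1], segs[1:]):
        if prev.category == CONTROLLED and cur.category == ASSISTED and abs(prev.end - cur.start) <= _EPS:
            a_type = RR_CHANGE if cur.provenance in (PROV_COMBINED, PROV_COMBINED_FALLBACK) else MODE_CHANGE
            attempts.append(
                SwitchAttempt(
                    stay_id=timeline.stay_id,
                    attempt_index=len(attempts) + 1,
                    time=cur.start,
                    attempt_type=a_type,
                )
            )
    return attempts


def label_attempt(
    attempt: SwitchAttempt,
    timeline: ModeTimeline,
    death_time: float | None,
    horizon: float = 72.0,
) -> SwitchAttempt:
    """Apply the 72-h success/failure definition to one attempt.

    Failure cause is the earliest qualifying event in ``(time, time + horizon]``:
    a controlled segment beginning in the window (a persistent return), or
    death.  Events at exactly ``time + horizon`` count as inside the window.
    If the stay ends alive before the horizon with no return, the attempt is
    a success ("did not return … while alive").
    """
    t0 = attempt.time
    if death_time is not None and death_time < t0 - _EPS:
        raise DataConsistencyError(
            f"stay {attempt.stay_id!r}: death at {death_time} precedes attempt at {t0}"
        )
    return_time = None
    for seg in timeline.invasive_segments():
        if seg.category == CONTROLLED and t0 + _EPS < seg.start <= t0 + horizon + _EPS:
            return_time = seg.start
            break
    death_in = (
        death_time is not None and t0 + _EPS < death_time <= t0 + horizon + _EPS
    )
    if return_time is not None and (not death_in or return_time <= death_time):
        return replace(attempt, outcome=FAILURE, failure_cause=CAUSE_RETURN, failure_time=return_time)
    if death_in:
        return replace(attempt, outcome=FAILURE, failure_cause=CAUSE_DEATH, failure_time=death_time)
    return replace(attempt, outcome=SUCCESS, failure_cause=CAUSE_NONE, failure_time=None)


def detect_and_label(
    timeline: ModeTimeline, death_time: float | None, horizon: float = 72.0
) -> list[SwitchAttempt]:
    """Detect all attempts and label the first one; later attempts stay unlabeled."""
    attempts = detect_attempts(timeline)
    if attempts:
        attempts[0] = label_attempt(attempts[0], timeline, death_time, horizon=horizon)
    return attempts


def summarize_attempts(attempts: list[SwitchAttempt]) -> tuple[float | None, int]:
    """Per-stay attempt summary: (time to first attempt in days, # secondary attempts)."""
    if not attempts:
        return None, 0
    return attempts[0].time / 24.0, len(attempts) - 1


def attempts_to_frame(attempts: list[SwitchAttempt]) -> pd.DataFrame:
    """Flatten attempts (possibly from many stays) into a tidy table."""
    return pd.DataFrame(
        {
            "stay_id": [a.stay_id for a in attempts],
            "attempt_index": [a.attempt_index for a in attempts],
            "time": [a.time for a in attempts],
            "attempt_type": [a.attempt_type for a in attempts],
            "outcome": [a.outcome for a in attempts],
            "failure_cause": [a.failure_cause for a in attempts],
            "failure_time": [a.failure_time for a in attempts],
            "time_to_failure": [a.time_to_failure for a in attempts],
        }
    )
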