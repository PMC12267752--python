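"""Harmonization of raw ventilator-mode logs into functional-category timelines.

Ventilators log a zoo of vendor- and hospital-specific mode labels.  For the
purpose of studying the transition from controlled to assisted ventilation,
all that matters is the *functional* category of each mode:

* ``CONTROLLED`` — no patient-triggered breaths; the ventilator delivers all
  breaths (e.g. PC-CMV, VC-CMV, PRVC, APRV).
* ``COMBINED`` — assist-control modes allowing patient-triggered breaths
  besides mandatory breaths (e.g. SIMV).  Combined modes are ambiguous with
  respect to patient effort and are reassigned to controlled or assisted
  using the nearest spontaneous respiratory rate (> 10 breaths/min implies
  active effort, hence assisted).
* ``ASSISTED`` — only patient-triggered breaths (e.g. pressure support).
* ``CPAP`` — continuous positive airway pressure; counted as assisted when
  delivered through an invasive airway, otherwise as non-invasive.
* ``NONINVASIVE_OR_NONE`` — everything outside invasive ventilation.

The pipeline is: :func:`build_timeline` (carry each logged mode forward to
the next log or extubation), :func:`reassign_combined`,
:func:`reassign_cpap`, and :func:`persistence_filter` (a mode change counts
only if the new mode persists for at least one hour, filtering out abrupt
transient changes such as those around procedures).

Times are real-valued hours since ICU admission; all intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

# Functional ventilation categories
CONTROLLED = "controlled"
COMBINED = "combined"
ASSISTED = "assisted"
CPAP = "cpap"
NONINVASIVE_OR_NONE = "noninvasive_or_none"

CATEGORIES = frozenset({CONTROLLED, COMBINED, ASSISTED, CPAP, NONINVASIVE_OR_NONE})

#: categories that can occur inside an invasive-ventilation interval after
#: combined/CPAP reassignment
INVASIVE_CATEGORIES = frozenset({CONTROLLED, ASSISTED})

# Segment provenance markers
PROV_LOGGED = "logged"
PROV_COMBINED = "combined_reassigned"
PROV_COMBINED_FALLBACK = "combined_reassigned_fallback"
PROV_CPAP = "cpap_reassigned"
PROV_MERGED = "persistence_merged"

_EPS = 1e-9


class UnknownModeLabel(KeyError):
    """Raised in strict mode when a raw mode label is not in the dialect."""


class MissingModeData(ValueError):
    """Raised when an invasive interval contains no mode record at all."""


@dataclass(frozen=True)
class ModeDialect:
    """A total mapping from one center's raw mode labels to categories."""

    name: str
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.mapping.values() if c not in CATEGORIES}
        if bad:
            raise ValueError(f"dialect {self.name!r} maps to unknown categories {sorted(bad)}")

    def labels_for(self, category: str) -> list[str]:
        return sorted(lbl for lbl, cat in self.mapping.items() if cat == category)

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "ModeDialect":
        # keep_default_na: raw labels like "None" are real mode labels
        df = pd.read_csv(path, keep_default_na=False)
        return cls(name or str(path), dict(zip(df["raw_label"].astype(str), df["category"])))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"raw_label": list(self.mapping), "category": list(self.mapping.values())}
        ).to_csv(path, index=False)


def map_raw_mode(raw_label: str, dialect: ModeDialect, strict: bool = True) -> str:
    """Map one raw mode label to its functional category.

    In lenient mode unknown labels fall back to ``NONINVASIVE_OR_NONE`` with
    a logged warning; in strict mode they raise :class:`UnknownModeLabel`.
    """
    try:
        return dialect.mapping[raw_label]
    except KeyError:
        if strict:
            raise UnknownModeLabel(f"label {raw_label!r} not in dialect {dialect.name!r}") from None
        logger.warning("unknown mode label %r (dialect %s); treating as non-invasive", raw_label, dialect.name)
        return NONINVASIVE_OR_NONE


@dataclass
class ModeSegment:
    start: float
    end: float
    category: str
    provenance: str = PROV_LOGGED

    @property
    def duration(self) -> float:
        return self.end - self.start

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"segment start {self.start} must precede end {self.end}")


@dataclass
class ModeTimeline:
    """Ordered, contiguous functional-category segments for one ICU stay."""

    stay_id: object
    segments: list[ModeSegment]
    invasive_intervals: list[tuple[float, float]]

    def categories(self) -> list[str]:
        return [s.category for s in self.segments]

    def total_time(self) -> float:
        return sum(s.duration for s in self.segments)

    def invasive_segments(self) -> list[ModeSegment]:
        out = []
        for s in self.segments:
            if any(a - _EPS <= s.start and s.end <= b + _EPS for a, b in self.invasive_intervals):
                out.append(s)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stay_id": self.stay_id,
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "category": [s.category for s in self.segments],
                "provenance": [s.provenance for s in self.segments],
            }
        )


def invasive_intervals_from_events(airway_events: pd.DataFrame, stay_end: float) -> list[tuple[float, float]]:
    """Pair intubation/extubation events into half-open invasive intervals.

    An intubation without a matching extubation is closed at ``stay_end``
    (death or ICU discharge while ventilated).
    """
    ev = airway_events.sort_values("time")
    intervals: list[tuple[float, float]] = []
    open_start: float | None = None
    for _, row in ev.iterrows():
        if row["event"] == "intubation":
            if open_start is None:
                open_start = float(row["time"])
        elif row["event"] == "extubation":
            if open_start is not None:
                if float(row["time"]) > open_start:
                    intervals.append((open_start, float(row["time"])))
                open_start = None
    if open_start is not None and stay_end > open_start:
        intervals.append((open_start, float(stay_end)))
    return intervals


def build_timeline(
    records: pd.DataFrame,
    airway_events: pd.DataFrame,
    dialect: ModeDialect,
    stay_end: float,
    strict: bool = True,
) -> ModeTimeline:
    """Carry logged modes forward into a contiguous category timeline.

    Each logged mode extends until the next log, extubation, or stay end.
    Within an invasive interval the first record's category is extended back
    to the interval start (the charted mode at intubation is normally logged
    within minutes of the event).  Time outside invasive intervals is
    ``NONINVASIVE_OR_NONE``.

    Raises
    ------
    MissingModeData
        if an invasive interval contains no mode record.
    """
    stay_id = records["stay_id"].iloc[0] if len(records) else airway_events["stay_id"].iloc[0]
    intervals = invasive_intervals_from_events(airway_events, stay_end)
    if not intervals:
        raise MissingModeData(f"stay {stay_id!r}: no intubation event")

    recs = records.sort_values("time", kind="stable")
    times = recs["time"].to_numpy(dtype=float)
    cats = [map_raw_mode(lbl, dialect, strict=strict) for lbl in recs["raw_label"]]

    segments: list[ModeSegment] = []
    cursor = 0.0

    def push(start: float, end: float, category: str, provenance: str = PROV_LOGGED) -> None:
        if end - start <= _EPS:
            return
        # adjacent COMBINED records stay separate: each logged combined
        # record is reassigned on its own nearest spontaneous rate, so a
        # true transition between two combined logs remains recoverable
        if (
            segments
            and category != COMBINED
            and segments[-1].category == category
            and segments[-1].provenance == provenance
        ):
            segments[-1].end = end
        else:
            segments.append(ModeSegment(start, end, category, provenance))

    for a, b in intervals:
        if a > cursor + _EPS:
            push(cursor, a, NONINVASIVE_OR_NONE)
        inside = [(t, c) for t, c in zip(times, cats) if a - _EPS <= t < b]
        if not inside:
            raise MissingModeData(f"stay {stay_id!r}: no mode record in invasive interval [{a}, {b})")
        for i, (t, c) in enumerate(inside):
            seg_start = a if i == 0 else max(t, a)
            seg_end = inside[i + 1][0] if i + 1 < len(inside) else b
            push(seg_start, seg_end, c)
        cursor = b
    if stay_end > cursor + _EPS:
        push(cursor, stay_end, NONINVASIVE_OR_NONE)

    return ModeTimeline(stay_id=stay_id, segments=segments, invasive_intervals=intervals)


def _nearest_value(times, values, at: float, tolerance: float) -> float | None:
    """Value whose timestamp is nearest to ``at`` within ``tolerance``.

    Ties (equidistant before/after) resolve to the earlier measurement.
    """
    best_d, best_v = None, None
    for t, v in zip(times, values):
        d = abs(t - at)
        if d <= tolerance + _EPS and (best_d is None or d < best_d - _EPS):
            best_d, best_v = d, v
    return best_v


def reassign_combined(
    timeline: ModeTimeline,
    spont_rr: pd.DataFrame | None,
    rr_threshold: float = 10.0,
    tolerance: float = 1.0,
) -> ModeTimeline:
    """Resolve combined (assist-control) segments by spontaneous effort.

    A combined segment becomes ``ASSISTED`` if the spontaneous respiratory
    rate nearest in time to the segment start (within ``tolerance`` hours)
    is strictly greater than ``rr_threshold`` breaths/min, else
    ``CONTROLLED``.  When no spontaneous rate is available within tolerance
    the segment is conservatively classified ``CONTROLLED`` (no attempt is
    fabricated) and flagged in provenance.

    Segment boundaries are never changed by this step.
    """
    if spont_rr is not None and len(spont_rr):
        rr = spont_rr.sort_values("time")
        rr_t = rr["time"].to_numpy(dtype=float)
        rr_v = rr["value"].to_numpy(dtype=float)
    else:
        rr_t, rr_v = [], []

    new_segments = []
    for seg in timeline.segments:
        if seg.category != COMBINED:
            new_segments.append(replace(seg))
            continue
        v = _nearest_value(rr_t, rr_v, seg.start, tolerance)
        if v is None:
            new_segments.append(replace(seg, category=CONTROLLED, provenance=PROV_COMBINED_FALLBACK))
        elif v > rr_threshold:
            new_segments.append(replace(seg, category=ASSISTED, provenance=PROV_COMBINED))
        else:
            new_segments.append(replace(seg, category=CONTROLLED, provenance=PROV_COMBINED))
    return ModeTimeline(timeline.stay_id, new_segments, list(timeline.invasive_intervals))


def reassign_cpap(timeline: ModeTimeline) -> ModeTimeline:
    """Reassign CPAP: assisted while invasively ventilated, non-invasive otherwise.

    A CPAP segment straddling an extubation is split at the boundary and each
    part reassigned per its side; this is the only reassignment that can
    change segment boundaries.
    """
    cuts = sorted({x for a, b in timeline.invasive_intervals for x in (a, b)})
    new_segments: list[ModeSegment] = []
    for seg in timeline.segments:
        if seg.category != CPAP:
            new_segments.append(replace(seg))
            continue
        points = [seg.start] + [c for c in cuts if seg.start < c < seg.end] + [seg.end]
        for a, b in zip(points[:-1], points[1:]):
            mid = (a + b) / 2
            invasive = any(lo - _EPS <= mid < hi + _EPS for lo, hi in timeline.invasive_intervals)
            cat = ASSISTED if invasive else NONINVASIVE_OR_NONE
            new_segments.append(ModeSegment(a, b, cat, PROV_CPAP))
    return ModeTimeline(timeline.stay_id, new_segments, list(timeline.invasive_intervals))


def _coalesce(segments: list[ModeSegment]) -> list[ModeSegment]:
    out: list[ModeSegment] = []
    for seg in segments:
        if out and out[-1].category == seg.category and abs(out[-1].end - seg.start) <= _EPS:
            out[-1] = replace(out[-1], end=seg.end)
        else:
            out.append(replace(seg))
    return out


def persistence_filter(timeline: ModeTimeline, min_duration: float = 1.0) -> ModeTimeline:
    """Drop mode transitions that do not persist for ``min_duration`` hours.

    Within each invasive interval, segments are scanned left to right: a run
    of a *new* category shorter than ``min_duration`` is absorbed into the
    preceding category (and the scan re-checks the following run against the
    extended segment).  The initial mode of an interval is never absorbed —
    only transitions into a new mode are filtered.  A run of exactly
    ``min_duration`` survives ("at least 1 h" is inclusive).

    The filter is idempotent and never changes total covered time.
    """
    new_segments: list[ModeSegment] = []
    for a, b in sorted(timeline.invasive_intervals):
        inside = [s for s in timeline.segments if a - _EPS <= s.start and s.end <= b + _EPS]
        stack: list[ModeSegment] = []
        for seg in _coalesce(inside):
            if stack and stack[-1].category == seg.category:
                stack[-1] = replace(stack[-1], end=seg.end)
            elif stack and seg.duration < min_duration - _EPS:
                # keep reassignment provenance on the absorbing segment: the
                # origin of its *start* boundary is what downstream attempt
                # typing needs
                prov = PROV_MERGED if stack[-1].provenance == PROV_LOGGED else stack[-1].provenance
                stack[-1] = replace(stack[-1], end=seg.end, provenance=prov)
            else:
                stack.append(replace(seg))
        new_segments.extend(stack)
    outside = [
        replace(s)
        for s in timeline.segments
        if not any(a - _EPS <= s.start and s.end <= b + _EPS for a, b in timeline.invasive_intervals)
    ]
    merged = sorted(new_segments + outside, key=lambda s: s.start)
    return ModeTimeline(timeline.stay_id, merged, list(timeline.invasive_intervals))


def harmonize(
    records: pd.DataFrame,
    airway_events: pd.DataFrame,
    dialect: ModeDialect,
    stay_end: float,
    spont_rr: pd.DataFrame | None = None,
    rr_threshold: float = 10.0,
    nearest_tolerance: float = 1.0,
    min_persistence: float = 1.0,
    strict: bool = True,
) -> ModeTimeline:
    """Full harmonization chain for one stay: build → combined → CPAP → persistence."""
    tl = build_timeline(records, airway_events, dialect, stay_end, strict=strict)
    tl = reassign_combined(tl, spont_rr, rr_threshold=rr_threshold, tolerance=nearest_tolerance)
    tl = reassign_cpap(tl)
    return persistence_filter(tl, min_duration=min_persistence)
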