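import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import persistence_oracle
from ventswitch.mode_timeline import (
    ASSISTED,
    COMBINED,
    CONTROLLED,
    CPAP,
    NONINVASIVE_OR_NONE,
    MissingModeData,
    ModeDialect,
    ModeSegment,
    ModeTimeline,
    UnknownModeLabel,
    build_timeline,
    map_raw_mode,
    persistence_filter,
    reassign_combined,
    reassign_cpap,
)

DIALECT = ModeDialect(
    "test",
    {
        "CMV": CONTROLLED,
        "PS": ASSISTED,
        "SIMV": COMBINED,
        "CPAP": CPAP,
        "None": NONINVASIVE_OR_NONE,
    },
)


def _records(stay_id, pairs):
    return pd.DataFrame({"stay_id": stay_id, "time": [t for t, _ in pairs], "raw_label": [l for _, l in pairs]})


def _airway(stay_id, pairs):
    return pd.DataFrame({"stay_id": stay_id, "time": [t for t, _ in pairs], "event": [e for _, e in pairs]})


def _timeline(segments, invasive):
    return ModeTimeline(stay_id=1, segments=[ModeSegment(*s) for s in segments], invasive_intervals=invasive)


class TestMapRawMode:
    @pytest.mark.parametrize(
        "label,expected",
        [("CMV", CONTROLLED), ("PS", ASSISTED), ("SIMV", COMBINED), ("CPAP", CPAP)],
    )
    def test_lookup(self, label, expected):
        assert map_raw_mode(label, DIALECT) == expected

    def test_unknown_strict_raises(self):
        with pytest.raises(UnknownModeLabel):
            map_raw_mode("NOVEL-MODE", DIALECT, strict=True)

    def test_unknown_lenient_falls_back(self):
        assert map_raw_mode("NOVEL-MODE", DIALECT, strict=False) == NONINVASIVE_OR_NONE

    def test_dialect_rejects_bad_category(self):
        with pytest.raises(ValueError):
            ModeDialect("bad", {"X": "warp-drive"})

    def test_dialect_csv_roundtrip(self, tmp_path):
        path = tmp_path / "dialect.csv"
        DIALECT.to_csv(path)
        back = ModeDialect.from_csv(path, name="test")
        assert back.mapping == DIALECT.mapping


class TestBuildTimeline:
    def test_carry_forward(self):
        tl = build_timeline(
            _records(1, [(0.0, "CMV"), (30.0, "PS")]),
            _airway(1, [(0.0, "intubation"), (45.0, "extubation")]),
            DIALECT,
            stay_end=45.0,
        )
        cats = [(s.start, s.end, s.category) for s in tl.segments]
        assert cats == [(0.0, 30.0, CONTROLLED), (30.0, 45.0, ASSISTED)]

    def test_single_log_spans_interval(self):
        tl = build_timeline(
            _records(1, [(0.0, "CMV")]),
            _airway(1, [(0.0, "intubation"), (48.0, "extubation")]),
            DIALECT,
            stay_end=48.0,
        )
        assert len(tl.segments) == 1
        assert (tl.segments[0].start, tl.segments[0].end) == (0.0, 48.0)

    def test_no_logs_raises(self):
        with pytest.raises(MissingModeData):
            build_timeline(
                _records(1, []).astype({"time": float}),
                _airway(1, [(0.0, "intubation"), (48.0, "extubation")]),
                DIALECT,
                stay_end=48.0,
            )

    def test_time_after_extubation_is_noninvasive(self):
        tl = build_timeline(
            _records(1, [(0.0, "CMV")]),
            _airway(1, [(0.0, "intubation"), (40.0, "extubation")]),
            DIALECT,
            stay_end=60.0,
        )
        assert tl.segments[-1].category == NONINVASIVE_OR_NONE
        assert (tl.segments[-1].start, tl.segments[-1].end) == (40.0, 60.0)

    def test_adjacent_combined_records_stay_separate(self):
        # each combined log keeps its own segment so per-record reassignment
        # can recover a transition hidden between two combined logs
        tl = build_timeline(
            _records(1, [(0.0, "CMV"), (10.0, "SIMV"), (11.0, "SIMV")]),
            _airway(1, [(0.0, "intubation"), (20.0, "extubation")]),
            DIALECT,
            stay_end=20.0,
        )
        combined = [s for s in tl.segments if s.category == COMBINED]
        assert len(combined) == 2


class TestReassignCombined:
    def _tl(self):
        return _timeline(
            [(0.0, 10.0, CONTROLLED), (10.0, 15.0, COMBINED), (15.0, 20.0, CONTROLLED)],
            [(0.0, 20.0)],
        )

    def _rr(self, pairs):
        return pd.DataFrame({"time": [t for t, _ in pairs], "value": [v for _, v in pairs]})

    def test_high_rate_becomes_assisted(self):
        out = reassign_combined(self._tl(), self._rr([(10.0, 14.0)]))
        assert out.segments[1].category == ASSISTED

    def test_rate_of_exactly_ten_becomes_controlled(self):
        # the rule is strictly "higher than ten breaths per minute"
        out = reassign_combined(self._tl(), self._rr([(10.0, 10.0)]))
        assert out.segments[1].category == CONTROLLED

    def test_no_rate_within_tolerance_falls_back_controlled(self):
        out = reassign_combined(self._tl(), self._rr([(5.0, 22.0)]), tolerance=1.0)
        assert out.segments[1].category == CONTROLLED
        assert "fallback" in out.segments[1].provenance

    def test_nearest_rate_to_segment_start_wins(self):
        out = reassign_combined(self._tl(), self._rr([(9.9, 22.0), (10.8, 2.0)]))
        assert out.segments[1].category == ASSISTED

    def test_boundaries_unchanged(self):
        tl = self._tl()
        out = reassign_combined(tl, self._rr([(10.0, 14.0)]))
        assert [(s.start, s.end) for s in out.segments] == [(s.start, s.end) for s in tl.segments]


class TestReassignCpap:
    def test_cpap_inside_invasive_is_assisted(self):
        tl = _timeline([(0.0, 20.0, CONTROLLED), (20.0, 25.0, CPAP)], [(0.0, 48.0)])
        out = reassign_cpap(tl)
        assert out.segments[1].category == ASSISTED

    def test_cpap_after_extubation_is_noninvasive(self):
        tl = _timeline([(0.0, 40.0, CONTROLLED), (50.0, 55.0, CPAP)], [(0.0, 48.0)])
        out = reassign_cpap(tl)
        assert out.segments[1].category == NONINVASIVE_OR_NONE

    def test_straddling_cpap_split_at_extubation(self):
        tl = _timeline([(0.0, 44.0, CONTROLLED), (44.0, 52.0, CPAP)], [(0.0, 48.0)])
        out = reassign_cpap(tl)
        parts = [(s.start, s.end, s.category) for s in out.segments[1:]]
        assert parts == [(44.0, 48.0, ASSISTED), (48.0, 52.0, NONINVASIVE_OR_NONE)]


class TestPersistenceFilter:
    def test_short_blip_removed(self):
        tl = _timeline(
            [(0.0, 10.0, CONTROLLED), (10.0, 10.5, ASSISTED), (10.5, 20.0, CONTROLLED)],
            [(0.0, 20.0)],
        )
        out = persistence_filter(tl)
        assert [(s.start, s.end, s.category) for s in out.segments] == [(0.0, 20.0, CONTROLLED)]

    def test_exactly_one_hour_retained(self):
        tl = _timeline(
            [(0.0, 10.0, CONTROLLED), (10.0, 11.0, ASSISTED), (11.0, 20.0, CONTROLLED)],
            [(0.0, 20.0)],
        )
        out = persistence_filter(tl)
        assert [s.category for s in out.segments] == [CONTROLLED, ASSISTED, CONTROLLED]

    def test_initial_short_segment_survives(self):
        # the first mode of an interval is not a transition and is never absorbed
        tl = _timeline([(0.0, 0.5, CONTROLLED), (0.5, 20.0, ASSISTED)], [(0.0, 20.0)])
        out = persistence_filter(tl)
        assert [s.category for s in out.segments] == [CONTROLLED, ASSISTED]

    def test_total_time_conserved(self):
        tl = _timeline(
            [(0.0, 5.0, CONTROLLED), (5.0, 5.4, ASSISTED), (5.4, 6.0, CONTROLLED), (6.0, 9.0, ASSISTED)],
            [(0.0, 9.0)],
        )
        out = persistence_filter(tl)
        assert out.total_time() == pytest.approx(tl.total_time())

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        durations=st.lists(st.floats(0.1, 3.0), min_size=1, max_size=12),
        start_assisted=st.booleans(),
        flips=st.lists(st.booleans(), min_size=0, max_size=12),
    )
    def test_matches_brute_force_oracle(self, durations, start_assisted, flips):
        cats, cur = [], ASSISTED if start_assisted else CONTROLLED
        for i in range(len(durations)):
            cats.append(cur)
            if i < len(flips) and flips[i]:
                cur = ASSISTED if cur == CONTROLLED else CONTROLLED
        t, segs = 0.0, []
        for d, c in zip(durations, cats):
            segs.append((t, t + d, c))
            t += d
        tl = _timeline(segs, [(0.0, t)])
        out = persistence_filter(tl, min_duration=1.0)
        expected = persistence_oracle(segs, 1.0)
        got = [(s.start, s.end, s.category) for s in out.segments]
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g[0] == pytest.approx(e[0])
            assert g[1] == pytest.approx(e[1])
            assert g[2] == e[2]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        durations=st.lists(st.floats(0.1, 3.0), min_size=1, max_size=10),
        flips=st.lists(st.booleans(), min_size=0, max_size=10),
    )
    def test_idempotent(self, durations, flips):
        cats, cur = [], CONTROLLED
        for i in range(len(durations)):
            cats.append(cur)
            if i < len(flips) and flips[i]:
                cur = ASSISTED if cur == CONTROLLED else CONTROLLED
        t, segs = 0.0, []
        for d, c in zip(durations, cats):
            segs.append((t, t + d, c))
            t += d
        tl = _timeline(segs, [(0.0, t)])
        once = persistence_filter(tl)
        twice = persistence_filter(once)
        assert [(s.start, s.end, s.category) for s in once.segments] == [
            (s.start, s.end, s.category) for s in twice.segments
        ]
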