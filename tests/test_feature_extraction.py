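import numpy as np
import pandas as pd
import pytest

from ventswitch.feature_extraction import (
    delta_sample,
    derive_crs,
    derive_dp,
    derive_pf,
    exclusion_for_delta,
    extract_deltas,
    extract_features,
    locf_sample,
    missingness_report,
    normalize_fio2,
    post_sample,
    select_variables,
)


def _series(pairs, stay_id=None):
    df = pd.DataFrame({"time": [t for t, _ in pairs], "value": [v for _, v in pairs]})
    if stay_id is not None:
        df.insert(0, "stay_id", stay_id)
    return df


class TestDerivedParameters:
    def test_pf_arithmetic(self):
        out = derive_pf(_series([(10.0, 100.0)], 1), _series([(9.5, 40.0)], 1))
        assert len(out) == 1
        assert out["value"].iloc[0] == pytest.approx(250.0)

    def test_pf_partner_beyond_tolerance_dropped(self):
        out = derive_pf(_series([(10.0, 100.0)], 1), _series([(8.0, 40.0)], 1))
        assert len(out) == 0

    def test_pf_simultaneous_partner_counts_as_prior(self):
        out = derive_pf(_series([(10.0, 90.0)], 1), _series([(10.0, 30.0)], 1))
        assert out["value"].iloc[0] == pytest.approx(300.0)

    def test_pf_future_fio2_never_used(self):
        out = derive_pf(_series([(10.0, 100.0)], 1), _series([(10.2, 40.0)], 1))
        assert len(out) == 0

    def test_fio2_fraction_normalized(self):
        out = normalize_fio2(_series([(0.0, 0.4), (1.0, 40.0)], 1))
        assert list(out["value"]) == [40.0, 40.0]

    def test_dp_arithmetic_and_negative_guard(self):
        pplat = _series([(5.0, 20.0), (8.0, 9.0)], 1)
        peep = _series([(4.8, 10.0), (7.9, 10.0)], 1)
        out = derive_dp(pplat, peep)
        assert len(out) == 1  # 9 - 10 < 0 dropped
        assert out["value"].iloc[0] == pytest.approx(10.0)

    def test_dp_zero_peep(self):
        out = derive_dp(_series([(5.0, 11.7)], 1), _series([(5.0, 0.0)], 1))
        assert out["value"].iloc[0] == pytest.approx(11.7)

    def test_crs_arithmetic(self):
        dp = _series([(5.0, 10.0)], 1)
        tv = _series([(4.5, 400.0)], 1)
        out = derive_crs(dp, tv)
        assert out["value"].iloc[0] == pytest.approx(40.0)

    def test_crs_zero_dp_skipped(self):
        out = derive_crs(_series([(5.0, 0.0)], 1), _series([(4.5, 400.0)], 1))
        assert len(out) == 0

    def test_crs_tv_beyond_tolerance_dropped(self):
        out = derive_crs(_series([(5.0, 10.0)], 1), _series([(3.8, 400.0)], 1))
        assert len(out) == 0

    def test_no_silent_extrapolation(self):
        """Derived points require a partner within tolerance, never farther."""
        rng = np.random.default_rng(1)
        pao2 = _series([(float(t), 100.0) for t in rng.uniform(0, 100, 40)], 1)
        fio2 = _series([(float(t), 40.0) for t in rng.uniform(0, 100, 15)], 1)
        out = derive_pf(pao2, fio2, tolerance=1.0)
        f_times = np.sort(fio2["time"].to_numpy())
        for t in out["time"]:
            prior = f_times[f_times <= t + 1e-9]
            assert len(prior) and t - prior[-1] <= 1.0 + 1e-9


class TestWindowedSampling:
    def test_locf_picks_latest_in_window(self):
        s = _series([(10.0, 1.0), (21.0, 2.0)])
        assert locf_sample(s, anchor=23.0, window=12.0) == (2.0, 21.0)

    def test_locf_outside_window_missing(self):
        s = _series([(10.0, 1.0)])
        assert locf_sample(s, anchor=23.0, window=12.0) is None

    def test_locf_window_edge_inclusive(self):
        s = _series([(11.0, 5.0)])
        assert locf_sample(s, anchor=23.0, window=12.0) == (5.0, 11.0)

    def test_post_sample_anchor_exclusive(self):
        s = _series([(23.0, 1.0)])
        assert post_sample(s, anchor=23.0, horizon=3.0) is None

    def test_post_sample_horizon_edge_inclusive(self):
        s = _series([(26.0, 9.0)])
        assert post_sample(s, anchor=23.0, horizon=3.0) == (9.0, 26.0)

    def test_delta_arithmetic_and_sign(self):
        s = _series([(22.0, 40.0), (25.5, 42.0)])
        assert delta_sample(s, anchor=23.0) == pytest.approx(2.0)

    def test_delta_missing_when_either_side_absent(self):
        only_pre = _series([(22.0, 40.0)])
        only_post = _series([(25.0, 42.0)])
        assert delta_sample(only_pre, anchor=23.0) is None
        assert delta_sample(only_post, anchor=23.0) is None

    def test_delta_antisymmetry(self):
        """Swapping the pre and post values negates the delta."""
        rng = np.random.default_rng(2)
        for _ in range(30):
            pre_v, post_v = rng.normal(size=2)
            s = _series([(20.0, pre_v), (25.0, post_v)])
            swapped = _series([(20.0, post_v), (25.0, pre_v)])
            d = delta_sample(s, anchor=23.0)
            assert d == pytest.approx(-delta_sample(swapped, anchor=23.0))

    def test_batch_extraction_matches_scalar(self):
        rng = np.random.default_rng(3)
        rows = []
        for sid in range(12):
            for t in np.sort(rng.uniform(0, 60, 25)):
                rows.append({"stay_id": sid, "time": float(t), "variable": "x", "value": float(rng.normal())})
        meas = pd.DataFrame(rows)
        anchors = pd.DataFrame({"stay_id": range(12), "time": rng.uniform(10, 50, 12)})
        feat = extract_features(meas, anchors, ["x"])
        deltas = extract_deltas(meas, anchors, ["x"])
        for sid in range(12):
            anchor = float(anchors.loc[anchors["stay_id"] == sid, "time"].iloc[0])
            s = meas[meas["stay_id"] == sid][["time", "value"]]
            expected = locf_sample(s, anchor)
            got = feat.loc[feat["stay_id"] == sid, "x"].iloc[0]
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected[0])
            exp_d = delta_sample(s, anchor)
            got_d = deltas.loc[deltas["stay_id"] == sid, "delta_x"].iloc[0]
            if exp_d is None:
                assert np.isnan(got_d)
            else:
                assert got_d == pytest.approx(exp_d)


class TestVariableSelection:
    def test_before_stage_keeps_over_one_third_observed(self):
        assert select_variables({"a": 40}, 100, "before") == ["a"]

    def test_before_stage_drops_two_thirds_missing(self):
        # observed for exactly 1/3 means missing for exactly 2/3: excluded
        assert select_variables({"a": 33}, 99, "before") == []

    def test_after_stage_boundary_inclusive(self):
        assert select_variables({"d": 33}, 99, "after") == ["d"]
        assert select_variables({"d": 20}, 100, "after") == []

    def test_unknown_stage_raises(self):
        with pytest.raises(ValueError):
            select_variables({"a": 1}, 10, "during")


class TestMissingness:
    def test_fully_observed_variable(self):
        m = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0]})
        out = missingness_report(m, pd.Series(["success", "success", "failure", "failure"]), ["v"])
        assert out["pct_missing_success"].iloc[0] == 0.0
        assert out["pct_missing_failure"].iloc[0] == 0.0

    def test_mcar_rate_recovered(self):
        rng = np.random.default_rng(4)
        n = 1000
        vals = rng.normal(size=n)
        vals[rng.random(n) < 0.3] = np.nan
        m = pd.DataFrame({"v": vals})
        out = missingness_report(m, pd.Series(np.where(rng.random(n) < 0.5, "success", "failure")), ["v"])
        assert 25.0 <= out["pct_missing_success"].iloc[0] <= 35.0
        assert 25.0 <= out["pct_missing_failure"].iloc[0] <= 35.0

    def test_group_dependent_gap_reproduced(self):
        rng = np.random.default_rng(5)
        n = 2000
        grp = np.where(np.arange(n) < n // 2, "success", "failure")
        vals = rng.normal(size=n)
        vals[(grp == "success") & (rng.random(n) < 0.1)] = np.nan
        vals[(grp == "failure") & (rng.random(n) < 0.4)] = np.nan
        out = missingness_report(pd.DataFrame({"v": vals}), pd.Series(grp), ["v"])
        assert out["pct_missing_success"].iloc[0] == pytest.approx(10.0, abs=3.0)
        assert out["pct_missing_failure"].iloc[0] == pytest.approx(40.0, abs=3.0)


class TestDeltaExclusion:
    def _attempts(self):
        return pd.DataFrame(
            {
                "stay_id": [1, 2, 3, 4],
                "time": [10.0, 10.0, 10.0, 10.0],
                "failure_time": [12.0, np.nan, 18.0, np.nan],
                "liberation_time": [np.nan, 12.5, np.nan, 40.0],
            }
        )

    def test_early_failure_and_early_liberation_excluded(self):
        kept = exclusion_for_delta(self._attempts(), horizon=3.0)
        assert sorted(kept["stay_id"]) == [3, 4]

    def test_late_failure_retained(self):
        kept = exclusion_for_delta(self._attempts(), horizon=3.0)
        assert 3 in set(kept["stay_id"])  # failure at +8 h stays in Δ3h

    def test_retained_set_monotone_in_horizon(self):
        """Shorter Δ horizons retain a superset of longer ones."""
        rng = np.random.default_rng(6)
        att = pd.DataFrame(
            {
                "stay_id": np.arange(200),
                "time": np.zeros(200),
                "failure_time": np.where(rng.random(200) < 0.6, rng.uniform(0.5, 30, 200), np.nan),
                "liberation_time": rng.uniform(1, 50, 200),
            }
        )
        prev = None
        for h in (1.0, 2.0, 3.0, 5.0, 8.0):
            kept = set(exclusion_for_delta(att, horizon=h)["stay_id"])
            if prev is not None:
                assert kept.issubset(prev)
            prev = kept
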