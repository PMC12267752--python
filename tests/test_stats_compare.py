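import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import fisher_oracle, quantile_oracle
from ventswitch.stats_compare import (
    PEEP_STRATA,
    RandomInterceptLogit,
    compare_groups,
    interaction_test,
    peep_stratum,
    simulate_interaction_cohort,
    stratified_summary,
)


def _binary(k, n):
    return np.concatenate([np.ones(k), np.zeros(n - k)])


class TestCompareGroups:
    def test_mortality_contrast_highly_significant(self):
        # 367/2191 vs 1259/4524 deaths: the reported 16% vs 27% mortality gap
        res = compare_groups(_binary(367, 2191), _binary(1259, 4524), "mort28", var_type="binary")
        assert res.test == "chi2"
        assert res.p_value < 0.001
        assert res.summary_success == "367 (17)"

    def test_identical_proportions_give_p_one(self):
        res = compare_groups(_binary(30, 100), _binary(30, 100), var_type="binary")
        assert res.p_value == pytest.approx(1.0)

    def test_small_table_uses_fisher_matching_enumeration(self):
        a, b = _binary(2, 12), _binary(7, 11)
        res = compare_groups(a, b, var_type="binary")
        assert res.test == "fisher"
        table = np.array([[2, 10], [7, 4]])
        assert res.p_value == pytest.approx(fisher_oracle(table), rel=1e-6)

    def test_wilcoxon_default_for_continuous(self):
        rng = np.random.default_rng(0)
        res = compare_groups(rng.normal(0, 1, 50), rng.normal(1, 1, 50))
        assert res.test == "wilcoxon"
        assert res.p_value < 0.01

    def test_t_test_on_request(self):
        rng = np.random.default_rng(1)
        res = compare_groups(rng.normal(size=30), rng.normal(size=30), continuous_test="t")
        assert res.test == "t"

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0, 2.0])

    def test_chi2_invariant_to_group_swap(self):
        res1 = compare_groups(_binary(30, 200), _binary(60, 210), var_type="binary")
        res2 = compare_groups(_binary(60, 210), _binary(30, 200), var_type="binary")
        assert res1.p_value == pytest.approx(res2.p_value)

    def test_null_p_values_approximately_uniform(self):
        """Permuted outcome labels should give a uniform p distribution."""
        rng = np.random.default_rng(2)
        values = rng.normal(size=60)
        ps = []
        for _ in range(1000):
            perm = rng.permutation(60)
            ps.append(compare_groups(values[perm[:30]], values[perm[30:]]).p_value)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestStratification:
    def test_stratum_assignment(self):
        out = peep_stratum([4.0, 5.0, 6.0, 10.0, 10.5, np.nan])
        assert list(out[:5]) == ["<=5", "<=5", "6-10", "6-10", ">10"]
        assert out[5] is None

    def test_known_cell_summary(self):
        values = np.arange(1.0, 10.0)
        peep = np.full(9, 4.0)
        outcome = np.array(["success"] * 9)
        table = stratified_summary(values, peep, outcome)
        row = table[table["stratum"] == "<=5"].iloc[0]
        assert row["summary_success"] == "5.0 (3.0; 7.0)"
        assert row["n_success"] == 9

    def test_empty_cell_gets_missing_marker(self):
        table = stratified_summary(np.array([1.0]), np.array([4.0]), np.array(["success"]))
        assert table[table["stratum"] == ">10"]["summary_failure"].iloc[0] is None

    def test_quartiles_match_brute_force(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=101)
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(x, q) == pytest.approx(quantile_oracle(x, q))


class TestRandomInterceptLogit:
    def test_matches_plain_logistic_when_sigma_fixed(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * X[:, 1])))).astype(float)
        fit = RandomInterceptLogit().fit(X, y, np.zeros(n), fix_sigma_zero=True)
        ref = sm.Logit(y, X).fit(disp=0)
        assert fit["llf"] == pytest.approx(ref.llf, abs=1e-4)
        assert fit["params"] == pytest.approx(ref.params, abs=1e-3)

    def test_matches_lme4_glmer(self, tmp_path):
        """Marginal likelihood and LRT agree with R's lme4 on the same data."""
        rng = np.random.default_rng(42)
        d = simulate_interaction_cohort(800, rng, interaction=0.4, center_sd=0.5)
        df = pd.DataFrame(
            {"y": d["success"].astype(int), "x": d["values"], "peep": d["peep"], "center": d["centers"]}
        )
        csv = tmp_path / "glmm.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "glmm.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                df <- read.csv("{csv}")
                df$stratum <- cut(df$peep, c(-Inf, 5, 10, Inf))
                df$z <- (df$x - mean(df$x)) / (sd(df$x) * sqrt((nrow(df) - 1) / nrow(df)))
                full <- glmer(y ~ z * stratum + (1 | center), data = df, family = binomial, nAGQ = 25)
                red <- glmer(y ~ z + stratum + (1 | center), data = df, family = binomial, nAGQ = 25)
                cat(logLik(full), logLik(red), anova(red, full)$`Pr(>Chisq)`[2], "\\n")
                """
            )
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        llf_full_r, llf_red_r, p_r = map(float, proc.stdout.split()[-3:])
        res = interaction_test(d["success"], d["values"], d["peep"], d["centers"])
        assert res.llf_full == pytest.approx(llf_full_r, abs=0.02)
        assert res.llf_reduced == pytest.approx(llf_red_r, abs=0.02)
        assert res.p_interaction == pytest.approx(p_r, abs=0.005)


class TestInteractionTest:
    def test_single_center_equals_plain_logistic_lrt(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        d = simulate_interaction_cohort(1200, rng, interaction=0.5, n_centers=1, center_sd=0.0)
        res = interaction_test(d["success"], d["values"], d["peep"], d["centers"])
        assert res.single_center

        strat = peep_stratum(d["peep"])
        present = [s for s in PEEP_STRATA if (strat == s).any()]
        z = (d["values"] - d["values"].mean()) / d["values"].std()
        dummies = np.column_stack([(strat == s).astype(float) for s in present[1:]])
        X_red = np.column_stack([np.ones(len(z)), z, dummies])
        X_full = np.column_stack([X_red, dummies * z[:, None]])
        llf_full = sm.Logit(d["success"], X_full).fit(disp=0).llf
        llf_red = sm.Logit(d["success"], X_red).fit(disp=0).llf
        lr = 2 * (llf_full - llf_red)
        p_ref = stats.chi2.sf(lr, dummies.shape[1])
        assert res.p_interaction == pytest.approx(p_ref, abs=1e-4)

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(6)
        d = simulate_interaction_cohort(4000, rng, interaction=0.8)
        res = interaction_test(d["success"], d["values"], d["peep"], d["centers"])
        assert res.p_interaction < 0.01

    def test_single_class_stratum_dropped(self):
        rng = np.random.default_rng(7)
        d = simulate_interaction_cohort(600, rng)
        d["success"][d["peep"] > 10.0] = 1.0  # degenerate high-PEEP stratum
        res = interaction_test(d["success"], d["values"], d["peep"], d["centers"])
        assert res.dropped_strata == [">10"]
        assert 0.0 <= res.p_interaction <= 1.0

    def test_too_few_strata_raise(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            interaction_test(
                (rng.random(100) < 0.5).astype(float),
                rng.normal(size=100),
                np.full(100, 8.0),
                np.zeros(100),
            )
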