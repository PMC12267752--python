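"""Group comparisons and the PEEP-interaction analysis.

Descriptive contrasts between successful and failed switch attempts use
chi-square (or Fisher's exact test when any expected cell count is below 5)
for proportions and the Wilcoxon rank-sum test (or Student's t on request)
for continuous variables, all two-sided.

Whether the association of a pre-switch variable (PaO2/FiO2, C_RS) with
switch success is modified by the set PEEP is tested with a mixed-effects
logistic regression: success ~ variable * PEEP stratum with a random
intercept per center, the interaction assessed by a likelihood-ratio test.
PEEP strata are ≤ 5, 6–10 and > 10 cmH2O, assigned from the PEEP paired to
the specific measurement.  The marginal likelihood of the random-intercept
model is computed by Gauss–Hermite quadrature; with a single center the
model reduces to a plain logistic regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

_EPS = 1e-9

PEEP_STRATA = ("<=5", "6-10", ">10")


# ---------------------------------------------------------------------------
# descriptive comparisons


@dataclass
class GroupComparison:
    variable: str
    summary_success: str
    summary_failure: str
    test: str  # chi2 | fisher | t | wilcoxon
    p_value: float


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation (type 7)
    return f"{med:.1f} ({q1:.1f}; {q3:.1f})"


def compare_groups(
    success: np.ndarray | list,
    failure: np.ndarray | list,
    variable: str = "",
    var_type: str = "continuous",
    continuous_test: str = "wilcoxon",
) -> GroupComparison:
    """Two-sided comparison of one variable between outcome groups.

    ``var_type='binary'`` expects 0/1 arrays and uses chi-square on the 2x2
    table, switching to Fisher's exact test when any expected cell count is
    below 5.  Continuous variables use the Wilcoxon rank-sum test by default
    or Student's t when ``continuous_test='t'``.
    """
    a = np.asarray(success, dtype=float)
    b = np.asarray(failure, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError(f"variable {variable!r}: both outcome groups must be non-empty")

    if var_type == "binary":
        table = np.array(
            [[a.sum(), a.size - a.sum()], [b.sum(), b.size - b.sum()]], dtype=float
        )
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            test = "fisher"
            _, p = stats.fisher_exact(table, alternative="two-sided")
        else:
            test = "chi2"
            res = stats.chi2_contingency(table, correction=False)
            p = res.pvalue
        s_a = f"{int(a.sum())} ({100 * a.mean():.0f})"
        s_b = f"{int(b.sum())} ({100 * b.mean():.0f})"
    elif var_type == "continuous":
        if continuous_test == "t":
            test = "t"
            _, p = stats.ttest_ind(a, b)
        else:
            test = "wilcoxon"
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        s_a, s_b = _median_iqr(a), _median_iqr(b)
    else:
        raise ValueError(f"unknown variable type {var_type!r}")

    return GroupComparison(variable, s_a, s_b, test, float(p))


def peep_stratum(peep: np.ndarray | list, bounds: tuple[float, float] = (5.0, 10.0)) -> np.ndarray:
    """Assign each PEEP value (cmH2O) to the strata ≤ 5 / 6–10 / > 10."""
    p = np.asarray(peep, dtype=float)
    out = np.where(p <= bounds[0] + _EPS, PEEP_STRATA[0], np.where(p <= bounds[1] + _EPS, PEEP_STRATA[1], PEEP_STRATA[2]))
    out = out.astype(object)
    out[np.isnan(p)] = None
    return out


def stratified_summary(
    values: np.ndarray, peep: np.ndarray, outcome: np.ndarray
) -> pd.DataFrame:
    """Median (IQR) of a variable per (PEEP stratum, outcome group) cell.

    Stratum assignment uses the PEEP paired to the specific measurement.
    Empty cells get a missing marker rather than raising.
    """
    v = np.asarray(values, dtype=float)
    strat = peep_stratum(peep)
    out = np.asarray(outcome)
    rows = []
    for s in PEEP_STRATA:
        rec = {"stratum": s}
        for g in ("success", "failure"):
            sel = v[(strat == s) & (out == g) & ~np.isnan(v)]
            rec[f"summary_{g}"] = _median_iqr(sel) if sel.size else None
            rec[f"n_{g}"] = int(sel.size)
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# random-intercept logistic regression (Gauss–Hermite marginal likelihood)


class RandomInterceptLogit:
    """Logistic regression with a Gaussian random intercept per cluster.

    The marginal log-likelihood integrates the random effect out with
    adaptive Gauss–Hermite quadrature: for each cluster the nodes are
    centered at the conditional mode of the random effect and scaled by the
    Laplace curvature, so a handful of nodes is accurate even for large
    clusters.  ``sigma`` (the random-effect SD) is bounded below at 0; at
    the boundary the model is an ordinary logistic regression.
    """

    def __init__(self, n_nodes: int = 9, max_sigma: float = 5.0):
        self.n_nodes = n_nodes
        self.max_sigma = max_sigma
        nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
        self._nodes = nodes
        self._logw_adapt = np.log(weights) + nodes**2

    @staticmethod
    def _cluster_loglik(eta_c: np.ndarray, s_c: np.ndarray, b) -> np.ndarray:
        """Sum of Bernoulli log-likelihoods at random-effect value(s) b."""
        u = np.atleast_1d(np.asarray(b, dtype=float))
        return -np.logaddexp(0.0, -(s_c[None, :] * (eta_c[None, :] + u[:, None]))).sum(axis=1)

    def _cluster_marginal(self, eta_c: np.ndarray, s_c: np.ndarray, sigma: float) -> float:
        if sigma < 1e-6:
            return float(self._cluster_loglik(eta_c, s_c, 0.0)[0])
        # Newton search for the conditional mode of
        # h(b) = cluster loglik(b) - b^2 / (2 sigma^2)
        b = 0.0
        for _ in range(30):
            p = 1.0 / (1.0 + np.exp(-(eta_c + b)))
            grad = np.sum(np.where(s_c > 0, 1.0 - p, -p)) - b / sigma**2
            hess = -np.sum(p * (1.0 - p)) - 1.0 / sigma**2
            step = grad / hess
            b -= step
            if abs(step) < 1e-10:
                break
        p = 1.0 / (1.0 + np.exp(-(eta_c + b)))
        hess = -np.sum(p * (1.0 - p)) - 1.0 / sigma**2
        tau = 1.0 / np.sqrt(-hess)
        z = b + np.sqrt(2.0) * tau * self._nodes
        h = self._cluster_loglik(eta_c, s_c, z) - z**2 / (2.0 * sigma**2)
        log_int = special.logsumexp(self._logw_adapt + h) + 0.5 * np.log(2.0) + np.log(tau)
        # normalizing constant of the N(0, sigma^2) density
        return float(log_int - 0.5 * np.log(2.0 * np.pi) - np.log(sigma))

    def _nll(self, params: np.ndarray, X: np.ndarray, s: np.ndarray, bounds: np.ndarray) -> float:
        beta, sigma = params[:-1], params[-1]
        eta = X @ beta
        total = 0.0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            total += self._cluster_marginal(eta[lo:hi], s[lo:hi], sigma)
        return -total

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        groups: np.ndarray,
        start: np.ndarray | None = None,
        fix_sigma_zero: bool = False,
    ) -> dict:
        """Maximize the marginal likelihood; returns params, sigma and llf."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        order = np.argsort(np.asarray(groups), kind="stable")
        Xs, ys = X[order], y[order]
        g = np.asarray(groups)[order]
        bounds_idx = np.concatenate([[0], np.flatnonzero(g[1:] != g[:-1]) + 1, [len(g)]])
        s = 2.0 * ys - 1.0

        k = X.shape[1]
        if start is None:
            x0 = np.zeros(k + 1)
            p_bar = min(max(ys.mean(), 1e-3), 1 - 1e-3)
            x0[0] = np.log(p_bar / (1 - p_bar))  # column 0 is the intercept
            x0[-1] = 0.2
        else:
            x0 = np.asarray(start, dtype=float).copy()
        if fix_sigma_zero:
            x0[-1] = 0.0
        box = [(None, None)] * k + [(0.0, 0.0 if fix_sigma_zero else self.max_sigma)]
        res = optimize.minimize(
            self._nll,
            x0,
            args=(Xs, s, bounds_idx),
            method="L-BFGS-B",
            bounds=box,
            options={"maxiter": 500, "ftol": 1e-10},
        )
        return {
            "params": res.x[:-1],
            "sigma": float(res.x[-1]),
            "llf": float(-res.fun),
            "converged": bool(res.success),
        }


@dataclass
class InteractionResult:
    variable: str
    strata: list[str]
    stratum_table: pd.DataFrame
    p_interaction: float
    llf_full: float
    llf_reduced: float
    df: int
    sigma: float
    n: int
    single_center: bool = False
    dropped_strata: list[str] = field(default_factory=list)


def interaction_test(
    success: np.ndarray,
    values: np.ndarray,
    peep: np.ndarray,
    centers: np.ndarray,
    variable: str = "",
    n_nodes: int = 9,
) -> InteractionResult:
    """Test whether PEEP modifies the association of a variable with success.

    Fits success ~ variable * stratum (random intercept per center) and the
    nested model without the interaction terms; ``p_interaction`` is from
    the likelihood-ratio chi-square with one degree of freedom per
    interaction column.  Strata containing a single outcome class are
    dropped with a warning.  With one center the random-effect SD is fixed
    at zero, which is exactly a plain logistic interaction fit.
    """
    y = np.asarray(success, dtype=float)
    v = np.asarray(values, dtype=float)
    p_arr = np.asarray(peep, dtype=float)
    strat = peep_stratum(peep)
    c = np.asarray(centers)

    keep = ~np.isnan(v) & ~pd.isna(strat) & ~np.isnan(y)
    y, v, p_arr, strat, c = y[keep], v[keep], p_arr[keep], strat[keep], c[keep]

    dropped = []
    for s in PEEP_STRATA:
        sel = strat == s
        if sel.any() and len(np.unique(y[sel])) < 2:
            logger.warning("stratum %s has a single outcome class; dropped", s)
            dropped.append(s)
            keep = ~sel
            y, v, p_arr, strat, c = y[keep], v[keep], p_arr[keep], strat[keep], c[keep]

    present = [s for s in PEEP_STRATA if (strat == s).any()]
    if len(present) < 2:
        raise ValueError("interaction test needs at least two populated PEEP strata")

    z = (v - v.mean()) / (v.std() or 1.0)
    dummies = np.column_stack([(strat == s).astype(float) for s in present[1:]])
    inter = dummies * z[:, None]
    intercept = np.ones_like(z)

    X_red = np.column_stack([intercept, z, dummies])
    X_full = np.column_stack([X_red, inter])

    single = len(np.unique(c)) < 2
    model = RandomInterceptLogit(n_nodes=n_nodes)
    red = model.fit(X_red, y, c, fix_sigma_zero=single)
    start_full = np.concatenate([red["params"], np.zeros(inter.shape[1]), [red["sigma"]]])
    full = model.fit(X_full, y, c, start=start_full, fix_sigma_zero=single)

    lr = max(0.0, 2.0 * (full["llf"] - red["llf"]))
    df = inter.shape[1]
    p = float(stats.chi2.sf(lr, df))

    outcome_lbl = np.where(y > 0.5, "success", "failure")
    table = stratified_summary(v, p_arr, outcome_lbl)

    return InteractionResult(
        variable=variable,
        strata=present,
        stratum_table=table,
        p_interaction=p,
        llf_full=full["llf"],
        llf_reduced=red["llf"],
        df=df,
        sigma=full["sigma"],
        n=int(len(y)),
        single_center=single,
        dropped_strata=dropped,
    )


# ---------------------------------------------------------------------------
# simulation helper for calibration studies of the interaction test


def simulate_interaction_cohort(
    n: int,
    rng: np.random.Generator,
    interaction: float = 0.0,
    beta_x: float = 0.3,
    stratum_shift: tuple[float, float] = (0.2, 0.4),
    center_sd: float = 0.3,
    n_centers: int = 3,
    base_logit: float = 0.3,
) -> dict:
    """Draw (success, variable, PEEP, center) with a planted interaction.

    The variable's log-odds slope is ``beta_x`` everywhere plus
    ``interaction`` added only in the PEEP > 10 stratum; ``interaction=0``
    gives a null cohort for type-I-error studies.  PEEP is drawn as integer
    cmH2O around 8 so all three strata are populated; centers carry a
    Gaussian random intercept of SD ``center_sd``.
    """
    center = rng.integers(0, n_centers, size=n)
    b = rng.normal(0.0, center_sd, size=n_centers)
    peep = np.clip(np.round(rng.normal(8.0, 2.5, size=n)), 0, 20)
    x = rng.normal(0.0, 1.0, size=n)
    high = peep > 10.0
    eta = base_logit + beta_x * x + interaction * x * high + b[center]
    eta += np.where(peep <= 5.0, 0.0, np.where(high, stratum_shift[1], stratum_shift[0]))
    ysucc = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return {"success": ysucc, "values": x, "peep": peep, "centers": center}
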