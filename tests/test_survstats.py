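"""Survival/categorical engine tests against independent oracles.

Oracles: brute-force partial-likelihood maximization on a grid, hand
product-limit calculations, exhaustive hypergeometric enumeration, a label
permutation reference for the log-rank test, and lifelines as an independent
implementation of Cox regression.
"""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from ovasig import survstats
from ovasig.survstats import CoxError


def breslow_partial_loglik(beta, x, time, event):
    """From-definition partial log-likelihood (scalar covariate, no ties)."""
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_matches_grid_search_on_four_sample_fixture(self):
        """Coefficient equals brute-force maximization of the hand-coded
        partial likelihood within 1e-6 (fixture with a finite MLE)."""
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        fit = survstats.fit_cox(x, time, event)
        grid = np.linspace(-5, 5, 200001)
        lls = [breslow_partial_loglik(b, x, time, event) for b in grid]
        b_grid = grid[int(np.argmax(lls))]
        res = minimize_scalar(lambda b: -breslow_partial_loglik(b, x, time, event),
                              bracket=(b_grid - 0.1, b_grid + 0.1))
        assert abs(fit.coef[0] - res.x) < 1e-6

    def test_risk_ordered_four_sample_fixture_diverges(self):
        """Covariate (1,1,0,0) with deaths at 1<2<3<4 has a monotone partial
        likelihood (score > 0 for every beta): the fit must refuse rather
        than return an arbitrary boundary value."""
        with pytest.raises(CoxError, match="monotone"):
            survstats.fit_cox(np.array([1.0, 1.0, 0.0, 0.0]),
                              np.array([1.0, 2.0, 3.0, 4.0]),
                              np.array([1, 1, 1, 1]))

    def test_constant_covariate_rejected(self):
        with pytest.raises(CoxError, match="zero-variance"):
            survstats.fit_cox(np.ones(6), np.arange(1.0, 7.0), np.ones(6, int))

    def test_no_events_rejected(self):
        with pytest.raises(CoxError, match="no events"):
            survstats.fit_cox(np.arange(6.0), np.arange(1.0, 7.0), np.zeros(6, int))

    def test_monotone_likelihood_detected(self):
        # covariate perfectly ordered with survival: likelihood diverges
        time = np.arange(1.0, 9.0)
        event = np.ones(8, int)
        x = np.arange(8.0)
        with pytest.raises(CoxError, match="monotone"):
            survstats.fit_cox(x, time, event)

    def test_recovers_true_coefficient_in_simulation(self):
        """Exponential hazards simulation: mean estimate near true beta=0.7."""
        est = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = 500
            x = rng.standard_normal(n)
            t = rng.exponential(np.exp(-0.7 * x))
            c = rng.exponential(np.exp(-0.7 * x).mean() * 2, n)
            e = (t <= c).astype(int)
            fit = survstats.fit_cox(x, np.minimum(t, c), e)
            est.append(fit.coef[0])
        assert abs(np.mean(est) - 0.7) < 0.1

    def test_breslow_equals_efron_without_ties(self, rng):
        n = 40
        x = rng.standard_normal((n, 2))
        t = rng.exponential(1, n)
        e = (rng.random(n) < 0.8).astype(int)
        fe = survstats.fit_cox(x, t, e, ties="efron")
        fb = survstats.fit_cox(x, t, e, ties="breslow")
        assert np.allclose(fe.coef, fb.coef, atol=1e-10)

    def test_multivariate_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        n = 120
        x = rng.standard_normal((n, 3))
        t = rng.exponential(np.exp(-(x @ [0.4, -0.6, 0.1])))
        e = (rng.random(n) < 0.75).astype(int)
        fit = survstats.fit_cox(x, t, e)
        df = pd.DataFrame(x, columns=list("abc"))
        df["T"], df["E"] = t, e
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(fit.coef, cph.params_.values, atol=2e-4)
        assert np.allclose(fit.se, cph.standard_errors_.values, atol=2e-4)

    def test_hr_and_ci_consistency(self, rng):
        n = 60
        x = rng.standard_normal(n)
        t = rng.exponential(1, n)
        fit = survstats.fit_cox(x, t, np.ones(n, int))
        lo, hi = fit.ci
        assert np.allclose(fit.hr, np.exp(fit.coef))
        assert np.allclose(lo, np.exp(fit.coef - 1.96 * fit.se))
        assert np.allclose(hi, np.exp(fit.coef + 1.96 * fit.se))


class TestUnivariateBatch:
    def test_matches_per_gene_lifelines_fits(self, rng):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        n = 70
        X = rng.standard_normal((n, 6))
        t = rng.exponential(1, n)
        e = (rng.random(n) < 0.7).astype(int)
        coef, se, p = survstats.cox_univariate_batch(X, t, e)
        for g in range(6):
            df = pd.DataFrame({"x": X[:, g], "T": t, "E": e})
            cph = lifelines.CoxPHFitter().fit(df, "T", "E")
            assert abs(coef[g] - cph.params_.values[0]) < 5e-4

    def test_tied_data_efron_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        n = 60
        X = rng.standard_normal((n, 4))
        t = np.round(rng.exponential(1, n), 1)  # heavy ties
        e = (rng.random(n) < 0.8).astype(int)
        coef, _, _ = survstats.cox_univariate_batch(X, t, e, ties="efron")
        for g in range(4):
            df = pd.DataFrame({"x": X[:, g], "T": t, "E": e})
            cph = lifelines.CoxPHFitter().fit(df, "T", "E")
            assert abs(coef[g] - cph.params_.values[0]) < 5e-4

    def test_numba_and_numpy_paths_agree(self, rng):
        n = 50
        X = rng.standard_normal((n, 8))
        t = np.round(rng.exponential(1, n), 1)
        e = (rng.random(n) < 0.8).astype(int)
        c1, s1, p1 = survstats.cox_univariate_batch(X, t, e)
        saved_kernel, saved_flag = survstats._NUMBA_KERNEL, survstats._NUMBA_FAILED
        try:
            survstats._NUMBA_KERNEL, survstats._NUMBA_FAILED = None, True
            c2, s2, p2 = survstats.cox_univariate_batch(X, t, e)
        finally:
            survstats._NUMBA_KERNEL, survstats._NUMBA_FAILED = saved_kernel, saved_flag
        assert np.allclose(c1, c2, atol=1e-12)
        assert np.allclose(p1, p2, atol=1e-12)

    def test_zero_variance_column_is_neutral(self, rng):
        n = 30
        X = rng.standard_normal((n, 3))
        X[:, 1] = 2.5
        t = rng.exponential(1, n)
        coef, se, p = survstats.cox_univariate_batch(X, t, np.ones(n, int))
        assert coef[1] == 0.0 and p[1] == 1.0


class TestKaplanMeier:
    def test_uniform_events_drop_tenth_median_five(self):
        time = np.arange(1.0, 11.0)
        curves = survstats.km_estimate(time, np.ones(10, int))
        km = curves["all"]
        assert np.allclose(km.surv, 1 - np.arange(1, 11) / 10)
        assert km.median == 5.0

    def test_hand_product_limit_with_censoring(self):
        """times (1, 2+, 3): S(1) = 2/3, S(3) = 0 by hand."""
        curves = survstats.km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        km = curves["all"]
        assert np.allclose(km.times, [1.0, 3.0])
        assert np.allclose(km.surv, [2 / 3, 0.0])

    def test_all_censored_median_not_reached(self):
        km = survstats.km_estimate([5.0, 8.0, 2.0], [0, 0, 0])["all"]
        assert km.median is None
        assert km.survival_at(10.0) == 1.0

    def test_group_sizes_sum_to_total(self, rng):
        n = 50
        groups = rng.choice(["a", "b", "c"], n)
        curves = survstats.km_estimate(rng.exponential(1, n),
                                       np.ones(n, int), groups)
        assert sum(c.n for c in curves.values()) == n


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array(["a"] * 3 + ["b"] * 3)
        res = survstats.logrank_test(g, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_tracks_exhaustive_permutation_oracle_on_small_fixture(self):
        """Chi-square p tracks the exact label-permutation p on a 10-sample
        fixture to within the chi-square approximation's finite-sample error
        (a few percent at this size)."""
        from itertools import combinations
        t = np.array([2.0, 5.0, 1.0, 7.0, 3.0, 8.0, 4.0, 9.0, 6.0, 10.0])
        e = np.array([1, 1, 1, 0, 1, 1, 1, 1, 0, 1])
        g = np.array(["a"] * 5 + ["b"] * 5)
        obs = survstats.logrank_test(g, t, e)
        stats_all = []
        for combo in combinations(range(10), 5):
            gp = np.array(["b"] * 10)
            gp[list(combo)] = "a"
            stats_all.append(survstats.logrank_test(gp, t, e).statistic)
        p_exact = float(np.mean(np.asarray(stats_all) >= obs.statistic - 1e-12))
        assert abs(obs.p_value - p_exact) < 0.05

    def test_null_p_uniformity(self):
        """Under no group difference the p-value is approximately uniform."""
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = 60
            t = rng.exponential(1, n)
            e = (rng.random(n) < 0.8).astype(int)
            g = rng.choice(["a", "b"], n)
            pvals.append(survstats.logrank_test(g, t, e).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_matches_lifelines_statistic(self, rng):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import multivariate_logrank_test
        n = 80
        t = rng.exponential(1, n)
        e = (rng.random(n) < 0.7).astype(int)
        g = rng.choice(["x", "y", "z"], n)
        mine = survstats.logrank_test(g, t, e)
        ref = multivariate_logrank_test(t, g, e)
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-8)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-6)


def enumerate_fisher_p(table):
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    probs = {k: stats.hypergeom.pmf(k, n, r1, c1) for k in range(kmin, kmax + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


class TestFisherExact:
    def test_example_tables_from_enumeration(self):
        res = survstats.fisher_exact([[3, 1], [1, 3]])
        assert res.odds_ratio == pytest.approx(9.0)
        assert res.p_value == pytest.approx(34 / 70, abs=1e-12)
        res = survstats.fisher_exact([[10, 10], [10, 10]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)
        res = survstats.fisher_exact([[5, 0], [0, 5]])
        assert res.p_value == pytest.approx(2 / 252, abs=1e-12)
        assert res.haldane

    def test_exhaustive_agreement_with_enumeration(self):
        """p matches from-definition enumeration on every table with margins
        <= 12 and positive margins."""
        for a in range(0, 13):
            for b in range(0, 13 - a):
                for c in range(0, 13):
                    for d in range(0, 13 - c):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        mine = survstats.fisher_exact([[a, b], [c, d]])
                        oracle = enumerate_fisher_p([[a, b], [c, d]])
                        assert mine.p_value == pytest.approx(oracle, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            survstats.fisher_exact([[0, 0], [3, 4]])


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert survstats.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_all_ones(self):
        assert np.allclose(survstats.bh_fdr([1, 1, 1]), 1.0)

    def test_step_up_formula_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        # from-definition: q_i = min over j >= i of p_(j) * m / j
        m = len(p)
        order = np.argsort(p)
        ps = p[order]
        q = np.minimum.accumulate((ps * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q, 1.0)
        assert np.allclose(survstats.bh_fdr(p), expected)


class TestClinicalCovariates:
    def test_dichotomization_rules(self):
        from conftest import make_clinical
        ct = make_clinical(
            [10, 20, 30, 40], [1, 1, 0, 0],
            age_years=[64.9, 65.0, np.nan, 70.0],
            stage=[2, 3, 4, np.nan],
            grade=[1, 3, 2, 3],
            debulking=["optimal", "suboptimal", "unknown", "grossly_visible"],
        )
        cov = survstats.build_clinical_covariates(ct)
        assert list(cov["age_ge65"]) == pytest.approx([0, 1, np.nan, 1], nan_ok=True)
        assert list(cov["advanced_stage"])[:2] == [0, 1]
        assert np.isnan(cov["suboptimal_debulking"].iloc[2])
        assert cov["suboptimal_debulking"].iloc[3] == 1.0
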