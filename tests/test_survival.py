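import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirsig.survival import (ConvergenceError, RankDeficientError, SurvivalData,
                             SurvivalError, cox_loglik_grad_hess, fit_cox,
                             fit_interaction_cox, km_estimate, logrank_test,
                             posthoc_power, univariate_cox_screen)
from tests.conftest import make_survival


def breslow_loglik_grid_oracle(time, event, x, grid):
    """Independent brute-force Breslow partial likelihood over a beta grid.

    Single covariate; direct double loop over events and risk sets.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = np.zeros(len(grid))
    for gi, b in enumerate(grid):
        eta = b * x
        s = 0.0
        for i in range(len(time)):
            if event[i] == 1:
                risk = time >= time[i]
                s += eta[i] - np.log(np.sum(np.exp(eta[risk])))
        ll[gi] = s
    return ll


class TestFitCox:
    def test_symmetric_groups_give_zero_beta(self):
        # both groups carry the same event-time multiset
        time = np.array([1, 2, 3, 4, 1, 2, 3, 4], float)
        event = np.ones(8, int)
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        fit = fit_cox(SurvivalData(time, event, g[:, None], ["g"]))
        assert abs(fit.beta[0]) < 1e-6

    def test_six_subject_toy_matches_grid_search(self):
        # interleaved groups keep the likelihood bounded (a group that fails
        # strictly first has an infinite MLE)
        time = np.arange(1.0, 7.0)
        event = np.ones(6, int)
        x = np.array([1, 0, 1, 0, 1, 0], float)
        fit = fit_cox(SurvivalData(time, event, x[:, None], ["x"]))
        grid = np.linspace(-4, 4, 160001)
        ll = breslow_loglik_grid_oracle(time, event, x, grid)
        assert abs(fit.beta[0] - grid[np.argmax(ll)]) < 1e-4

    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter

        time, event, X = make_survival(rng, n=50, p=1, beta=[0.7])
        fit = fit_cox(SurvivalData(time, event, X, ["x"]))
        df = pd.DataFrame({"T": time, "E": event, "x": X[:, 0]})
        cph = CoxPHFitter().fit(df, "T", "E", fit_options={"precision": 1e-10})
        assert abs(fit.beta[0] - cph.params_.iloc[0]) < 1e-6
        assert abs(fit.se[0] - cph.standard_errors_.iloc[0]) < 1e-6

    def test_matches_lifelines_multivariate(self, rng):
        from lifelines import CoxPHFitter

        time, event, X = make_survival(rng, n=80, p=3, beta=[0.5, -0.4, 0.0])
        fit = fit_cox(SurvivalData(time, event, X, ["a", "b", "c"]))
        df = pd.DataFrame({"T": time, "E": event, "a": X[:, 0], "b": X[:, 1], "c": X[:, 2]})
        cph = CoxPHFitter().fit(df, "T", "E", fit_options={"precision": 1e-10})
        assert np.allclose(fit.beta, cph.params_.to_numpy(), atol=1e-6)
        assert np.allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-6)

    def test_efron_matches_lifelines_with_ties(self, rng):
        from lifelines import CoxPHFitter

        time, event, X = make_survival(rng, n=60, p=2, beta=[0.6, -0.3])
        time = np.ceil(time)  # force heavy ties; lifelines uses Efron
        fit = fit_cox(SurvivalData(time, event, X, ["a", "b"]), ties="efron")
        df = pd.DataFrame({"T": time, "E": event, "a": X[:, 0], "b": X[:, 1]})
        cph = CoxPHFitter().fit(df, "T", "E", fit_options={"precision": 1e-10})
        assert np.allclose(fit.beta, cph.params_.to_numpy(), atol=1e-6)

    def test_subject_reordering_invariance(self, rng):
        time, event, X = make_survival(rng, n=40, p=2, beta=[0.5, 0.2])
        fit1 = fit_cox(SurvivalData(time, event, X, ["a", "b"]))
        perm = rng.permutation(40)
        fit2 = fit_cox(SurvivalData(time[perm], event[perm], X[perm], ["a", "b"]))
        assert np.allclose(fit1.beta, fit2.beta, atol=1e-9)

    def test_loglik_nondecreasing_and_ci_shape(self, rng):
        time, event, X = make_survival(rng, n=50, p=2, beta=[1.0, 0.0])
        fit = fit_cox(SurvivalData(time, event, X, ["a", "b"]))
        assert fit.loglik >= fit.loglik_null
        ci = fit.ci
        assert np.allclose(ci[:, 0], np.exp(fit.beta - 1.959963984540054 * fit.se))
        assert (fit.hr > 0).all()

    def test_collinear_columns_are_named(self, rng):
        time, event, X = make_survival(rng, n=30, p=2)
        X3 = np.column_stack([X, X[:, 0] + X[:, 1]])
        with pytest.raises(RankDeficientError):
            fit_cox(SurvivalData(time, event, X3, ["a", "b", "absum"]))

    def test_perfect_separation_flagged(self):
        # covariate perfectly ordered with event times: monotone likelihood
        time = np.arange(1.0, 13.0)
        event = np.ones(12, int)
        x = np.arange(12.0)
        with pytest.raises(ConvergenceError):
            fit_cox(SurvivalData(time, event, x[:, None], ["x"]), max_iter=50)
        fit = fit_cox(SurvivalData(time, event, x[:, None], ["x"]), on_fail="flag")
        assert not fit.converged


class TestGridSearchFuzz:
    def test_beta_matches_1d_likelihood_scan_on_toys(self):
        """200 random toy datasets (n <= 8): Newton beta vs grid-search max."""
        rng = np.random.default_rng(77)
        checked = 0
        while checked < 200:
            n = int(rng.integers(4, 9))
            x = rng.normal(size=n)
            time = rng.exponential(1.0, n) + 0.01
            event = (rng.uniform(size=n) < 0.8).astype(int)
            if event.sum() < 2 or np.std(x[event == 1]) < 1e-3:
                continue
            grid = np.linspace(-3, 3, 6001)
            ll = breslow_loglik_grid_oracle(time, event, x, grid)
            b_grid = grid[np.argmax(ll)]
            if abs(b_grid) > 2.5:   # optimum outside grid / near separation
                continue
            fit = fit_cox(SurvivalData(time, event, x[:, None], ["x"]), on_fail="flag")
            assert abs(fit.beta[0] - b_grid) < 1e-3 + (grid[1] - grid[0])
            checked += 1


class TestScoreVsLogrank:
    def test_cox_score_test_equals_logrank_without_ties(self):
        """For one binary covariate and untied events the score test is the
        log-rank chi-square."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(10, 30))
            time = rng.exponential(1.0, n)
            event = (rng.uniform(size=n) < 0.7).astype(int)
            g = (rng.uniform(size=n) < 0.5).astype(float)
            if event.sum() < 2 or g.var() == 0 or event[g == 1].sum() == 0 or event[g == 0].sum() == 0:
                continue
            data = SurvivalData(time, event, g[:, None], ["g"])
            _, U, H = cox_loglik_grad_hess(data, np.zeros(1))
            score_stat = float(U[0] ** 2 / -H[0, 0])
            lr = logrank_test(time, event, g.astype(int))
            assert abs(score_stat - lr.statistic) < 1e-8


class TestKaplanMeier:
    def test_all_events_hand_values(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])["all"]
        assert km.evaluate(2)[0] == pytest.approx(0.5)
        assert km.median == 2

    def test_censoring_hand_product(self):
        km = km_estimate([1, 2, 3, 4], [1, 0, 1, 1])["all"]
        assert km.evaluate(3)[0] == pytest.approx(0.375)

    def test_no_events_median_not_reached(self):
        km = km_estimate([5, 6, 7], [0, 0, 0])["all"]
        assert km.evaluate(10)[0] == 1.0
        assert km.median is None

    def test_uncensored_equals_empirical_survival(self, rng):
        t = rng.exponential(5.0, 40)
        km = km_estimate(t, np.ones(40, int))["all"]
        pts = np.quantile(t, [0.1, 0.4, 0.6, 0.9])
        emp = [(t > u).mean() for u in pts]
        assert np.allclose(km.evaluate(pts), emp, atol=1e-12)

    def test_median_ci_brackets_median(self, rng):
        t, e, _ = make_survival(rng, n=120, p=1, beta=[0.0], censor_rate=0.2)
        km = km_estimate(t, e)["all"]
        lo, hi = km.median_ci
        assert lo is not None and lo <= km.median
        assert hi is None or hi >= km.median


def logrank_bruteforce_2group(time, event, group):
    """Independent O-E/V computation from the 2x2 table at each event time."""
    time, event, group = map(np.asarray, (time, event, group))
    O = E = V = 0.0
    for u in np.unique(time[event == 1]):
        at = time >= u
        n = at.sum()
        n1 = (at & (group == 1)).sum()
        d = ((time == u) & (event == 1)).sum()
        d1 = ((time == u) & (event == 1) & (group == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        lr = logrank_test([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1], [0, 0, 0, 1, 1, 1])
        assert lr.statistic < 1e-10
        assert abs(lr.observed.sum() - lr.expected.sum()) < 1e-10

    def test_toy_matches_bruteforce_tables(self):
        time = [1, 2, 3, 4, 2, 4, 5, 6]
        event = [1, 1, 0, 1, 1, 1, 1, 0]
        group = [0, 0, 0, 0, 1, 1, 1, 1]
        lr = logrank_test(time, event, group)
        assert lr.statistic == pytest.approx(logrank_bruteforce_2group(time, event, np.array(group)), abs=1e-10)
        assert lr.df == 1

    def test_bruteforce_fuzz(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 25))
            time = rng.exponential(1.0, n)
            event = (rng.uniform(size=n) < 0.7).astype(int)
            group = (rng.uniform(size=n) < 0.5).astype(int)
            if event.sum() < 1 or group.var() == 0:
                continue
            lr = logrank_test(time, event, group)
            assert lr.statistic == pytest.approx(logrank_bruteforce_2group(time, event, group), abs=1e-8)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        time, event, _ = make_survival(rng, n=60, p=1)
        group = (rng.uniform(size=60) < 0.4).astype(int)
        lr = logrank_test(time, event, group)
        ref = multivariate_logrank_test(time, group, event)
        assert lr.statistic == pytest.approx(ref.test_statistic, abs=1e-8)

    def test_invariant_under_monotone_time_transform(self, rng):
        time, event, _ = make_survival(rng, n=40, p=1)
        group = (rng.uniform(size=40) < 0.5).astype(int)
        a = logrank_test(time, event, group)
        b = logrank_test(time**2, event, group)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-10)

    def test_single_group_errors(self):
        with pytest.raises(SurvivalError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestCoxScreen:
    def test_alpha_zero_keeps_nothing(self, rng):
        from tests.conftest import make_cohort

        expr, clin = make_cohort(rng, n=40)
        kept, _ = univariate_cox_screen(expr, clin, alpha=1e-12)
        assert kept == []

    def test_planted_feature_retained(self, rng):
        from tests.conftest import make_cohort

        hits = 0
        for r in range(20):
            expr, clin = make_cohort(np.random.default_rng(900 + r), n=67, beta=(0.8, 0.0, 0.0))
            kept, _ = univariate_cox_screen(expr, clin, alpha=0.1)
            hits += "f0" in kept
        assert hits >= 19


class TestInteraction:
    def test_null_interaction_p_uniform(self):
        """Zero planted interaction: Wald p for the product term ~ U(0,1)."""
        rng = np.random.default_rng(13)
        ps = []
        while len(ps) < 200:
            n = 120
            a = (rng.uniform(size=n) < 0.5).astype(float)
            b = (rng.uniform(size=n) < 0.5).astype(float)
            lp = 0.4 * a + 0.3 * b      # main effects only
            T = rng.exponential(10.0 / np.exp(lp))
            C = rng.exponential(30.0, n)
            time, event = np.minimum(T, C), (T <= C).astype(int)
            try:
                fit = fit_interaction_cox(time, event, a, b)
            except (RankDeficientError, SurvivalError, ConvergenceError):
                continue
            ps.append(fit.p[2])
        stat = stats.kstest(ps, "uniform")
        assert stat.pvalue > 0.01

    def test_interaction_recovery(self):
        # unbiasedness at n=300: the mean over replicates recovers the
        # planted product coefficient well inside one Monte-Carlo SE
        rng = np.random.default_rng(29)
        n = 300
        est = []
        for _ in range(6):
            a = (rng.uniform(size=n) < 0.5).astype(float)
            b = (rng.uniform(size=n) < 0.5).astype(float)
            lp = 0.3 * a + 0.2 * b + 1.0 * a * b
            T = rng.exponential(10.0 / np.exp(lp))
            C = rng.exponential(40.0, n)
            time, event = np.minimum(T, C), (T <= C).astype(int)
            est.append(fit_interaction_cox(time, event, a, b).beta[2])
        assert abs(np.mean(est) - 1.0) < 0.2

    def test_constant_factor_names_product_term(self, rng):
        time, event, _ = make_survival(rng, n=30, p=1)
        a = (rng.uniform(size=30) < 0.5).astype(float)
        b = np.zeros(30)
        with pytest.raises(RankDeficientError, match="a:b"):
            fit_interaction_cox(time, event, a, b)


class TestPosthocPower:
    def test_null_hr_gives_alpha_half(self):
        assert posthoc_power(1.0, 100) == pytest.approx(stats.norm.cdf(-stats.norm.ppf(0.975)), abs=1e-12)

    def test_hand_value(self):
        # HR=2, d=100, p=0.5: Phi(ln2 * 5 - 1.96)
        expected = stats.norm.cdf(np.log(2) * 5 - stats.norm.ppf(0.975))
        assert posthoc_power(2.0, 100, 0.5, 0.05) == pytest.approx(expected, abs=1e-9)
        assert posthoc_power(2.0, 100, 0.5, 0.05) == pytest.approx(0.9339, abs=5e-4)

    def test_monotone_in_events_and_effect(self):
        p1 = [posthoc_power(2.0, d) for d in (20, 50, 100, 200)]
        assert all(np.diff(p1) > 0)
        p2 = [posthoc_power(h, 80) for h in (1.2, 1.5, 2.0, 3.0)]
        assert all(np.diff(p2) > 0)
        assert posthoc_power(0.5, 80) == posthoc_power(2.0, 80)

    def test_zero_events_errors(self):
        with pytest.raises(SurvivalError):
            posthoc_power(2.0, 0)
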