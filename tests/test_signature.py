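import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirsig.io import ExpressionMatrix
from mirsig.signature import (ContingencyResult, RiskSignature, SignatureError,
                              chisq_or_fisher, classify_risk, evaluate_km_by_risk,
                              fit_signature, progressive_rate, response_by_risk,
                              risk_score, td_auc)
from tests.conftest import make_cohort

#: the published two-miRNA signature: risk = 0.092*miR-933 - 0.259*miR-125b-2-3p
PUB = RiskSignature(feature_ids=["miR-125b-2-3p", "miR-933"],
                    coefficients=[-0.259, 0.092], cutoff=0.022)


class TestRiskScore:
    def test_published_coefficients_on_unit_input(self):
        assert risk_score(PUB, {"miR-125b-2-3p": 1.0, "miR-933": 1.0}) == pytest.approx(-0.167)

    def test_arithmetic_example(self):
        s = risk_score(PUB, {"miR-933": 4.0, "miR-125b-2-3p": 2.5})
        assert s == pytest.approx(0.368 - 0.6475, abs=1e-12)

    def test_zero_expression_gives_zero(self):
        assert risk_score(PUB, {"miR-933": 0.0, "miR-125b-2-3p": 0.0}) == 0.0

    def test_missing_feature_is_named(self):
        with pytest.raises(SignatureError, match="miR-933"):
            risk_score(PUB, {"miR-125b-2-3p": 1.0})

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-5, 5, allow_nan=False), st.floats(-5, 5, allow_nan=False),
           st.floats(-3, 3, allow_nan=False))
    def test_linearity(self, x1, x2, a):
        base = risk_score(PUB, {"miR-125b-2-3p": x1, "miR-933": x2})
        scaled = risk_score(PUB, {"miR-125b-2-3p": a * x1, "miR-933": a * x2})
        assert scaled == pytest.approx(a * base, abs=1e-9)

    def test_matrix_scoring_matches_per_patient(self, rng):
        data = pd.DataFrame(rng.normal(5, 1, (2, 6)),
                            index=["miR-125b-2-3p", "miR-933"],
                            columns=[f"s{i}" for i in range(6)])
        m = ExpressionMatrix(data)
        series = risk_score(PUB, m)
        for s in m.sample_ids:
            one = risk_score(PUB, data[s].to_dict())
            assert series[s] == pytest.approx(one, abs=1e-12)


class TestClassifyRisk:
    def test_published_cutoff_boundary_rule(self):
        a = classify_risk(np.array([-0.1, 0.022, 0.5]), 0.022)
        assert list(a.groups) == ["low", "low", "high"]

    def test_median_split_sizes(self, rng):
        scores = rng.normal(size=68)
        cutoff = float(np.median(scores))
        a = classify_risk(scores, cutoff)
        assert abs((a.groups == "low").sum() - (a.groups == "high").sum()) <= 1

    def test_shift_invariance(self, rng):
        scores = rng.normal(size=31)
        cutoff = float(np.median(scores))
        a = classify_risk(scores, cutoff)
        b = classify_risk(scores + 3.7, cutoff + 3.7)
        assert (a.groups == b.groups).all()

    def test_non_finite_rejected(self):
        with pytest.raises(SignatureError):
            classify_risk(np.array([1.0, np.inf]), 0.0)


class TestFitSignature:
    def test_cutoff_is_exact_median_of_training_scores(self, rng):
        expr, clin = make_cohort(rng, n=41, beta=(0.9, -0.4, 0.0))
        sig, fit = fit_signature(expr, clin, ["f0", "f1"])
        scores = risk_score(sig, expr)
        assert sig.cutoff == pytest.approx(float(np.median(scores)), abs=1e-12)
        assert len(sig.feature_ids) == len(sig.coefficients) == 2

    def test_single_feature_signature_valid(self, rng):
        expr, clin = make_cohort(rng, n=40, beta=(0.9, 0.0, 0.0))
        sig, _ = fit_signature(expr, clin, ["f0"])
        assert len(sig.feature_ids) == 1

    def test_duplicated_feature_pair_rejected(self, rng):
        expr, clin = make_cohort(rng, n=40)
        expr.data.loc["f1"] = expr.data.loc["f0"]
        from mirsig.survival import RankDeficientError

        with pytest.raises(RankDeficientError):
            fit_signature(expr, clin, ["f0", "f1"])

    def test_signature_json_round_trip(self, tmp_path):
        path = tmp_path / "sig.json"
        PUB.save(path)
        back = RiskSignature.load(path)
        assert back.feature_ids == PUB.feature_ids
        assert np.allclose(back.coefficients, PUB.coefficients)
        assert back.cutoff == PUB.cutoff


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestChisqOrFisher:
    def test_independence_gives_zero(self):
        stat, p, method = chisq_or_fisher([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert method == "chi-square"

    def test_small_cells_use_fisher_matching_enumeration(self):
        table = [[1, 9], [8, 2]]
        _, p, method = chisq_or_fisher(table)
        assert method == "fisher"
        assert p == pytest.approx(fisher_enumeration_oracle(table), rel=1e-9)

    def test_doubling_counts_doubles_chisq(self):
        t = np.array([[20, 12], [9, 24]])
        s1, _, m1 = chisq_or_fisher(t)
        s2, _, m2 = chisq_or_fisher(2 * t)
        assert m1 == m2 == "chi-square"
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_fisher_fuzz_against_enumeration(self, rng):
        from scipy.stats import fisher_exact

        done = 0
        while done < 500:
            total = int(rng.integers(4, 31))
            cells = rng.multinomial(total, [0.25] * 4)
            table = cells.reshape(2, 2)
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            _, p_sp = fisher_exact(table)
            assert p_sp == pytest.approx(fisher_enumeration_oracle(table), rel=1e-8)
            done += 1

    def test_degenerate_margin_errors(self):
        with pytest.raises(SignatureError):
            chisq_or_fisher([[0, 0], [3, 4]])


class TestProgressiveRate:
    def test_published_fractions(self):
        counts = pd.DataFrame({"low": [15, 11, 4], "high": [8, 20, 9]},
                              index=["CR+PR", "SD", "PD"])
        cont = ContingencyResult(counts=counts, statistic=0.0, p=1.0, method="chi-square")
        rate = progressive_rate(cont)
        assert rate["low"]["percent"] == 13.33
        assert rate["high"]["percent"] == 24.32
        assert rate["low"]["fraction"] == pytest.approx(4 / 30)

    def test_forty_percent(self):
        counts = pd.DataFrame({"low": [10, 12, 3], "high": [2, 7, 6]},
                              index=["CR+PR", "SD", "PD"])
        cont = ContingencyResult(counts=counts, statistic=0.0, p=1.0, method="chi-square")
        assert progressive_rate(cont)["high"]["percent"] == 40.00

    def test_zero_pd(self):
        counts = pd.DataFrame({"low": [5, 5, 0], "high": [4, 2, 1]},
                              index=["CR+PR", "SD", "PD"])
        cont = ContingencyResult(counts=counts, statistic=0.0, p=1.0, method="chi-square")
        assert progressive_rate(cont)["low"]["percent"] == 0.0

    def test_proportions_sum_to_one(self):
        counts = pd.DataFrame({"low": [15, 11, 4], "high": [8, 20, 9]},
                              index=["CR+PR", "SD", "PD"])
        cont = ContingencyResult(counts=counts, statistic=0.0, p=1.0, method="chi-square")
        assert np.allclose(cont.proportions.sum(axis=0), 1.0, atol=1e-12)


class TestKMByRisk:
    def test_identical_groups_logrank_near_zero(self, rng):
        expr, clin = make_cohort(rng, n=30, beta=(0.0, 0.0, 0.0))
        # duplicate the cohort so low/high carry identical data
        t = np.concatenate([clin.time, clin.time])
        e = np.concatenate([clin.event, clin.event])
        scores = np.concatenate([np.zeros(30), np.ones(30)])
        import pandas as pd

        from mirsig.io import ClinicalCohort

        table = pd.DataFrame({"pfs_months": t, "event": e},
                             index=[f"x{i}" for i in range(60)])
        clin2 = ClinicalCohort(table)
        a = classify_risk(scores, 0.5, sample_ids=list(table.index))
        curves, lr = evaluate_km_by_risk(a, clin2)
        assert lr.statistic < 1e-10

    def test_planted_group_effect_orders_medians(self):
        rng = np.random.default_rng(55)
        n = 150
        g = (rng.uniform(size=n) < 0.5).astype(float)
        T = rng.exponential(12.0 / np.exp(np.log(2.8) * g))
        table = pd.DataFrame({"pfs_months": np.maximum(T, 1e-3), "event": np.ones(n, int)},
                             index=[f"p{i}" for i in range(n)])
        from mirsig.io import ClinicalCohort

        clin = ClinicalCohort(table)
        a = classify_risk(g, 0.5, sample_ids=list(table.index))
        curves, lr = evaluate_km_by_risk(a, clin)
        assert curves["low"].median > curves["high"].median
        assert lr.p < 0.01


class TestTdAuc:
    def test_perfect_concordance(self, rng):
        t = rng.exponential(10, 80) + 0.1
        scores = -t   # earlier event = higher risk exactly
        for u in (np.quantile(t, 0.3), np.quantile(t, 0.6)):
            res = td_auc(scores, t, np.ones(80, int), u, n_boot=0)
            assert res.auc == 1.0

    def test_random_scores_near_half(self, rng):
        n = 500
        t = rng.exponential(10, n)
        scores = rng.normal(size=n)
        res = td_auc(scores, t, np.ones(n, int), float(np.quantile(t, 0.5)), n_boot=0)
        assert abs(res.auc - 0.5) < 0.1

    def test_uncensored_ipcw_equals_naive(self, rng):
        n = 120
        t = rng.exponential(10, n)
        scores = rng.normal(size=n) + 1 / t
        u = float(np.quantile(t, 0.5))
        a = td_auc(scores, t, np.ones(n, int), u, estimator="ipcw", n_boot=0)
        b = td_auc(scores, t, np.ones(n, int), u, estimator="naive", n_boot=0)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_matches_sksurv_cumulative_dynamic_auc(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        n = 150
        x = rng.normal(size=n)
        T = rng.exponential(10 / np.exp(0.8 * x))
        C = rng.exponential(25, n)
        E = T <= C
        tobs = np.minimum(T, C)
        y = Surv.from_arrays(E, tobs)
        for u in (np.quantile(tobs, 0.3), np.quantile(tobs, 0.6)):
            mine = td_auc(x, tobs, E.astype(int), float(u), n_boot=0)
            ref, _ = cumulative_dynamic_auc(y, y, x, [u])
            assert mine.auc == pytest.approx(ref[0], abs=1e-10)

    def test_bootstrap_ci_brackets_estimate(self, rng):
        n = 200
        x = rng.normal(size=n)
        T = rng.exponential(10 / np.exp(0.8 * x))
        res = td_auc(x, T, np.ones(n, int), float(np.quantile(T, 0.5)),
                     n_boot=100, seed=4)
        assert res.ci is not None
        assert res.ci[0] <= res.auc <= res.ci[1]

    def test_time_outside_followup_rejected(self, rng):
        t = rng.exponential(10, 50)
        with pytest.raises(SignatureError):
            td_auc(rng.normal(size=50), t, np.ones(50, int), t.max() * 2)


class TestResponseByRisk:
    def test_counts_and_collapse(self, rng):
        expr, clin = make_cohort(rng, n=60)
        scores = rng.normal(size=60)
        a = classify_risk(scores, float(np.median(scores)), sample_ids=clin.sample_ids)
        cont = response_by_risk(clin, a)
        assert list(cont.counts.index) == ["CR+PR", "SD", "PD"]
        assert cont.counts.to_numpy().sum() == 60
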