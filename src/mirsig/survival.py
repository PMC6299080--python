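"""From-scratch survival machinery.

Cox proportional-hazards fitting by Newton–Raphson on the Breslow or Efron
partial likelihood, the univariate Cox screen, interaction models,
Kaplan–Meier product-limit curves with Greenwood variance and a
Brookmeyer–Crowley-type median CI on the log(-log) scale, the unweighted
log-rank test, and a Schoenfeld-approximation post hoc power calculation.

lifelines / scikit-survival are deliberately not used here; they serve as
independent oracles in the test suite only.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalCohort, ExpressionMatrix, MirsigError

Z_95 = 1.959963984540054  # Phi^{-1}(0.975); fixed Wald quantile for 95% CIs


class SurvivalError(MirsigError):
    pass


class ConvergenceError(SurvivalError):
    pass


class RankDeficientError(SurvivalError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"covariate matrix is rank deficient; collinear column(s): {self.columns}")


@dataclasses.dataclass
class SurvivalData:
    """Right-censored outcomes with a covariate matrix.

    ``time`` positive (months), ``event`` in {0,1}; ``covariates`` is
    n x p with ``names`` labelling columns (categoricals are dummy-coded by
    the caller, reference levels recorded in ``reference_levels``).
    """

    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray
    names: list[str]
    reference_levels: dict | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.time.shape[0]:
            self.covariates = self.covariates.T
        if np.any(self.time <= 0):
            raise SurvivalError("all times must be positive")
        if not np.isin(self.event, [0, 1]).all():
            raise SurvivalError("event indicators must be 0/1")
        if len(self.names) != self.covariates.shape[1]:
            raise SurvivalError("names/covariate column mismatch")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @classmethod
    def from_cohort(cls, clinical: ClinicalCohort, expr: ExpressionMatrix | None = None,
                    feature_ids=None, covariate_cols=()) -> "SurvivalData":
        """Assemble survival data from a clinical cohort and optional features."""
        cols, names = [], []
        if expr is not None and feature_ids:
            block = expr.values_for(clinical.sample_ids, feature_ids)
            cols.append(block)
            names.extend(feature_ids)
        for c in covariate_cols:
            cols.append(clinical.table[c].to_numpy(float)[:, None])
            names.append(c)
        X = np.hstack(cols) if cols else np.empty((clinical.n, 0))
        return cls(clinical.time, clinical.event, X, names)


@dataclasses.dataclass
class CoxFit:
    """Newton–Raphson Cox fit: coefficients, Wald inference, likelihoods."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    ties: str
    converged: bool
    n_iter: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.z))

    @property
    def ci(self) -> np.ndarray:
        """(p, 2) array of exp(beta -/+ 1.96 SE)."""
        with np.errstate(over="ignore"):
            lo = np.exp(self.beta - Z_95 * self.se)
            hi = np.exp(self.beta + Z_95 * self.se)
        return np.column_stack([lo, hi])

    def summary(self) -> pd.DataFrame:
        ci = self.ci
        return pd.DataFrame(
            {"beta": self.beta, "hr": self.hr, "se": self.se, "z": self.z,
             "p": self.p, "ci_low": ci[:, 0], "ci_high": ci[:, 1]},
            index=self.names,
        )

    def coef_dict(self) -> dict[str, float]:
        return {n: float(b) for n, b in zip(self.names, self.beta)}


def _sorted_views(data: SurvivalData):
    order = np.argsort(data.time, kind="stable")
    return data.time[order], data.event[order], data.covariates[order]


def cox_loglik_grad_hess(data: SurvivalData, beta: np.ndarray, ties: str = "breslow"):
    """Log partial likelihood, score vector and Hessian at beta."""
    t, d, X = _sorted_views(data)
    n, p = X.shape
    eta = X @ beta
    # clip to keep exp finite during wild Newton trial steps
    ex = np.exp(np.clip(eta, -500, 500))
    ll = 0.0
    U = np.zeros(p)
    H = np.zeros((p, p))
    # accumulate risk-set sums from latest time backwards
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = n - 1
    groups = []
    while i >= 0:
        j = i
        while j >= 0 and t[j] == t[i]:
            j -= 1
        idx = np.arange(j + 1, i + 1)
        S0 += ex[idx].sum()
        S1 += ex[idx] @ X[idx]
        S2 += (ex[idx][:, None] * X[idx]).T @ X[idx]
        ev = idx[d[idx] == 1]
        if ev.size:
            D = ev.size
            xev = X[ev]
            ll += eta[ev].sum()
            if ties == "breslow" or D == 1:
                ll -= D * np.log(S0)
                m1 = S1 / S0
                U += xev.sum(axis=0) - D * m1
                H -= D * (S2 / S0 - np.outer(m1, m1))
            elif ties == "efron":
                e0 = ex[ev].sum()
                e1 = ex[ev] @ xev
                e2 = (ex[ev][:, None] * xev).T @ xev
                for k in range(D):
                    f = k / D
                    den = S0 - f * e0
                    num1 = S1 - f * e1
                    num2 = S2 - f * e2
                    ll -= np.log(den)
                    m1 = num1 / den
                    U -= m1
                    H -= num2 / den - np.outer(m1, m1)
                U += xev.sum(axis=0)
            else:
                raise ValueError(f"unknown ties method {ties!r}")
        i = j
    return ll, U, H


def cox_loglik(data: SurvivalData, beta: np.ndarray, ties: str = "breslow") -> float:
    return cox_loglik_grad_hess(data, beta, ties)[0]


def _check_rank(X: np.ndarray, names) -> None:
    if X.shape[1] == 0:
        raise SurvivalError("no covariates to fit")
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    zero = norms < 1e-12
    if zero.any():
        raise RankDeficientError([n for n, z in zip(names, zero) if z])
    rank = np.linalg.matrix_rank(Xc)
    if rank < X.shape[1]:
        # pivoted QR: columns beyond the numerical rank are the dependent ones
        from scipy.linalg import qr

        _, r, piv = qr(Xc, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = piv[diag < 1e-10 * diag[0]] if diag.size else piv[rank:]
        bad = list(bad) + list(piv[rank:])
        cols = sorted({names[int(b)] for b in bad})
        raise RankDeficientError(cols)


def fit_cox(data: SurvivalData, ties: str = "breslow", max_iter: int = 50,
            tol_score: float = 1e-8, tol_loglik: float = 1e-10,
            on_fail: str = "raise") -> CoxFit:
    """Maximize the Cox partial likelihood by Newton–Raphson with step-halving.

    Convergence when max |score| < ``tol_score`` or the log-likelihood gain
    falls below ``tol_loglik``.  Monotone likelihood (perfect separation)
    surfaces as non-convergence at the iteration cap; ``on_fail="flag"``
    returns the fit with ``converged=False`` instead of raising.
    """
    if data.event.sum() < 1:
        raise SurvivalError("need at least one event to fit a Cox model")
    _check_rank(data.covariates, data.names)
    p = data.covariates.shape[1]
    beta = np.zeros(p)
    ll, U, H = cox_loglik_grad_hess(data, beta, ties)
    ll_null = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-H, U)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-H, U, rcond=None)[0]
        # step-halving: the partial likelihood must not decrease
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, U_new, H_new = cox_loglik_grad_hess(data, cand, ties)
            if ll_new >= ll - 1e-14:
                break
            scale /= 2
        gain = ll_new - ll
        beta, ll, U, H = cand, ll_new, U_new, H_new
        if np.max(np.abs(beta)) > 20:
            # monotone likelihood: the score flattens while beta runs away,
            # so magnitude is the only reliable tell
            break
        if np.max(np.abs(U)) < tol_score or (0 <= gain < tol_loglik):
            converged = True
            break
    if not converged or np.max(np.abs(beta)) > 20:
        if on_fail == "raise":
            raise ConvergenceError(
                f"Cox fit did not converge in {max_iter} iterations "
                "(possible monotone likelihood / perfect separation)"
            )
        converged = False
    cov = np.linalg.pinv(-H)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return CoxFit(names=list(data.names), beta=beta, se=se, loglik=float(ll),
                  loglik_null=float(ll_null), ties=ties, converged=converged, n_iter=it)


def match_samples(expr: ExpressionMatrix, clinical: ClinicalCohort) -> list[str]:
    common = [s for s in clinical.sample_ids if s in set(expr.sample_ids)]
    if not common:
        raise SurvivalError("expression and clinical tables share no sample ids")
    return common


def univariate_cox_screen(expr: ExpressionMatrix, clinical: ClinicalCohort,
                          alpha: float = 0.1, ties: str = "breslow"):
    """One single-covariate Cox fit per feature; keep Wald p < alpha.

    Returns ``(kept_feature_ids, fits)`` where ``fits`` maps every feature id
    to its :class:`CoxFit` (constant features are skipped and map to None).
    """
    common = match_samples(expr, clinical)
    clin = clinical.subset(common)
    kept, fits = [], {}
    for fid in expr.feature_ids:
        x = expr.values_for(common, [fid])[:, 0]
        if np.isnan(x).any() or np.std(x) < 1e-12:
            fits[fid] = None
            continue
        data = SurvivalData(clin.time, clin.event, x[:, None], [fid])
        fit = fit_cox(data, ties=ties, on_fail="flag")
        fits[fid] = fit
        if fit.p[0] < alpha:
            kept.append(fid)
    return kept, fits


def fit_interaction_cox(data_time, data_event, factor_a, factor_b,
                        names=("a", "b"), ties: str = "breslow") -> CoxFit:
    """Cox model with binary main effects a, b and their product a*b.

    The interaction row is named ``"<a>:<b>"``.  An empty cell in the 2x2
    factor table makes the product collinear; the resulting rank error names
    the product term.
    """
    a = np.asarray(factor_a, dtype=float)
    b = np.asarray(factor_b, dtype=float)
    for arr, nm in ((a, names[0]), (b, names[1])):
        if not np.isin(arr, [0, 1]).all():
            raise SurvivalError(f"factor {nm!r} must be binary 0/1 coded")
    cells = {(int(x), int(y)) for x, y in zip(a, b)}
    if len(cells) < 4:
        missing = sorted(set((i, j) for i in (0, 1) for j in (0, 1)) - cells)
        raise RankDeficientError([f"{names[0]}:{names[1]} (empty cell(s) {missing})"])
    X = np.column_stack([a, b, a * b])
    data = SurvivalData(data_time, data_event, X,
                        [names[0], names[1], f"{names[0]}:{names[1]}"])
    return fit_cox(data, ties=ties)


@dataclasses.dataclass
class KMCurve:
    """Kaplan–Meier product-limit estimate for one group."""

    times: np.ndarray          # distinct event times
    n_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray       # S(t) just after each event time
    variance: np.ndarray       # Greenwood variance of S(t)
    median: float | None
    median_ci: tuple[float | None, float | None]
    label: str = ""

    def evaluate(self, t) -> np.ndarray:
        """Step-function value S(t) (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out if out.size > 1 else out


def _km_single(time, event, label="") -> KMCurve:
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    utimes, starts = np.unique(t, return_index=True)
    n = t.size
    times, n_risk, n_ev = [], [], []
    for u in utimes:
        at_risk = int(np.sum(t >= u))
        dd = int(np.sum(d[t == u]))
        if dd > 0:
            times.append(u)
            n_risk.append(at_risk)
            n_ev.append(dd)
    times = np.array(times)
    n_risk = np.array(n_risk, dtype=float)
    n_ev = np.array(n_ev, dtype=float)
    frac = 1.0 - n_ev / n_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(n_ev / (n_risk * (n_risk - n_ev)))
    gw = np.where(np.isfinite(gw), gw, np.inf)
    with np.errstate(invalid="ignore"):
        var = np.where(surv > 0, surv**2 * gw, 0.0)

    # log(-log) pointwise CI for S(t), then invert for the median CI
    with np.errstate(divide="ignore", invalid="ignore"):
        se_cloglog = np.sqrt(gw) / np.abs(np.log(surv))
        lo = surv ** np.exp(Z_95 * se_cloglog)
        hi = surv ** np.exp(-Z_95 * se_cloglog)
    lo = np.where(surv <= 0, 0.0, np.where(np.isfinite(lo), lo, 0.0))
    hi = np.where(surv <= 0, 0.0, np.where(np.isfinite(hi), hi, 1.0))

    def _first_leq(values, level):
        idx = np.flatnonzero(values <= level)
        return float(times[idx[0]]) if idx.size else None

    median = _first_leq(surv, 0.5)
    median_lo = _first_leq(lo, 0.5)
    median_hi = _first_leq(hi, 0.5)
    return KMCurve(times=times, n_risk=n_risk.astype(int), n_events=n_ev.astype(int),
                   survival=surv, variance=var, median=median,
                   median_ci=(median_lo, median_hi), label=label)


def km_estimate(time, event, groups=None) -> dict[str, KMCurve]:
    """Kaplan–Meier curve per group (single group "all" when groups=None)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if groups is None:
        return {"all": _km_single(time, event, "all")}
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise SurvivalError(f"group {g!r} is empty")
        out[str(g)] = _km_single(time[mask], event[mask], str(g))
    return out


@dataclasses.dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float
    observed: np.ndarray
    expected: np.ndarray
    groups: list[str]


def logrank_test(time, event, groups) -> LogRankResult:
    """Unweighted log-rank chi-square over G groups, df = G - 1."""
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    g = np.asarray(groups)
    labels = list(pd.unique(g))
    G = len(labels)
    if G < 2:
        raise SurvivalError("log-rank test needs at least two groups")
    if d.sum() < 1:
        raise SurvivalError("log-rank test needs at least one event")
    gidx = np.array([labels.index(x) for x in g])
    obs = np.zeros(G)
    exp = np.zeros(G)
    V = np.zeros((G, G))
    for u in np.unique(t[d == 1]):
        at_risk = t >= u
        n_s = at_risk.sum()
        d_s = int(((t == u) & (d == 1)).sum())
        n_gs = np.bincount(gidx[at_risk], minlength=G).astype(float)
        d_gs = np.bincount(gidx[(t == u) & (d == 1)], minlength=G).astype(float)
        obs += d_gs
        exp += d_s * n_gs / n_s
        if n_s > 1:
            c = d_s * (n_s - d_s) / (n_s - 1)
            V += c * (np.diag(n_gs * n_s) - np.outer(n_gs, n_gs)) / n_s**2
    diff = (obs - exp)[:-1]
    Vsub = V[:-1, :-1]
    stat = float(diff @ np.linalg.pinv(Vsub) @ diff) if diff.size else 0.0
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, G - 1))
    return LogRankResult(statistic=stat, df=G - 1, p=p,
                         observed=obs, expected=exp, groups=[str(x) for x in labels])


def posthoc_power(hr: float, n_events: int, group_fraction: float = 0.5,
                  alpha: float = 0.05) -> float:
    """Schoenfeld-approximation power of a two-group log-rank comparison.

    power = Phi(|ln HR| * sqrt(d * p * (1-p)) - z_{1-alpha/2}) with d the
    observed number of events and p the fraction in one group.
    """
    if hr <= 0:
        raise SurvivalError("hazard ratio must be positive")
    if n_events < 1:
        raise SurvivalError("need at least one event for a power calculation")
    if not 0 < group_fraction < 1:
        raise SurvivalError("group_fraction must lie in (0,1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    arg = abs(np.log(hr)) * np.sqrt(n_events * group_fraction * (1 - group_fraction)) - z_a
    return float(stats.norm.cdf(arg))
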