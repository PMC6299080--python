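"""Risk-signature construction and evaluation.

Refits an unpenalized Cox model on the selected features, scores patients
by the linear predictor, dichotomizes at the training-set median risk
score, and evaluates: Kaplan–Meier by risk group with the log-rank test,
response-by-risk contingency analysis with progressive rates, interaction
Cox models, and time-dependent ROC AUC with inverse-probability-of-
censoring weighting.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalCohort, ExpressionMatrix, MirsigError, RESPONSE_LEVELS, write_json, read_json
from .survival import (CoxFit, KMCurve, LogRankResult, SurvivalData, fit_cox,
                       km_estimate, logrank_test, match_samples)


class SignatureError(MirsigError):
    pass


@dataclasses.dataclass
class RiskSignature:
    """Selected features, their refit Cox coefficients and the training
    median cutoff used to dichotomize every cohort."""

    feature_ids: list[str]
    coefficients: np.ndarray
    cutoff: float
    ties_method: str = "breslow"
    training_cohort: str = "training"
    created_from: str | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.feature_ids) != self.coefficients.size:
            raise SignatureError("feature/coefficient length mismatch")

    def to_dict(self) -> dict:
        return {
            "features": list(self.feature_ids),
            "coefficients": [float(c) for c in self.coefficients],
            "cutoff": float(self.cutoff),
            "ties_method": self.ties_method,
            "training_cohort": self.training_cohort,
            "created_from": self.created_from,
        }

    def save(self, path) -> None:
        write_json(self.to_dict(), path)

    @classmethod
    def load(cls, path) -> "RiskSignature":
        d = read_json(path)
        return cls(feature_ids=d["features"], coefficients=np.array(d["coefficients"]),
                   cutoff=d["cutoff"], ties_method=d.get("ties_method", "breslow"),
                   training_cohort=d.get("training_cohort", "training"),
                   created_from=d.get("created_from"))


def fit_signature(expr: ExpressionMatrix, clinical: ClinicalCohort, features,
                  ties: str = "breslow") -> tuple[RiskSignature, CoxFit]:
    """Unpenalized multi-feature Cox refit on the training cohort.

    The cutoff is the exact median of the training risk scores.
    """
    features = list(features)
    common = match_samples(expr, clinical)
    clin = clinical.subset(common)
    data = SurvivalData.from_cohort(clin, expr, feature_ids=features)
    fit = fit_cox(data, ties=ties)
    scores = data.covariates @ fit.beta
    cutoff = float(np.median(scores))
    sig = RiskSignature(feature_ids=features, coefficients=fit.beta, cutoff=cutoff,
                        ties_method=ties, training_cohort=clinical.name)
    return sig, fit


def risk_score(signature: RiskSignature, values) -> np.ndarray | float:
    """Linear risk score sum_j beta_j x_j.

    ``values`` may be a mapping {feature: value} for one patient (returns a
    scalar), or an :class:`ExpressionMatrix` (returns a Series over
    samples).  A missing feature raises, naming the feature.
    """
    if isinstance(values, ExpressionMatrix):
        missing = [f for f in signature.feature_ids if f not in values.data.index]
        if missing:
            raise SignatureError(f"expression matrix lacks signature feature(s): {missing}")
        block = values.data.loc[signature.feature_ids]
        if block.isna().to_numpy().any():
            bad = block.columns[block.isna().any(axis=0)][0]
            raise SignatureError(f"missing signature value(s) for sample {bad!r}")
        scores = signature.coefficients @ block.to_numpy(float)
        return pd.Series(scores, index=values.sample_ids)
    missing = [f for f in signature.feature_ids if f not in values]
    if missing:
        raise SignatureError(f"missing value for signature feature(s): {missing}")
    return float(sum(b * float(values[f])
                     for f, b in zip(signature.feature_ids, signature.coefficients)))


@dataclasses.dataclass
class RiskAssignment:
    """Per-patient risk score and low/high group under a fixed cutoff."""

    sample_ids: list[str]
    scores: np.ndarray
    groups: np.ndarray   # "low" / "high"
    cutoff: float
    cohort: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.scores, "group": self.groups},
                            index=self.sample_ids)


def classify_risk(scores, cutoff: float, sample_ids=None, cohort: str = "") -> RiskAssignment:
    """Dichotomize risk scores: score > cutoff is high risk, <= cutoff low.

    A patient sitting exactly on the cutoff (the training median itself for
    odd-sized cohorts) goes to the low-risk group.
    """
    if isinstance(scores, pd.Series):
        sample_ids = list(scores.index)
        scores = scores.to_numpy(float)
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(cutoff):
        raise SignatureError("cutoff must be finite")
    if not np.isfinite(scores).all():
        raise SignatureError("risk scores must be finite")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(scores.size)]
    groups = np.where(scores > cutoff, "high", "low")
    return RiskAssignment(sample_ids=list(sample_ids), scores=scores, groups=groups,
                          cutoff=float(cutoff), cohort=cohort)


def evaluate_km_by_risk(assignment: RiskAssignment, clinical: ClinicalCohort):
    """KM curve per risk group plus the two-group log-rank test."""
    clin = clinical.subset(assignment.sample_ids)
    for g in ("low", "high"):
        if not (assignment.groups == g).any():
            raise SignatureError(f"risk group {g!r} is empty")
    curves = km_estimate(clin.time, clin.event, assignment.groups)
    lr = logrank_test(clin.time, clin.event, assignment.groups)
    return curves, lr


@dataclasses.dataclass
class ContingencyResult:
    """Response-by-risk-group cross-tabulation with an independence test."""

    counts: pd.DataFrame        # rows: response categories; cols: low, high
    statistic: float
    p: float
    method: str                 # "chi-square" or "fisher"

    @property
    def proportions(self) -> pd.DataFrame:
        return self.counts / self.counts.sum(axis=0)


def chisq_or_fisher(table) -> tuple[float, float, str]:
    """Pearson chi-square (no continuity correction); Fisher exact for a
    2x2 table whenever any expected cell count is below 5."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise SignatureError("contingency table must hold non-negative integer counts")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise SignatureError("degenerate contingency table: an all-zero margin")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()
    if counts.shape == (2, 2) and (expected < 5).any():
        stat, p = stats.fisher_exact(counts.astype(int))
        return float(stat), float(p), "fisher"
    stat, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), float(p), "chi-square"


def response_by_risk(clinical: ClinicalCohort, assignment: RiskAssignment,
                     collapse_cr_pr: bool = True) -> ContingencyResult:
    """Cross-tabulate best response against risk group.

    ``collapse_cr_pr`` merges CR and PR into one responder row, the usual
    reporting convention.
    """
    clin = clinical.subset(assignment.sample_ids)
    if "response" not in clin.table.columns:
        raise SignatureError("clinical table lacks a response column")
    resp = clin.table["response"]
    levels = (["CR+PR", "SD", "PD"] if collapse_cr_pr else list(RESPONSE_LEVELS))
    mapped = resp.map(lambda r: "CR+PR" if collapse_cr_pr and r in ("CR", "PR") else r)
    counts = pd.DataFrame(0, index=levels, columns=["low", "high"], dtype=int)
    for lev in levels:
        for grp in ("low", "high"):
            counts.loc[lev, grp] = int(((mapped == lev) & (assignment.groups == grp)).sum())
    # empty categories carry no information; test on the occupied rows
    occupied = counts.loc[counts.sum(axis=1) > 0]
    if len(occupied) >= 2 and (occupied.sum(axis=0) > 0).all():
        stat, p, method = chisq_or_fisher(occupied.to_numpy())
    else:
        stat, p, method = float("nan"), float("nan"), "undefined"
    return ContingencyResult(counts=counts, statistic=stat, p=p, method=method)


def progressive_rate(contingency: ContingencyResult) -> dict:
    """Share of progressive disease (PD) per risk group.

    Returns exact fractions plus display percentages rounded to 2 decimals.
    """
    if "PD" not in contingency.counts.index:
        raise SignatureError("contingency table has no PD row")
    out = {}
    for grp in contingency.counts.columns:
        total = int(contingency.counts[grp].sum())
        if total == 0:
            raise SignatureError(f"risk group {grp!r} is empty")
        pd_count = int(contingency.counts.loc["PD", grp])
        frac = pd_count / total
        out[grp] = {"pd": pd_count, "n": total, "fraction": frac,
                    "percent": round(100.0 * frac, 2)}
    return out


@dataclasses.dataclass
class TDROCResult:
    """Time-dependent cumulative/dynamic AUC at evaluation time t."""

    t: float
    auc: float
    estimator: str
    ci: tuple[float, float] | None = None
    n_cases: int = 0
    n_controls: int = 0


def _censoring_km(time, event):
    """KM of the censoring distribution G(t) (events flipped)."""
    curves = km_estimate(time, 1 - np.asarray(event, dtype=int))
    return curves["all"]


def _auc_at(scores, time, event, t, estimator):
    cases = (time <= t) & (event == 1)
    controls = time > t
    if cases.sum() < 1 or controls.sum() < 1:
        return None
    if estimator == "ipcw":
        G = _censoring_km(time, event)
        # left limit G(T-): evaluate just below each case's event time
        gvals = G.evaluate(np.asarray(time)[cases] * (1 - 1e-12))
        w = 1.0 / np.clip(np.atleast_1d(gvals), 1e-12, None)
    elif estimator == "naive":
        w = np.ones(int(cases.sum()))
    else:
        raise SignatureError(f"unknown estimator {estimator!r}")
    sc = np.asarray(scores, dtype=float)
    s_case = sc[cases]
    s_ctrl = sc[controls]
    gt = (s_case[:, None] > s_ctrl[None, :]).sum(axis=1)
    eq = (s_case[:, None] == s_ctrl[None, :]).sum(axis=1)
    num = float(np.sum(w * (gt + 0.5 * eq)))
    den = float(np.sum(w) * s_ctrl.size)
    return num / den


def td_auc(scores, time, event, t: float, estimator: str = "ipcw",
           n_boot: int = 200, seed=0) -> TDROCResult:
    """Cumulative/dynamic AUC(t) for a risk score under right censoring.

    Cases are subjects with an observed event by t, controls those still at
    risk after t; cases are weighted by 1/G(T-) with G the Kaplan–Meier
    estimate of the censoring distribution (the constant control weight
    1/G(t) cancels in the ratio).  The CI is a percentile bootstrap over
    patients.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if t <= 0 or t >= time.max():
        raise SignatureError("evaluation time must lie within observed follow-up")
    auc = _auc_at(scores, time, event, t, estimator)
    if auc is None:
        raise SignatureError(f"no cases or no controls by t={t}")
    cases = int(((time <= t) & (event == 1)).sum())
    controls = int((time > t).sum())
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(n_boot):
            idx = rng.integers(0, time.size, time.size)
            v = _auc_at(scores[idx], time[idx], event[idx], t, estimator)
            if v is not None:
                vals.append(v)
        if len(vals) >= 20:
            ci = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
    return TDROCResult(t=float(t), auc=float(auc), estimator=estimator, ci=ci,
                       n_cases=cases, n_controls=controls)
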