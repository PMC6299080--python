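"""Paired tumour-vs-normal differential expression screen.

Implements the classical paired t-test, an empirical-Bayes moderated t
(per-feature variances shrunk toward a common prior estimated by the method
of moments on log sample variances), and Benjamini–Hochberg FDR control.

The moderated statistic assumes the hierarchical model

    s_g^2 | sigma_g^2  ~  sigma_g^2 * chi^2_{d_g} / d_g
    1 / sigma_g^2      ~  chi^2_{d0} / (d0 * s0^2)

under which the posterior variance is the precision-weighted blend

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t = mean_diff / (s~_g / sqrt(n)) has d0 + d_g degrees of
freedom.  (d0, s0^2) are estimated by matching the first two moments of
log s_g^2, whose mean and variance have closed forms in the digamma and
trigamma functions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionMatrix, MirsigError


class DEError(MirsigError):
    pass


@dataclasses.dataclass
class DEResult:
    """Per-feature paired differential-expression statistics.

    ``table`` columns: mean_diff, s2 (raw sample variance of differences),
    t, p, q (BH-adjusted), direction (+1 up in tumour, -1 down, 0 flat),
    zero_variance flag, and after moderation: s2_mod, t_mod, p_mod, q_mod.
    ``d0`` / ``s0_sq`` are the estimated prior degrees of freedom and prior
    variance (d0 may be ``inf`` when the variances are homogeneous).
    """

    table: pd.DataFrame
    n_pairs: int
    d0: float | None = None
    s0_sq: float | None = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)


def paired_differences(expr: ExpressionMatrix, pairing: dict[str, tuple[str, str]]) -> pd.DataFrame:
    """Tumour-minus-normal log difference per feature (rows) and pair (cols)."""
    samples = set(expr.sample_ids)
    for pid, (tum, nor) in pairing.items():
        missing = [s for s in (tum, nor) if s not in samples]
        if missing:
            raise DEError(f"pair {pid!r} is missing sample(s) {missing}")
    tum_cols = [t for t, _ in pairing.values()]
    nor_cols = [n for _, n in pairing.values()]
    diffs = expr.data[tum_cols].to_numpy(float) - expr.data[nor_cols].to_numpy(float)
    return pd.DataFrame(diffs, index=expr.data.index, columns=list(pairing))


def paired_t(expr: ExpressionMatrix, pairing: dict[str, tuple[str, str]]) -> DEResult:
    """Classical paired two-sided t-test per feature, df = n_pairs - 1.

    Features whose differences have zero variance get p = 1 and a
    ``zero_variance`` flag rather than an infinite statistic.
    """
    if len(pairing) < 3:
        raise DEError("need at least 3 pairs for a paired t-test")
    diffs = paired_differences(expr, pairing)
    d = diffs.to_numpy(float)
    n = d.shape[1]
    mean = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    zero = s2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s2 / n)
    df = n - 1
    p = 2 * stats.t.sf(np.abs(t), df)
    t = np.where(zero, 0.0, t)
    p = np.where(zero, 1.0, p)
    table = pd.DataFrame(
        {
            "mean_diff": mean,
            "s2": s2,
            "t": t,
            "p": p,
            "direction": np.sign(mean).astype(int),
            "zero_variance": zero,
        },
        index=diffs.index,
    )
    table["q"] = bh_fdr(table["p"].to_numpy())
    return DEResult(table=table, n_pairs=n)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        step = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from sample variances with df each.

    Matches the mean and variance of e_g = log s_g^2 - digamma(df/2) +
    log(df/2); returns d0 = inf when the observed spread of log-variances is
    no larger than the chi-square sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise DEError("need at least 2 features with positive variance")
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1)
    excess = evar - special.polygamma(1, df / 2)
    if excess <= 0:
        return float("inf"), float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_sq


def moderated_t(de: DEResult, d0: float | None = None, s0_sq: float | None = None) -> DEResult:
    """Add empirical-Bayes moderated statistics to a paired-t result.

    ``d0``/``s0_sq`` may be forced (mainly for the analytic limits d0 = 0,
    reproducing the raw t, and d0 = inf, a fully pooled variance); by default
    they are estimated from the positive sample variances.
    """
    table = de.table.copy()
    s2 = table["s2"].to_numpy(float)
    ok = s2 > 0
    if not ok.any():
        raise DEError("all features have zero variance; cannot moderate")
    df = de.n_pairs - 1
    if d0 is None or s0_sq is None:
        d0_est, s0_est = estimate_variance_prior(s2[ok], df)
        d0 = d0_est if d0 is None else d0
        s0_sq = s0_est if s0_sq is None else s0_sq
    if np.isinf(d0):
        s2_mod = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_mod = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    n = de.n_pairs
    mean = table["mean_diff"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = mean / np.sqrt(s2_mod / n)
    zero = ~ok & (s2_mod <= 0)
    t_mod = np.where(zero, 0.0, t_mod)
    p_mod = np.where(zero, 1.0, 2 * stats.t.sf(np.abs(t_mod), df_total))
    table["s2_mod"] = s2_mod
    table["t_mod"] = t_mod
    table["p_mod"] = p_mod
    table["q_mod"] = bh_fdr(p_mod)
    return DEResult(table=table, n_pairs=de.n_pairs, d0=float(d0), s0_sq=float(s0_sq))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j, mapped back to input order and
    clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise DEError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DEError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_de(de: DEResult, alpha: float = 0.05, use_fdr: bool = True, moderated: bool = True) -> dict:
    """Threshold a DE result into up/down feature sets.

    Returns ``{"up": [...], "down": [...], "all": [...]}`` with feature ids
    ordered as in the input table.  ``use_fdr`` switches between the BH
    q-value and the raw p-value column.
    """
    table = de.table
    if moderated and "p_mod" in table:
        col = "q_mod" if use_fdr else "p_mod"
    else:
        col = "q" if use_fdr else "p"
    hit = table[col].to_numpy(float) < alpha
    up = list(table.index[hit & (table["direction"] > 0)])
    down = list(table.index[hit & (table["direction"] < 0)])
    return {"up": up, "down": down, "all": list(table.index[hit])}


def de_screen(expr: ExpressionMatrix, pairing, alpha: float = 0.05, use_fdr: bool = True) -> tuple[DEResult, dict]:
    """Full stage-1 screen: paired t -> moderated t -> thresholded call."""
    de = moderated_t(paired_t(expr, pairing))
    return de, call_de(de, alpha=alpha, use_fdr=use_fdr)
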