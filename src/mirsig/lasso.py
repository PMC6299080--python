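"""Bootstrap-stability feature selection by L1-penalized Cox regression.

The selection procedure: qRT-PCR-scale normalization, a LASSO Cox
coefficient path solved by proximal Newton with coordinate-wise
soft-thresholding on the quadratic model, per-resample 10-fold
cross-validated partial-likelihood deviance with the 1-SE rule, B bootstrap
resamples, and the resample model inclusion proportion (RMIP) — the
fraction of resamples in which a feature carries a nonzero coefficient at
the CV-selected lambda.

Objective (features standardized internally, coefficients reported on the
original scale):

    minimize  -(1/n) * l_Breslow(beta)  +  lambda * sum_j |beta_j|

The path runs over a log-spaced grid from lambda_max = max_j |(1/n) U_j(0)|
down to lambda_max * min_ratio; solutions are warm-started and the exact KKT
stationarity conditions are verified at every grid point.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._cdnet import breslow_loglik_grid, cox_breslow_quantities, lasso_cox_path_kernel
from .io import ExpressionMatrix, MirsigError


class SelectionError(MirsigError):
    pass


class CVError(SelectionError):
    """Cross-validation could not be carried out (degenerate folds)."""


def normalize_qpcr(values):
    """Map relative qRT-PCR expression (2^-dCt) to a readable log scale.

    x' = log2(10000 * x), i.e. log2(10000) - dCt.  Accepts an ndarray or an
    :class:`ExpressionMatrix` (returned with scale="log").  Zero or negative
    entries are reported with their row/column address.
    """
    if isinstance(values, ExpressionMatrix):
        arr = values.data.to_numpy(dtype=float)
        bad = np.argwhere(~(arr > 0))
        if bad.size:
            r, c = bad[0]
            raise SelectionError(
                f"non-positive expression value {arr[r, c]!r} at feature "
                f"{values.data.index[r]!r}, sample {values.data.columns[c]!r}"
            )
        out = values.data.copy()
        out.loc[:, :] = np.log2(10000.0 * arr)
        return ExpressionMatrix(out, scale="log")
    arr = np.asarray(values, dtype=float)
    bad = np.argwhere(~(np.atleast_2d(arr) > 0))
    if bad.size:
        r, c = bad[0]
        raise SelectionError(f"non-positive expression value at position ({r}, {c})")
    return np.log2(10000.0 * arr)


def _prepare(time, event):
    """Sort by ascending time; build tie-group first/last index arrays."""
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=np.int64)
    order = np.argsort(t, kind="stable")
    ts, ds = t[order], d[order]
    n = ts.size
    grp_first = np.empty(n, dtype=np.int64)
    grp_last = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        grp_first[i:j + 1] = i
        grp_last[i:j + 1] = j
        i = j + 1
    return order, ds, grp_first, grp_last


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd < 1e-12, 1.0, sd)
    Xs = (X - mu) / sd_safe
    Xs[:, sd < 1e-12] = 0.0
    return Xs, mu, sd_safe


def breslow_loglik(time, event, eta) -> float:
    """Unscaled Breslow log partial likelihood at linear predictor eta."""
    order, ds, gf, gl = _prepare(time, event)
    eta = np.asarray(eta, dtype=float)[order]
    ll, _, _ = cox_breslow_quantities(eta, ds, gf, gl)
    return float(ll)


@dataclasses.dataclass
class LassoPath:
    """Coefficient path of the L1-penalized Cox model."""

    feature_names: list[str]
    lambdas: np.ndarray          # descending grid
    coefs: np.ndarray            # K x p, original scale
    coefs_std: np.ndarray        # K x p, standardized scale
    lambda_max: float
    kkt_residual: np.ndarray     # exact stationarity residual per lambda
    n_iter: np.ndarray

    @property
    def df(self) -> np.ndarray:
        """Nonzero-coefficient count per lambda."""
        return (self.coefs_std != 0).sum(axis=1)

    def coefs_at(self, lam: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.lambdas - lam)))
        return self.coefs[idx]


def lambda_grid(lambda_max: float, K: int, min_ratio: float) -> np.ndarray:
    return np.geomspace(lambda_max, lambda_max * min_ratio, K)


def lasso_cox_path(time, event, X, feature_names=None, K: int = 100,
                   min_ratio: float = 0.01, lambdas=None,
                   kkt_tol: float = 1e-7, max_outer: int = 50,
                   max_inner: int = 300, beta_bound: float = 30.0,
                   dev_tol: float = 0.0, dfmax: int = 0,
                   on_failure: str = "raise") -> LassoPath:
    """Solve the LASSO Cox path over a descending lambda grid.

    Features are standardized internally; coefficients are returned both on
    the standardized and on the original scale.  At small lambda the
    penalized optimum can be unbounded (monotone likelihood, frequent on
    bootstrap resamples with duplicated subjects); ``on_failure="raise"``
    reports the offending lambda index, ``"truncate"`` returns the solved
    prefix of the grid, as penalized-regression path software customarily
    does.  ``dev_tol > 0`` additionally terminates the path once the
    relative likelihood gain between consecutive grid points falls below it
    (a saturated fit adds nothing to the cross-validation curve).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    if np.asarray(event).sum() < 1:
        raise SelectionError("need at least one event")
    order, ds, gf, gl = _prepare(time, event)
    Xs, mu, sd = _standardize(X)
    Xo = np.ascontiguousarray(Xs[order])
    # score at beta = 0 gives lambda_max
    _, grad0, _ = cox_breslow_quantities(np.zeros(n), ds, gf, gl)
    g0 = Xo.T @ grad0 / n
    lam_max = float(np.max(np.abs(g0)))
    if lambdas is None:
        if lam_max <= 0:
            raise SelectionError("no signal: the score at beta=0 is zero for every feature")
        lambdas = lambda_grid(lam_max, K, min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    betas, kkt, iters = lasso_cox_path_kernel(Xo, ds, gf, gl, lambdas,
                                              kkt_tol, max_outer, max_inner,
                                              beta_bound, dev_tol, dfmax)
    if (iters == -2).any():   # benign saturation stop
        k_sat = int(np.flatnonzero(iters == -2)[0])
        lambdas = lambdas[:k_sat]
        betas, kkt, iters = betas[:k_sat], kkt[:k_sat], iters[:k_sat]
    if (iters == -1).any():
        k_bad = int(np.flatnonzero(iters == -1)[0])
        if on_failure == "raise" or k_bad == 0:
            raise SelectionError(
                f"coordinate descent did not reach the KKT tolerance at lambda "
                f"index {k_bad} (lambda={lambdas[k_bad]:.4g})"
            )
        lambdas = lambdas[:k_bad]
        betas, kkt, iters = betas[:k_bad], kkt[:k_bad], iters[:k_bad]
    coefs = betas / sd  # back-transform to original scale
    return LassoPath(feature_names=list(feature_names), lambdas=lambdas,
                     coefs=coefs, coefs_std=betas, lambda_max=lam_max,
                     kkt_residual=kkt, n_iter=iters)


@dataclasses.dataclass
class CVResult:
    """Cross-validated deviance curve and the 1-SE lambda choice."""

    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    lambda_min: float
    lambda_1se: float
    index_1se: int
    selected: list[str]          # nonzero features of the full-data path at lambda_1se
    coef_1se: np.ndarray         # original-scale coefficients at lambda_1se
    fold_assignment: np.ndarray
    path: LassoPath


def _deal_folds(n, folds, rng) -> np.ndarray:
    perm = rng.permutation(n)
    assign = np.empty(n, dtype=np.int64)
    assign[perm] = np.arange(n) % folds
    return assign


def cv_lasso(time, event, X, feature_names=None, folds: int = 10, seed=0,
             K: int = 100, min_ratio: float = 0.01,
             dev_tol: float = 1e-5, dfmax: int | None = None) -> CVResult:
    """K-fold cross-validated LASSO Cox with the 1-SE rule.

    Per-fold deviance is the Verweij–Van Houwelingen cross-validated partial
    likelihood: dev_k = -2 * (l_full(beta_{-k}) - l_{-k}(beta_{-k})),
    computed over the lambda grid of the full-data path.  Fold deviances
    are normalized by the fold's event count and averaged with event-count
    weights (as penalized-Cox CV software conventionally does — otherwise
    the fold-to-fold variation in event totals swamps the SE and the 1-SE
    rule degenerates).  lambda_1SE is the largest lambda whose mean
    deviance is within one standard error of the minimum.  A fold deal
    that leaves a training set without events is re-dealt once.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=np.int64)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    if folds < 2:
        raise CVError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    if dfmax is None:
        # CV never picks a model denser than ~ one coefficient per three
        # events (EPV heuristic); capping the path there skips the
        # expensive saturated tail without touching the 1-SE choice.
        # Irrelevant (disabled) when the panel is no larger than the cap.
        dfmax = int(max(5, event.sum() // 3))
        if dfmax >= X.shape[1]:
            dfmax = 0
    path = lasso_cox_path(time, event, X, feature_names, K=K,
                          min_ratio=min_ratio, dev_tol=dev_tol, dfmax=dfmax,
                          on_failure="truncate")
    lambdas = path.lambdas

    assign = None
    for _ in range(2):
        cand = _deal_folds(n, folds, rng)
        ok = all(event[cand != k].sum() >= 1 and (cand == k).sum() >= 1
                 for k in range(folds))
        if ok:
            assign = cand
            break
    if assign is None:
        raise CVError("could not deal folds with at least one event per training set")

    order_all, d_all, gf_all, gl_all = _prepare(time, event)
    sub_coefs = []
    n_lam = lambdas.size
    for k in range(folds):
        tr = assign != k
        # fold fits only feed the deviance curve; a looser KKT tolerance is
        # plenty and roughly halves the Newton work
        sub = lasso_cox_path(time[tr], event[tr], X[tr], feature_names,
                             lambdas=lambdas, dev_tol=dev_tol, dfmax=dfmax,
                             kkt_tol=1e-5, on_failure="truncate")
        sub_coefs.append(sub.coefs)
        n_lam = min(n_lam, sub.lambdas.size)
    if n_lam < 2:
        raise CVError("penalized path collapsed on the training folds")
    lambdas = lambdas[:n_lam]
    devs = np.empty((folds, n_lam))
    for k in range(folds):
        tr = assign != k
        etas = X @ sub_coefs[k][:n_lam].T          # n x n_lam
        ll_all = breslow_loglik_grid(np.ascontiguousarray(etas[order_all]),
                                     d_all, gf_all, gl_all)
        o_tr, d_tr, gf_tr, gl_tr = _prepare(time[tr], event[tr])
        etas_tr = etas[tr]
        ll_tr = breslow_loglik_grid(np.ascontiguousarray(etas_tr[o_tr]),
                                    d_tr, gf_tr, gl_tr)
        devs[k] = -2.0 * (ll_all - ll_tr)
    # event-weighted deviance-per-event across folds (glmnet convention)
    ev_w = np.array([event[assign == k].sum() for k in range(folds)], dtype=float)
    ok = ev_w > 0
    if ok.sum() < 2:
        raise CVError("fewer than two folds contain events")
    per_event = devs[ok] / ev_w[ok, None]
    w = ev_w[ok] / ev_w[ok].sum()
    mean_dev = w @ per_event
    se_dev = np.sqrt((w @ (per_event - mean_dev) ** 2) / (ok.sum() - 1))
    i_min = int(np.argmin(mean_dev))
    thresh = mean_dev[i_min] + se_dev[i_min]
    i_1se = int(np.flatnonzero(mean_dev <= thresh + 1e-12)[0])  # largest lambda
    coef = path.coefs[i_1se]
    selected = [f for f, c in zip(path.feature_names, path.coefs_std[i_1se]) if c != 0.0]
    return CVResult(lambdas=lambdas, mean_deviance=mean_dev, se_deviance=se_dev,
                    lambda_min=float(lambdas[i_min]), lambda_1se=float(lambdas[i_1se]),
                    index_1se=i_1se, selected=selected, coef_1se=coef,
                    fold_assignment=assign, path=path)


@dataclasses.dataclass
class RMIPTable:
    """Per-feature resample model inclusion proportion over B resamples."""

    table: pd.DataFrame          # index feature_id; columns rmip, count, B, rank
    B: int
    n_redrawn: int = 0

    @property
    def rmip(self) -> pd.Series:
        return self.table["rmip"]

    def to_tsv(self, path) -> None:
        self.table.sort_values("rank").rename_axis("feature_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "RMIPTable":
        t = pd.read_csv(path, sep="\t", index_col="feature_id")
        return cls(table=t, B=int(t["B"].iloc[0]))


def _rank_rmip(counts: pd.Series, B: int) -> pd.DataFrame:
    table = pd.DataFrame({"count": counts.astype(int)})
    table["rmip"] = table["count"] / B
    table["B"] = B
    order = sorted(table.index, key=lambda f: (-table.loc[f, "rmip"], str(f)))
    table["rank"] = pd.Series({f: i + 1 for i, f in enumerate(order)})
    return table[["rmip", "count", "B", "rank"]]


def bag_lasso(time, event, X, feature_names=None, B: int = 1000,
              folds: int = 10, seed=0, K: int = 100, min_ratio: float = 0.01,
              max_degenerate_frac: float = 0.1) -> RMIPTable:
    """RMIP by LASSO-Cox bagging.

    For each of B resamples: draw n subjects with replacement (duplicates
    materialized as repeated rows), run :func:`cv_lasso` with a fresh fold
    deal, and record the nonzero set at lambda_1SE.  RMIP_j = count_j / B.
    Resamples whose CV degenerates are redrawn (counted); more than
    ``max_degenerate_frac * B`` redraws aborts.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=np.int64)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    if B < 1:
        raise SelectionError("B must be >= 1")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    counts = pd.Series(0, index=pd.Index(feature_names), dtype=int)
    n_redrawn = 0
    max_redraws = max(1, int(np.ceil(max_degenerate_frac * B)))
    done = 0
    while done < B:
        child = ss.spawn(1)[0]
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, n)
        try:
            cv = cv_lasso(time[idx], event[idx], X[idx], feature_names,
                          folds=folds, seed=child.spawn(1)[0], K=K,
                          min_ratio=min_ratio)
        except (CVError, SelectionError):
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise SelectionError(
                    f"more than {max_redraws} degenerate bootstrap resamples "
                    f"({n_redrawn} of {B}); data too sparse for bagging"
                )
            continue
        counts.loc[cv.selected] += 1
        done += 1
    return RMIPTable(table=_rank_rmip(counts, B), B=B, n_redrawn=n_redrawn)


def select_top_features(rmip: RMIPTable, k: int, elbow: bool = False):
    """Top-k features by descending RMIP (ties broken lexicographically).

    With ``elbow=True`` also returns the position of the largest consecutive
    RMIP drop as a suggested k.
    """
    table = rmip.table
    if k > len(table):
        raise SelectionError(f"k={k} exceeds the {len(table)} available features")
    if (table["rmip"] == 0).all():
        raise SelectionError("all RMIP values are zero: no feature was ever selected")
    ordered = table.sort_values("rank")
    top = list(ordered.index[:k])
    if not elbow:
        return top
    vals = ordered["rmip"].to_numpy()
    drops = vals[:-1] - vals[1:]
    suggestion = int(np.argmax(drops)) + 1 if drops.size else 1
    return top, suggestion
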