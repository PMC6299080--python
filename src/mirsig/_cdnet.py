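"""Numba kernels for the L1-penalized Cox path.

Subjects must be pre-sorted by ascending time.  ``grp_first[i]`` /
``grp_last[i]`` give the first / last index of subject i's tie group, so
risk-set sums and the Breslow event terms are O(n) per evaluation.

The path solver is a proximal-Newton method restricted to a working set:
features are screened by the sequential strong rule, the exact gradient and
Hessian of the (1/n)-scaled Breslow log partial likelihood are computed on
the working set only, the L1-penalized quadratic model is minimized by
cyclic coordinate descent with soft-thresholding, steps are safeguarded by
halving on the penalized objective, and the exact KKT stationarity
conditions over ALL features decide convergence (violators join the
working set).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def cox_breslow_quantities(eta, d, grp_first, grp_last):
    """Breslow log partial likelihood, per-subject gradient and diagonal
    Hessian weights of l(eta), for time-ascending-sorted subjects."""
    n = eta.shape[0]
    ex = np.exp(eta)
    suf = np.empty(n + 1)
    suf[n] = 0.0
    for i in range(n - 1, -1, -1):
        suf[i] = suf[i + 1] + ex[i]
    ll = 0.0
    c1 = np.zeros(n)
    c2 = np.zeros(n)
    for i in range(n):
        if d[i] == 1:
            s0 = suf[grp_first[i]]
            ll += eta[i] - np.log(s0)
            c1[i] = 1.0 / s0
            c2[i] = 1.0 / (s0 * s0)
    p1 = 0.0
    p2 = 0.0
    P1 = np.empty(n)
    P2 = np.empty(n)
    for i in range(n):
        p1 += c1[i]
        p2 += c2[i]
        P1[i] = p1
        P2[i] = p2
    grad = np.empty(n)
    w = np.empty(n)
    for i in range(n):
        a = P1[grp_last[i]]
        b = P2[grp_last[i]]
        grad[i] = d[i] - ex[i] * a
        w[i] = ex[i] * a - ex[i] * ex[i] * b
    return ll, grad, w


@njit(cache=True)
def breslow_loglik_grid(etas, d, grp_first, grp_last):
    """Breslow log partial likelihood for each column of etas (n x K)."""
    n, K = etas.shape
    out = np.empty(K)
    for k in range(K):
        ll, _, _ = cox_breslow_quantities(etas[:, k].copy(), d, grp_first, grp_last)
        out[k] = ll
    return out


@njit(cache=True)
def _ll_grad_hess_ws(X, eta, d, grp_first, grp_last, ws):
    """Unscaled Breslow ll, score and negative Hessian on working set ws.

    Accumulates risk-set sums from the latest time backwards, one tie group
    at a time; O(n * |ws|^2).
    """
    n = X.shape[0]
    m = ws.shape[0]
    # contiguous gather of the working-set block for cache-friendly loops
    Xw = np.empty((n, m))
    for i in range(n):
        for a in range(m):
            Xw[i, a] = X[i, ws[a]]
    ex = np.exp(eta)
    ll = 0.0
    U = np.zeros(m)
    A = np.zeros((m, m))
    S0 = 0.0
    S1 = np.zeros(m)
    S2 = np.zeros((m, m))
    i = n - 1
    while i >= 0:
        j = i
        while j >= 0 and grp_first[j] == grp_first[i]:
            j -= 1
        for k in range(j + 1, i + 1):
            e = ex[k]
            S0 += e
            for a in range(m):
                xa = e * Xw[k, a]
                S1[a] += xa
                for b in range(a, m):
                    S2[a, b] += xa * Xw[k, b]
        D = 0
        for k in range(j + 1, i + 1):
            if d[k] == 1:
                D += 1
                ll += eta[k]
                for a in range(m):
                    U[a] += Xw[k, a]
        if D > 0:
            ll -= D * np.log(S0)
            for a in range(m):
                ma = S1[a] / S0
                U[a] -= D * ma
                for b in range(a, m):
                    A[a, b] += D * (S2[a, b] / S0 - ma * S1[b] / S0)
        i = j
    for a in range(m):
        for b in range(a + 1, m):
            A[b, a] = A[a, b]
    return ll, U, A


@njit(cache=True)
def _full_score(X, eta, d, grp_first, grp_last):
    """(1/n)-scaled score over all features, and the log likelihood."""
    n, p = X.shape
    ll, grad, _ = cox_breslow_quantities(eta, d, grp_first, grp_last)
    g = np.zeros(p)
    for i in range(n):
        gi = grad[i]
        if gi != 0.0:
            for j in range(p):
                g[j] += X[i, j] * gi
    for j in range(p):
        g[j] /= n
    return ll, g


@njit(cache=True)
def _kkt_violation(g, beta, lam, p):
    viol = 0.0
    for j in range(p):
        if beta[j] == 0.0:
            v = abs(g[j]) - lam
        else:
            s = 1.0 if beta[j] > 0.0 else -1.0
            v = abs(g[j] - lam * s)
        if v > viol:
            viol = v
    return viol


@njit(cache=True)
def lasso_cox_path_kernel(X, d, grp_first, grp_last, lambdas, kkt_tol,
                          max_outer, max_inner, beta_bound, dev_tol, dfmax):
    """Warm-started proximal-Newton path over a descending lambda grid.

    Minimizes -(1/n) * Breslow log partial likelihood + lambda * ||beta||_1
    on (already standardized) X.  Returns (K x p) coefficients, the exact
    KKT residual per lambda, and a status/iteration array: > 0 outer
    iterations used, -1 failure (tolerance not reached or unbounded optimum
    under monotone likelihood), -2 early path termination because the fit
    is saturated (relative likelihood gain below ``dev_tol``; 0 disables)
    or denser than ``dfmax`` nonzero coefficients (glmnet's dfmax/pmax
    device; 0 disables).  The path stops at the first -1/-2.
    """
    n, p = X.shape
    K = lambdas.shape[0]
    betas = np.zeros((K, p))
    kkt = np.zeros(K)
    iters = np.zeros(K, dtype=np.int64)
    beta = np.zeros(p)
    eta = np.zeros(n)
    ll_prev = 0.0
    ll_null, g = _full_score(X, eta, d, grp_first, grp_last)
    fail = 0
    for k in range(K):
        lam = lambdas[k]
        lam_prev = lambdas[k - 1] if k > 0 else lambdas[0]
        # sequential strong rule + current support
        in_ws = np.zeros(p, dtype=np.uint8)
        thresh = 2.0 * lam - lam_prev
        for j in range(p):
            if beta[j] != 0.0 or abs(g[j]) >= thresh:
                in_ws[j] = 1
        converged = False
        n_out = 0
        ll_cur = ll_prev
        for round_ in range(12):
            ws = np.flatnonzero(in_ws).astype(np.int64)
            m = ws.shape[0]
            if m == 0:
                # nothing active: KKT over all features decides
                ll_cur, g = _full_score(X, eta, d, grp_first, grp_last)
                viol = _kkt_violation(g, beta, lam, p)
                kkt[k] = viol
                if viol <= kkt_tol:
                    converged = True
                    break
                # admit the worst violator and retry
                worst = 0
                best = -1.0
                for j in range(p):
                    if abs(g[j]) > best:
                        best = abs(g[j])
                        worst = j
                in_ws[worst] = 1
                continue
            # proximal Newton on the working set
            ws_ok = True
            for outer in range(max_outer):
                n_out += 1
                ll, U, A = _ll_grad_hess_ws(X, eta, d, grp_first, grp_last, ws)
                ll_cur = ll
                viol = 0.0
                for a in range(m):
                    ga = U[a] / n
                    ba = beta[ws[a]]
                    if ba == 0.0:
                        v = abs(ga) - lam
                    else:
                        s = 1.0 if ba > 0.0 else -1.0
                        v = abs(ga - lam * s)
                    if v > viol:
                        viol = v
                if viol <= kkt_tol:
                    break
                # CD on the penalized quadratic model, variables b = beta[ws]
                bvec = np.empty(m)
                for a in range(m):
                    bvec[a] = beta[ws[a]]
                b0 = bvec.copy()
                rho = U / n       # rho = c - A b / n; equals U/n at b = b0
                adiag = np.empty(m)
                for a in range(m):
                    adiag[a] = A[a, a] / n
                cd_tol = 1e-10 if kkt_tol < 1e-6 else 1e-8
                diverged = False
                it = 0
                while it < max_inner:
                    delta = 0.0
                    bmax = 0.0
                    for a in range(m):
                        if adiag[a] <= 1e-12:
                            continue
                        z = rho[a] + adiag[a] * bvec[a]
                        if z > lam:
                            nb = (z - lam) / adiag[a]
                        elif z < -lam:
                            nb = (z + lam) / adiag[a]
                        else:
                            nb = 0.0
                        diff = nb - bvec[a]
                        if diff != 0.0:
                            for t in range(m):
                                rho[t] -= A[t, a] * diff / n
                            bvec[a] = nb
                            if abs(diff) > delta:
                                delta = abs(diff)
                        if abs(nb) > bmax:
                            bmax = abs(nb)
                    it += 1
                    if bmax > beta_bound:
                        diverged = True
                        break
                    if delta < cd_tol:
                        break
                    while it < max_inner:   # active-set sweeps
                        delta = 0.0
                        for a in range(m):
                            if bvec[a] == 0.0 or adiag[a] <= 1e-12:
                                continue
                            z = rho[a] + adiag[a] * bvec[a]
                            if z > lam:
                                nb = (z - lam) / adiag[a]
                            elif z < -lam:
                                nb = (z + lam) / adiag[a]
                            else:
                                nb = 0.0
                            diff = nb - bvec[a]
                            if diff != 0.0:
                                for t in range(m):
                                    rho[t] -= A[t, a] * diff / n
                                bvec[a] = nb
                                if abs(diff) > delta:
                                    delta = abs(diff)
                        it += 1
                        if delta < cd_tol:
                            break
                if diverged:
                    ws_ok = False
                    break
                # step halving on the penalized objective (working set only)
                obj_old = -ll / n
                for a in range(m):
                    obj_old += lam * abs(b0[a])
                step = 1.0
                accepted = False
                deta = np.zeros(n)
                for i in range(n):
                    s = 0.0
                    for a in range(m):
                        da = bvec[a] - b0[a]
                        if da != 0.0:
                            s += X[i, ws[a]] * da
                    deta[i] = s
                for h in range(20):
                    eta_c = eta + step * deta
                    ll_c, _, _ = cox_breslow_quantities(eta_c, d, grp_first, grp_last)
                    obj_new = -ll_c / n
                    for a in range(m):
                        obj_new += lam * abs(b0[a] + step * (bvec[a] - b0[a]))
                    if obj_new <= obj_old + 1e-14:
                        for a in range(m):
                            beta[ws[a]] = b0[a] + step * (bvec[a] - b0[a])
                        eta = eta_c
                        ll_cur = ll_c
                        accepted = True
                        break
                    step *= 0.5
                if not accepted:
                    break
            if not ws_ok:
                fail = -1
                break
            # exact KKT over all features; admit violators
            ll_cur, g = _full_score(X, eta, d, grp_first, grp_last)
            viol = _kkt_violation(g, beta, lam, p)
            kkt[k] = viol
            if viol <= kkt_tol:
                converged = True
                break
            added = False
            for j in range(p):
                if in_ws[j] == 0:
                    if abs(g[j]) > lam + kkt_tol:
                        in_ws[j] = 1
                        added = True
            if not added:
                # violation inside the working set: Newton failed to polish
                fail = -1
                break
        if fail == -1 or not converged:
            for kk in range(k, K):
                iters[kk] = -1
            break
        iters[k] = n_out
        df_k = 0
        for j in range(p):
            betas[k, j] = beta[j]
            if beta[j] != 0.0:
                df_k += 1
        if dfmax > 0 and df_k >= dfmax and k + 1 < K:
            for kk in range(k + 1, K):
                iters[kk] = -2
            break
        # saturation-based early termination (glmnet-style fdev/devmax rules):
        # stop once the incremental likelihood gain is negligible relative to
        # the deviance explained so far, or nearly all deviance is explained
        if dev_tol > 0.0 and k > 0:
            explained = ll_cur - ll_null
            gain = ll_cur - ll_prev
            if explained > 0.99 * (-ll_null) or (explained > 0.0 and gain <= dev_tol * explained):
                for kk in range(k + 1, K):
                    iters[kk] = -2
                break
        ll_prev = ll_cur
    return betas, kkt, iters
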