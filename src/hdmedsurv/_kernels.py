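"""Numba kernels for Cox partial-likelihood computations.

All kernels assume subjects sorted by ascending observed time, with tie
blocks described by ``first[i]``/``last[i]`` (index of the first/last subject
sharing ``time[i]``). Risk sets follow the Breslow convention
``R_i = {l : T_l >= T_i}``, i.e. the suffix starting at ``first[i]``.

Linear systems are solved by Gauss–Jordan with partial pivoting so that
singularity is reported through a flag (numba's LAPACK bindings signal it
via exceptions, which do not compose well inside nopython loops).

Status codes: 0 = converged, 1 = singular information, 2 = not converged
(max iterations or diverging coefficients, e.g. monotone likelihood).
"""

from __future__ import annotations

import numpy as np
from numba import njit

F8 = np.float64


@njit(cache=True)
def _inv_flag(A):
    """Gauss–Jordan inverse; returns (A_inv, ok)."""
    c = A.shape[0]
    M = np.empty((c, 2 * c), dtype=F8)
    scale = 0.0
    for i in range(c):
        for j in range(c):
            M[i, j] = A[i, j]
            if abs(A[i, j]) > scale:
                scale = abs(A[i, j])
            M[i, c + j] = 0.0
        M[i, c + i] = 1.0
    if scale == 0.0:
        return np.zeros((c, c), dtype=F8), False
    tol = 1e-12 * scale
    for col in range(c):
        piv = col
        big = abs(M[col, col])
        for i in range(col + 1, c):
            if abs(M[i, col]) > big:
                big = abs(M[i, col])
                piv = i
        if big <= tol:
            return np.zeros((c, c), dtype=F8), False
        if piv != col:
            for j in range(2 * c):
                tmp = M[col, j]
                M[col, j] = M[piv, j]
                M[piv, j] = tmp
        d = M[col, col]
        for j in range(2 * c):
            M[col, j] /= d
        for i in range(c):
            if i != col and M[i, col] != 0.0:
                f = M[i, col]
                for j in range(2 * c):
                    M[i, j] -= f * M[col, j]
    return M[:, c:].copy(), True


@njit(cache=True)
def cox_lpl(P, delta, first, beta):
    """Breslow log partial likelihood at ``beta`` (sorted data)."""
    n = P.shape[0]
    eta = P @ beta
    m = eta[0]
    for i in range(n):
        if eta[i] > m:
            m = eta[i]
    lpl = 0.0
    s0 = 0.0
    i = n - 1
    while i >= 0:
        f = first[i]
        for l in range(f, i + 1):
            s0 += np.exp(eta[l] - m)
        s0f = s0 if s0 > 1e-290 else 1e-290
        for l in range(f, i + 1):
            if delta[l] > 0.0:
                lpl += eta[l] - m - np.log(s0f)
        i = f - 1
    return lpl


@njit(cache=True)
def cox_derivs(P, delta, first, beta):
    """Log partial likelihood, score vector and observed information."""
    n, c = P.shape
    eta = P @ beta
    m = eta[0]
    for i in range(n):
        if eta[i] > m:
            m = eta[i]
    lpl = 0.0
    grad = np.zeros(c, dtype=F8)
    info = np.zeros((c, c), dtype=F8)
    s0 = 0.0
    s1 = np.zeros(c, dtype=F8)
    s2 = np.zeros((c, c), dtype=F8)
    i = n - 1
    while i >= 0:
        f = first[i]
        for l in range(f, i + 1):
            e = np.exp(eta[l] - m)
            s0 += e
            for jj in range(c):
                pe = e * P[l, jj]
                s1[jj] += pe
                for kk in range(jj, c):
                    s2[jj, kk] += pe * P[l, kk]
        s0f = s0 if s0 > 1e-290 else 1e-290
        for l in range(f, i + 1):
            if delta[l] > 0.0:
                lpl += eta[l] - m - np.log(s0f)
                for jj in range(c):
                    xbar = s1[jj] / s0f
                    grad[jj] += P[l, jj] - xbar
                    for kk in range(jj, c):
                        info[jj, kk] += s2[jj, kk] / s0f - xbar * (s1[kk] / s0f)
        i = f - 1
    for jj in range(c):
        for kk in range(jj + 1, c):
            info[kk, jj] = info[jj, kk]
    return lpl, grad, info


@njit(cache=True)
def newton_cox(P, delta, first, beta0, tol, maxit):
    """Newton–Raphson maximization with step halving.

    Returns (beta, covariance, lpl, n_iter, status).
    """
    c = P.shape[1]
    beta = beta0.copy()
    lpl, grad, info = cox_derivs(P, delta, first, beta)
    status = 2
    it = 0
    for it in range(1, maxit + 1):
        inv, ok = _inv_flag(info)
        if not ok:
            return beta, np.zeros((c, c), dtype=F8), lpl, it, 1
        step = inv @ grad
        scale = 1.0
        bnew = beta + step
        lnew = cox_lpl(P, delta, first, bnew)
        h = 0
        while lnew < lpl - 1e-13 * (abs(lpl) + 1.0) and h < 40:
            scale *= 0.5
            bnew = beta + scale * step
            lnew = cox_lpl(P, delta, first, bnew)
            h += 1
        beta = bnew
        diverged = False
        for j in range(c):
            if abs(beta[j]) > 150.0 or not np.isfinite(beta[j]):
                diverged = True
        lold = lpl
        lpl, grad, info = cox_derivs(P, delta, first, beta)
        if diverged:
            status = 2
            break
        if abs(lpl - lold) < tol * (abs(lold) + 1.0):
            status = 0
            break
    inv, ok = _inv_flag(info)
    if not ok:
        return beta, np.zeros((c, c), dtype=F8), lpl, it, 1
    return beta, inv, lpl, it, status


@njit(cache=True)
def marginal_cox_batch(base, M, delta, first, beta_base, tol, maxit):
    """Per-mediator Cox fit on design ``[base | M[:, k]]``.

    Returns an (p, 3) array of (coef, se, status) for the mediator column,
    warm-started from the base-model coefficients.
    """
    n, cb = base.shape
    p = M.shape[1]
    out = np.empty((p, 3), dtype=F8)
    P = np.empty((n, cb + 1), dtype=F8)
    for i in range(n):
        for j in range(cb):
            P[i, j] = base[i, j]
    b0 = np.zeros(cb + 1, dtype=F8)
    for k in range(p):
        for i in range(n):
            P[i, cb] = M[i, k]
        for j in range(cb):
            b0[j] = beta_base[j]
        b0[cb] = 0.0
        beta, cov, lpl, it, status = newton_cox(P, delta, first, b0, tol, maxit)
        out[k, 0] = beta[cb]
        var = cov[cb, cb]
        out[k, 1] = np.sqrt(var) if var > 0.0 else 0.0
        out[k, 2] = status
    return out


@njit(cache=True)
def _subject_gw(eta, delta, first, last):
    """Subject-level score g_l and diagonal-Hessian weight w_l, plus lpl.

    g_l = delta_l - e_l * sum_{events i: T_i <= T_l} 1/S0_i
    w_l = e_l * A_l - e_l^2 * B_l   (B uses 1/S0^2)
    """
    n = eta.shape[0]
    m = eta[0]
    for i in range(n):
        if eta[i] > m:
            m = eta[i]
    e = np.empty(n, dtype=F8)
    for i in range(n):
        e[i] = np.exp(eta[i] - m)
    inv0 = np.zeros(n, dtype=F8)
    inv2 = np.zeros(n, dtype=F8)
    lpl = 0.0
    s0 = 0.0
    i = n - 1
    while i >= 0:
        f = first[i]
        for l in range(f, i + 1):
            s0 += e[l]
        # exp(eta - m) can underflow to exactly 0 for early (large-time)
        # blocks when the linear predictor has a huge spread; floor the
        # risk-set sum so 1/S0 stays finite
        s0f = s0 if s0 > 1e-290 else 1e-290
        for l in range(f, i + 1):
            if delta[l] > 0.0:
                lpl += eta[l] - m - np.log(s0f)
                inv0[l] = 1.0 / s0f
                inv2[l] = 1.0 / (s0f * s0f)
        i = f - 1
    pa = 0.0
    pb = 0.0
    PA = np.empty(n, dtype=F8)
    PB = np.empty(n, dtype=F8)
    for i in range(n):
        pa += inv0[i]
        pb += inv2[i]
        PA[i] = pa
        PB[i] = pb
    g = np.empty(n, dtype=F8)
    w = np.empty(n, dtype=F8)
    for l in range(n):
        A = PA[last[l]]
        B = PB[last[l]]
        g[l] = delta[l] - e[l] * A
        w[l] = e[l] * A - e[l] * e[l] * B
    return g, w, lpl


@njit(cache=True, inline="always")
def _soft(u, lam):
    if u > lam:
        return u - lam
    if u < -lam:
        return u + lam
    return 0.0


@njit(cache=True, inline="always")
def _mcp_1d(u, v, lam, a):
    """Exact minimizer of (v/2) b^2 - u b + MCP(b; lam, a) over b."""
    au = abs(u)
    if v > 1.0 / a + 1e-12:
        if au <= lam:
            return 0.0
        if au <= a * lam * v:
            s = 1.0 if u > 0.0 else -1.0
            return s * (au - lam) / (v - 1.0 / a)
        return u / v
    # curvature too small for the firm-threshold rule: the inner region is
    # concave, so the minimum is at 0 or in the saturated region
    flat = 0.5 * a * lam * lam
    best = 0.0
    fbest = 0.0
    b2 = u / v
    if abs(b2) >= a * lam:
        f2 = -0.5 * u * b2 + flat
        if f2 < fbest:
            best = b2
            fbest = f2
    s = 1.0 if u >= 0.0 else -1.0
    b3 = s * a * lam
    f3 = 0.5 * v * b3 * b3 - u * b3 + flat
    if f3 < fbest:
        best = b3
    return best


@njit(cache=True)
def _pen_sum(beta, n_unpen, lam, a, kind):
    s = 0.0
    for j in range(n_unpen, beta.shape[0]):
        ab = abs(beta[j])
        if kind == 1:
            s += lam * ab
        else:
            if ab <= a * lam:
                s += lam * ab - ab * ab / (2.0 * a)
            else:
                s += 0.5 * a * lam * lam
    return s


@njit(cache=True)
def _cd_pass(P, w, r, v, beta, idx, n_unpen, lam, a, kind, n):
    """One coordinate-descent sweep over ``idx``; updates r/beta in place."""
    maxd = 0.0
    for t in range(idx.shape[0]):
        j = idx[t]
        vj = v[j]
        if vj <= 0.0:
            continue
        u = beta[j] * vj
        for i in range(n):
            u += w[i] * P[i, j] * r[i] / n
        if j < n_unpen:
            bnew = u / vj
        elif kind == 1:
            bnew = _soft(u, lam) / vj
        else:
            bnew = _mcp_1d(u, vj, lam, a)
        d = bnew - beta[j]
        if d != 0.0:
            for i in range(n):
                r[i] -= d * P[i, j]
            beta[j] = bnew
            ad = abs(d)
            if ad > maxd:
                maxd = ad
    return maxd


@njit(cache=True)
def _quad_refresh(P, delta, first, last, beta, w, r, v):
    """Recompute the quadratic approximation at ``beta``; returns lpl."""
    n = P.shape[0]
    eta = P @ beta
    g, ww, lpl = _subject_gw(eta, delta, first, last)
    for i in range(n):
        wi = ww[i]
        if wi < 1e-9:
            wi = 1e-9
        w[i] = wi
        r[i] = g[i] / wi
    for j in range(P.shape[1]):
        s = 0.0
        for i in range(n):
            s += w[i] * P[i, j] * P[i, j]
        v[j] = s / n
    return lpl


@njit(cache=True)
def _lpl_eta(eta, delta, first):
    """Breslow log partial likelihood from a precomputed linear predictor."""
    n = eta.shape[0]
    m = eta[0]
    for i in range(n):
        if eta[i] > m:
            m = eta[i]
    lpl = 0.0
    s0 = 0.0
    i = n - 1
    while i >= 0:
        f = first[i]
        for l in range(f, i + 1):
            s0 += np.exp(eta[l] - m)
        s0f = s0 if s0 > 1e-290 else 1e-290
        for l in range(f, i + 1):
            if delta[l] > 0.0:
                lpl += eta[l] - m - np.log(s0f)
        i = f - 1
    return lpl


@njit(cache=True, inline="always")
def _pen_prime(b, lam, a, kind):
    """Signed penalty derivative at b != 0."""
    s = 1.0 if b > 0.0 else -1.0
    if kind == 1:
        return s * lam
    ab = abs(b)
    if ab >= a * lam:
        return 0.0
    return s * (lam - ab / a)


@njit(cache=True)
def _active_newton(P, delta, first, beta, act, n_unpen, lam, a, kind, tol, maxit):
    """Penalized Newton on a fixed active set.

    Maximizes (1/n) lpl - sum pen over the active coordinates, holding the
    rest at zero. Steps are sign-constrained (a penalized coordinate wanting
    to cross zero is set to zero and reported as a support change). Returns
    0 converged, 1 singular/failed, 2 maxit, 3 support changed.
    """
    n = P.shape[0]
    k = act.shape[0]
    Pa = np.empty((n, k), dtype=F8)
    for t in range(k):
        j = act[t]
        for i in range(n):
            Pa[i, t] = P[i, j]
    ba = np.empty(k, dtype=F8)
    for t in range(k):
        ba[t] = beta[act[t]]
    lpl, grad, info = cox_derivs(Pa, delta, first, ba)
    fcur = lpl / n
    for t in range(k):
        j = act[t]
        if j >= n_unpen:
            ab = abs(ba[t])
            if kind == 1:
                fcur -= lam * ab
            elif ab <= a * lam:
                fcur -= lam * ab - ab * ab / (2.0 * a)
            else:
                fcur -= 0.5 * a * lam * lam
    for it in range(maxit):
        # gradient and curvature of the penalized objective
        gq = np.empty(k, dtype=F8)
        M = np.empty((k, k), dtype=F8)
        for t in range(k):
            for u in range(k):
                M[t, u] = info[t, u] / n
        for t in range(k):
            j = act[t]
            gq[t] = grad[t] / n
            if j >= n_unpen:
                gq[t] -= _pen_prime(ba[t], lam, a, kind)
                if kind == 0 and abs(ba[t]) < a * lam:
                    M[t, t] -= 1.0 / a
        inv, ok = _inv_flag(M)
        if not ok:
            return 1
        step = inv @ gq
        # cap the step so no penalized coordinate crosses zero
        smax = 1.0
        cross = -1
        for t in range(k):
            j = act[t]
            if j >= n_unpen and step[t] != 0.0:
                s_t = -ba[t] / step[t]
                if 0.0 < s_t < smax:
                    smax = s_t
                    cross = t
        if smax < 0.05:
            beta[act[cross]] = 0.0
            return 3
        s = smax
        accepted = False
        for h in range(30):
            bn = ba + s * step
            lpl_n, grad_n, info_n = cox_derivs(Pa, delta, first, bn)
            fnew = lpl_n / n
            for t in range(k):
                j = act[t]
                if j >= n_unpen:
                    ab = abs(bn[t])
                    if kind == 1:
                        fnew -= lam * ab
                    elif ab <= a * lam:
                        fnew -= lam * ab - ab * ab / (2.0 * a)
                    else:
                        fnew -= 0.5 * a * lam * lam
            if fnew >= fcur - 1e-13 * (abs(fcur) + 1.0):
                accepted = True
                break
            s *= 0.5
        if not accepted:
            return 1
        big = 0.0
        for t in range(k):
            d = abs(s * step[t])
            if d > big:
                big = d
        ba = bn
        lpl, grad, info = lpl_n, grad_n, info_n
        fcur = fnew
        for t in range(k):
            beta[act[t]] = ba[t]
        if big < tol:
            return 0
    return 2


@njit(cache=True)
def cd_fit(P, delta, first, last, n_unpen, lam, a, kind, tol, max_refresh, beta):
    """Penalized Cox fit at one lambda.

    Alternates (i) a diagonal-Hessian quadratic refresh with coordinate-
    descent sweeps (full sweep for KKT violations, then active-set sweeps)
    and an overrelaxation line search along the refresh direction — the
    diagonal weights overestimate curvature when many subjects share risk
    sets, so the optimal step often exceeds 1 — with (ii) an exact Newton
    polish on the stabilized active set, which restores fast local
    convergence. The penalized objective is monotone up to line-search
    tolerance. Returns (flag, n_refresh); flag 0 = converged.
    """
    n, c = P.shape
    w = np.empty(n, dtype=F8)
    r = np.empty(n, dtype=F8)
    v = np.empty(c, dtype=F8)
    all_idx = np.arange(c)
    beta_prev = beta.copy()
    support_prev = np.zeros(c, dtype=np.int64)
    for j in range(c):
        support_prev[j] = 1 if (j < n_unpen or beta[j] != 0.0) else 0
    have_support_prev = False
    flag = 1
    ref = 0
    for ref in range(1, max_refresh + 1):
        lpl = _quad_refresh(P, delta, first, last, beta, w, r, v)
        obj = lpl / n - _pen_sum(beta, n_unpen, lam, a, kind)
        for j in range(c):
            beta_prev[j] = beta[j]
        # coordinate sweeps under the fixed quadratic
        _cd_pass(P, w, r, v, beta, all_idx, n_unpen, lam, a, kind, n)
        for inner in range(100):
            na = 0
            for j in range(c):
                if j < n_unpen or beta[j] != 0.0:
                    na += 1
            act = np.empty(na, dtype=np.int64)
            t = 0
            for j in range(c):
                if j < n_unpen or beta[j] != 0.0:
                    act[t] = j
                    t += 1
            maxd = _cd_pass(P, w, r, v, beta, act, n_unpen, lam, a, kind, n)
            if maxd < tol:
                break
        # line search (halving and overrelaxation) on the true objective
        dirn = np.empty(c, dtype=F8)
        for j in range(c):
            dirn[j] = beta[j] - beta_prev[j]
        eta0 = P @ beta_prev
        etad = P @ dirn
        s = 1.0
        tmp = np.empty(c, dtype=F8)
        fs = _lpl_eta(eta0 + etad, delta, first) / n
        for j in range(c):
            tmp[j] = beta_prev[j] + dirn[j]
        fs -= _pen_sum(tmp, n_unpen, lam, a, kind)
        h = 0
        while fs < obj - 1e-13 * (abs(obj) + 1.0) and h < 30:
            s *= 0.5
            for j in range(c):
                tmp[j] = beta_prev[j] + s * dirn[j]
            fs = _lpl_eta(eta0 + s * etad, delta, first) / n - _pen_sum(
                tmp, n_unpen, lam, a, kind)
            h += 1
        if h == 0:
            # try doubling: diagonal weights overdamp the IRLS direction
            while s < 64.0:
                s2 = 2.0 * s
                for j in range(c):
                    tmp[j] = beta_prev[j] + s2 * dirn[j]
                f2 = _lpl_eta(eta0 + s2 * etad, delta, first) / n - _pen_sum(
                    tmp, n_unpen, lam, a, kind)
                if f2 > fs:
                    s = s2
                    fs = f2
                else:
                    break
        if s != 1.0:
            for j in range(c):
                beta[j] = beta_prev[j] + s * dirn[j]
        big = 0.0
        for j in range(c):
            d = abs(beta[j] - beta_prev[j])
            if d > big:
                big = d
        if big < tol:
            flag = 0
            break
        # Newton polish once the support has stabilized
        same = have_support_prev
        for j in range(c):
            cur = 1 if (j < n_unpen or beta[j] != 0.0) else 0
            if cur != support_prev[j]:
                same = False
            support_prev[j] = cur
        have_support_prev = True
        if same:
            na = 0
            for j in range(c):
                if support_prev[j] == 1:
                    na += 1
            act = np.empty(na, dtype=np.int64)
            t = 0
            for j in range(c):
                if support_prev[j] == 1:
                    act[t] = j
                    t += 1
            _active_newton(P, delta, first, beta, act, n_unpen, lam, a, kind,
                           tol * 0.1, 50)
            # the next refresh + sweep acts as the KKT verification
    return flag, ref


@njit(cache=True)
def cd_path(P, delta, first, last, n_unpen, lambdas, a, kind, tol, max_refresh,
            beta0, dfmax):
    """Warm-started penalized path over a decreasing lambda grid.

    Stops early once the active set exceeds ``dfmax`` (the remaining
    lambdas are reported as unvisited via n_valid). Returns
    (coefs (L, c), lpls (L,), flags (L,), n_valid); lpls are raw
    (unscaled) Breslow log partial likelihoods.
    """
    L = lambdas.shape[0]
    c = P.shape[1]
    coefs = np.zeros((L, c), dtype=F8)
    lpls = np.zeros(L, dtype=F8)
    flags = np.zeros(L, dtype=np.int64)
    beta = beta0.copy()
    n_valid = 0
    for li in range(L):
        flag, ref = cd_fit(P, delta, first, last, n_unpen, lambdas[li], a, kind,
                           tol, max_refresh, beta)
        for j in range(c):
            coefs[li, j] = beta[j]
        lpls[li] = cox_lpl(P, delta, first, beta)
        flags[li] = flag
        n_valid = li + 1
        nnz = 0
        for j in range(n_unpen, c):
            if beta[j] != 0.0:
                nnz += 1
        if nnz > dfmax:
            break
    return coefs, lpls, flags, n_valid
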