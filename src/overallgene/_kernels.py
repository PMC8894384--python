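"""Jitted hot paths shared by the public test functions and the simulation
drivers.

The replication estimate of the p-value correlation matrix and the type-I /
power experiments evaluate the full battery of 3(K+1) tests tens of
thousands of times, so the per-replicate pipeline (tuning-parameter MLE in
the LD eigenbasis, weighted burden/SKAT/SKAT-O, extended-Simes combination)
lives here as numba kernels. The public API wraps these with validation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._quadform import (
    _chi2_sf,
    _nc_qf_sf,
    _norm_ppf_upper,
    _qf_quantile_upper,
    _qf_sf,
)

EIG_TRUNC_REL = 1e-10
# internal stand-in for rho = 1 in the SKAT-O conditional integration, where
# the (1 - rho) denominator degenerates (the rho = 1 test itself is still
# evaluated exactly through its rank-1 null)
_RHO_CAP = 0.999

# Gauss-Legendre base rules on [0, 1]; the SKAT-O conditional integral
# applies them on equal panels of the integrand's exact support. The fine
# tier is used whenever the min-p statistic is small enough to matter for
# significance counting; the coarse tier serves central-region p-values in
# the replication loops.
_GLF_X, _GLF_W = np.polynomial.legendre.leggauss(8)
_GL01_T = np.ascontiguousarray(0.5 * (_GLF_X + 1.0))
_GL01_W = np.ascontiguousarray(0.5 * _GLF_W)
_N_PANELS = 8
_GLC_X, _GLC_W = np.polynomial.legendre.leggauss(6)
_GL01_TC = np.ascontiguousarray(0.5 * (_GLC_X + 1.0))
_GL01_WC = np.ascontiguousarray(0.5 * _GLC_W)
_N_PANELS_C = 4
# min-p above this threshold switches the replication loops to the coarse
# tier (absolute p error there ~1e-3, far from any counting threshold)
_COARSE_T = 0.02


# ---------------------------------------------------------------------------
# LD shrinkage likelihood in the eigenbasis of R
# ---------------------------------------------------------------------------


@njit(cache=True)
def _nll_eig(a, evals, v2):
    """0.5 * (log det U + Z' U^-1 Z) for U = a R + (1-a) I, computed from the
    eigenvalues of R and the squared rotated Z (v = Q'Z)."""
    m = evals.size
    dmin = 1e300
    for i in range(m):
        d = a * evals[i] + (1.0 - a)
        if d < dmin:
            dmin = d
    ridge = 1e-10 if dmin < 1e-12 else 0.0
    total = 0.0
    for i in range(m):
        d = a * evals[i] + (1.0 - a) + ridge
        total += math.log(d) + v2[i] / d
    return 0.5 * total


@njit(cache=True)
def _estimate_a(evals, v2, tol):
    """argmin over a in [0,1] of the negative log-likelihood, by a 21-point
    grid scan refined with golden-section search; ties broken toward a = 1."""
    ngrid = 21
    best_f = 1e300
    best_i = ngrid - 1
    fvals = np.empty(ngrid)
    for i in range(ngrid):
        a = i / (ngrid - 1.0)
        fvals[i] = _nll_eig(a, evals, v2)
        if fvals[i] < best_f - 1e-12 * (1.0 + abs(best_f)):
            best_f = fvals[i]
            best_i = i
        elif fvals[i] <= best_f + 1e-12 * (1.0 + abs(best_f)):
            best_f = min(best_f, fvals[i])
            best_i = i  # tie: prefer the larger a
    step = 1.0 / (ngrid - 1.0)
    lo = max(0.0, best_i * step - step)
    hi = min(1.0, best_i * step + step)
    # golden-section refinement
    gr = 0.5 * (math.sqrt(5.0) - 1.0)
    x1 = hi - gr * (hi - lo)
    x2 = lo + gr * (hi - lo)
    f1 = _nll_eig(x1, evals, v2)
    f2 = _nll_eig(x2, evals, v2)
    while hi - lo > tol:
        if f1 > f2:
            lo = x1
            x1 = x2
            f1 = f2
            x2 = lo + gr * (hi - lo)
            f2 = _nll_eig(x2, evals, v2)
        else:
            hi = x2
            x2 = x1
            f2 = f1
            x1 = hi - gr * (hi - lo)
            f1 = _nll_eig(x1, evals, v2)
    a_gold = 0.5 * (lo + hi)
    f_gold = _nll_eig(a_gold, evals, v2)
    # keep the better of the refined point and the grid best; on a flat
    # likelihood prefer the larger a (no shrinkage of a perfect LD estimate)
    a_hat = a_gold
    f_hat = f_gold
    tie = 1e-12 * (1.0 + abs(f_hat))
    a_grid = best_i * step
    if fvals[best_i] < f_hat - tie or (fvals[best_i] <= f_hat + tie and a_grid > a_hat):
        a_hat = a_grid
        f_hat = fvals[best_i]
    return min(max(a_hat, 0.0), 1.0)


@njit(cache=True)
def _truncated_positive(evals):
    """Eigenvalues above the relative floor, as a fresh array."""
    lmax = 0.0
    for i in range(evals.size):
        if evals[i] > lmax:
            lmax = evals[i]
    thresh = EIG_TRUNC_REL * lmax
    count = 0
    for i in range(evals.size):
        if evals[i] > thresh:
            count += 1
    out = np.empty(count)
    j = 0
    for i in range(evals.size):
        if evals[i] > thresh:
            out[j] = evals[i]
            j += 1
    return out


# ---------------------------------------------------------------------------
# SKAT-O
# ---------------------------------------------------------------------------


@njit(cache=True)
def _skato_p(sigma, evals_s, evecs_s, q_skat, q_bt, rho, allow_coarse=False):
    """SKAT-O p-value from the weighted null covariance Sigma = W U W.

    Per-rho statistics Q_rho = (1-rho) Q_SKAT + rho Q_BT are referred to
    their exact mixture-of-chi-square nulls, giving the minimum per-rho
    p-value T. The p-value of T is then computed by one-dimensional
    integration conditional on the shared burden chi-square component x:
    given x, the residual of every Q_rho is one and the same noncentral
    weighted chi-square (complete-the-square in the subspace orthogonal to
    the burden direction), so

        P(min_rho p_rho > T)
            = int P(Q_res < min_rho (q_rho(T) - tau_rho x)/(1-rho) | x)
                  dF_chi2_1(x),

    evaluated with the noncentral-quadratic-form survival function. The
    result is clipped to the analytic envelope [T, min(1, n_rho * T)].
    """
    m = sigma.shape[0]
    nrho = rho.size
    taubar = 0.0
    for i in range(m):
        for j in range(m):
            taubar += sigma[i, j]
    if m == 1:
        return _chi2_sf(q_bt / sigma[0, 0], 1.0)
    # rotated burden direction: utilde = Lambda^(1/2) V' 1 (Sigma eigenbasis)
    ut = np.zeros(m)
    for i in range(m):
        acc = 0.0
        for j in range(m):
            acc += evecs_s[j, i]
        ut[i] = math.sqrt(max(evals_s[i], 0.0)) * acc
    # per-rho exact p-values and their eigenvalue sets
    lam_store = np.empty((nrho, m))
    lam_count = np.empty(nrho, dtype=np.int64)
    q_obs = np.empty(nrho)
    tmin = 2.0
    j_min = 0
    for j in range(nrho):
        r = rho[j]
        if r == 0.0:
            # the SKAT endpoint reuses Sigma's own spectrum
            ljt = _truncated_positive(evals_s)
        elif r == 1.0:
            # the burden endpoint is rank one with eigenvalue 1'Sigma1
            ljt = np.empty(1)
            ljt[0] = max(taubar, 1e-300)
        else:
            arho = np.empty((m, m))
            for i in range(m):
                for k in range(m):
                    arho[i, k] = r * ut[i] * ut[k]
                arho[i, i] += (1.0 - r) * max(evals_s[i], 0.0)
            lj = np.linalg.eigvalsh(arho)
            ljt = _truncated_positive(lj)
        lam_count[j] = ljt.size
        for i in range(ljt.size):
            lam_store[j, i] = ljt[i]
        qj = (1.0 - r) * q_skat + r * q_bt
        q_obs[j] = qj
        pj, ok = _qf_sf(qj, ljt)
        if not ok:
            pj = 1.0
        if pj < tmin:
            tmin = pj
            j_min = j
    if nrho == 1:
        return tmin
    tmin = min(max(tmin, 1e-300), 1.0)
    if taubar <= 1e-12:
        # burden direction carries no variance; the rho mixture degenerates
        return min(max(tmin, 0.0), min(1.0, nrho * tmin))
    # conditional decomposition: phi = Sigma^(1/2) 1 / sqrt(taubar);
    # A = (I - phi phi') Sigma (I - phi phi'), b = (I - phi phi') Sigma phi
    sq = math.sqrt(taubar)
    phi = np.zeros(m)
    for i in range(m):
        acc = 0.0
        for j in range(m):
            acc += evecs_s[i, j] * ut[j]
        phi[i] = acc / sq
    sig_phi = sigma @ phi
    d_phi = 0.0
    for i in range(m):
        d_phi += phi[i] * sig_phi[i]
    amat = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            amat[i, j] = (
                sigma[i, j]
                - phi[i] * sig_phi[j]
                - sig_phi[i] * phi[j]
                + d_phi * phi[i] * phi[j]
            )
    evals_a, evecs_a = np.linalg.eigh(amat)
    bvec = sig_phi - d_phi * phi
    amax = max(evals_a[m - 1], 0.0)
    nk = 0
    for i in range(m):
        if evals_a[i] > 1e-12 * amax:
            nk += 1
    if nk == 0:
        return min(max(tmin, 0.0), min(1.0, nrho * tmin))
    lamk = np.empty(nk)
    dcoef = np.empty(nk)  # delta_i = x * dcoef_i
    c0 = 0.0
    idx = 0
    for i in range(m):
        if evals_a[i] > 1e-12 * amax:
            bi = 0.0
            for j in range(m):
                bi += evecs_a[j, i] * bvec[j]
            lamk[idx] = evals_a[i]
            dcoef[idx] = (bi / evals_a[i]) ** 2
            c0 += bi * bi / evals_a[i]
            idx += 1
    coarse = allow_coarse and tmin > _COARSE_T
    q_tol = 1e-3 if coarse else 1e-6
    nc_nodes = 16 if coarse else 24
    margin = 0.35 if coarse else 0.5
    # per-rho thresholds at level T and burden multipliers tau(rho).
    # Only thresholds whose line (q_j - tau_j x)/(1 - rho_j) can touch the
    # lower envelope over the support influence the integral, so cheap
    # Wilson-Hilferty approximations locate the binding lines and only
    # those are inverted exactly. The argmin rho needs no inversion at all:
    # its threshold is the observed statistic itself.
    qt = np.empty(nrho)
    tau = np.empty(nrho)
    z_t = _norm_ppf_upper(tmin)
    for j in range(nrho):
        r = min(rho[j], _RHO_CAP)
        tau[j] = r * taubar + (1.0 - r) * d_phi
        if j == j_min:
            qt[j] = q_obs[j]
            continue
        if lam_count[j] == 1:
            # rank-one line: exact chi-square quantile via its own scale
            qt[j] = _qf_quantile_upper(tmin, lam_store[j, :1], -1.0, q_tol)
            continue
        mean_j = 0.0
        var_j = 0.0
        for i in range(lam_count[j]):
            li = lam_store[j, i]
            mean_j += li
            var_j += 2.0 * li * li
        cj = var_j / (2.0 * mean_j)
        dfj = 2.0 * mean_j * mean_j / var_j
        hj = 2.0 / (9.0 * dfj)
        qa = cj * dfj * (1.0 - hj + z_t * math.sqrt(hj)) ** 3
        qt[j] = max(qa, 1e-12 * mean_j)
    # provisional support end from the approximate thresholds
    x_end = 40.0
    for j in range(nrho):
        r = min(rho[j], _RHO_CAP)
        slope = tau[j] / (1.0 - r) - c0
        if slope > 0.0:
            root = qt[j] / ((1.0 - r) * slope)
            if root < x_end:
                x_end = root
    if x_end <= 0.0:
        return min(max(tmin, 0.0), min(1.0, nrho * tmin))
    # exact inversion for lines within the margin of the provisional
    # envelope anywhere on the support
    for j in range(nrho):
        if j == j_min or lam_count[j] == 1:
            continue
        r_j = min(rho[j], _RHO_CAP)
        near = False
        for gx in range(9):
            x = x_end * gx / 8.0
            dmin = 1e300
            for k in range(nrho):
                r_k = min(rho[k], _RHO_CAP)
                d = (qt[k] - tau[k] * x) / (1.0 - r_k)
                if d < dmin:
                    dmin = d
            dj = (qt[j] - tau[j] * x) / (1.0 - r_j)
            if dj - margin * qt[j] / (1.0 - r_j) <= dmin:
                near = True
                break
        if near:
            qt[j] = _qf_quantile_upper(
                tmin, lam_store[j, : lam_count[j]], qt[j], q_tol
            )
    # final support end with the refined thresholds
    x_end = 40.0
    for j in range(nrho):
        r = min(rho[j], _RHO_CAP)
        slope = tau[j] / (1.0 - r) - c0
        if slope > 0.0:
            root = qt[j] / ((1.0 - r) * slope)
            if root < x_end:
                x_end = root
    if x_end <= 0.0:
        return min(max(tmin, 0.0), min(1.0, nrho * tmin))
    # integrate over the burden component on [0, x_end], x = t^2
    t_end = math.sqrt(x_end)
    cnorm = 2.0 / math.sqrt(2.0 * math.pi)
    deltas = np.empty(nk)
    integral = 0.0
    n_panels = _N_PANELS_C if coarse else _N_PANELS
    gl_t = _GL01_TC if coarse else _GL01_T
    gl_w = _GL01_WC if coarse else _GL01_W
    h = t_end / n_panels
    for panel in range(n_panels):
        t0 = panel * h
        for g in range(gl_t.size):
            t = t0 + h * gl_t[g]
            x = t * t
            thresh = 1e300
            for j in range(nrho):
                r = min(rho[j], _RHO_CAP)
                d = (qt[j] - tau[j] * x) / (1.0 - r)
                if d < thresh:
                    thresh = d
            q_nc = thresh + x * c0
            if q_nc <= 0.0:
                continue
            for i in range(nk):
                deltas[i] = x * dcoef[i]
            s_nc = _nc_qf_sf(q_nc, lamk, deltas, nc_nodes)
            integral += h * gl_w[g] * (1.0 - s_nc) * cnorm * math.exp(-0.5 * x)
    p = 1.0 - integral
    lo = tmin
    hi = min(1.0, nrho * tmin)
    if p != p:  # numerical failure: fall back to the Bonferroni envelope
        return hi
    return min(max(p, lo), hi)


# ---------------------------------------------------------------------------
# full battery for one Z-vector
# ---------------------------------------------------------------------------


@njit(cache=True)
def _all_pvalues(z, evecs_r, evals_r, weights, rho, fit_a, a_fixed, tol_a,
                 allow_coarse=False):
    """All 3(K+1) p-values for one Z-vector.

    weights is the (K+1, M) matrix of diagonal weight vectors (row 0 is the
    unweighted all-ones vector). Returns (pvals ordered BT/SKAT/SKATO per
    weight, a_hat). Degenerate tests yield NaN. ``allow_coarse`` lets the
    SKAT-O integration drop to its coarse tier for central-region p-values
    (used by the replication loops).
    """
    m = z.size
    v = evecs_r.T @ z
    v2 = v * v
    if fit_a:
        a_hat = _estimate_a(evals_r, v2, tol_a)
    else:
        a_hat = a_fixed
    d = a_hat * evals_r + (1.0 - a_hat)
    u = (evecs_r * d) @ evecs_r.T
    n_w = weights.shape[0]
    out = np.full(3 * n_w, np.nan)
    for k in range(n_w):
        w = weights[k]
        wz_sum = 0.0
        q_skat = 0.0
        for i in range(m):
            wz = w[i] * z[i]
            wz_sum += wz
            q_skat += wz * wz
        q_bt = wz_sum * wz_sum
        sigma = np.empty((m, m))
        vbt = 0.0
        for i in range(m):
            for j in range(m):
                sigma[i, j] = w[i] * u[i, j] * w[j]
                vbt += sigma[i, j]
        if vbt > 1e-12:
            out[3 * k] = _chi2_sf(q_bt / vbt, 1.0)
        evals_s, evecs_s = np.linalg.eigh(sigma)
        if evals_s[m - 1] > 0.0:
            lam_s = _truncated_positive(evals_s)
            p_skat, ok = _qf_sf(q_skat, lam_s)
            if ok:
                out[3 * k + 1] = p_skat
            if m == 1:
                out[3 * k + 1] = out[3 * k]
                out[3 * k + 2] = out[3 * k]
            else:
                out[3 * k + 2] = _skato_p(
                    sigma, evals_s, evecs_s, q_skat, q_bt, rho, allow_coarse
                )
    return out, a_hat


@njit(cache=True)
def _pvalue_matrix(zs, evecs_r, evals_r, weights, rho, fit_a, a_fixed, tol_a):
    """Battery over a (B, M) matrix of Z-vectors -> (B, L) p-values, a_hats.

    Replication loops run with the coarse SKAT-O tier enabled: small
    p-values keep full precision, central ones tolerate ~1e-3.
    """
    b = zs.shape[0]
    n_w = weights.shape[0]
    pmat = np.empty((b, 3 * n_w))
    a_hats = np.empty(b)
    for i in range(b):
        pv, a_hat = _all_pvalues(
            zs[i], evecs_r, evals_r, weights, rho, fit_a, a_fixed, tol_a, True
        )
        pmat[i] = pv
        a_hats[i] = a_hat
    return pmat, a_hats


# ---------------------------------------------------------------------------
# extended Simes combination
# ---------------------------------------------------------------------------


@njit(cache=True)
def _effective_number(corr):
    """l - sum over eigenvalues above one of (lambda - 1); negative
    eigenvalues of a noisy sample correlation are clipped at zero."""
    ev = np.linalg.eigh(corr)[0]
    l = corr.shape[0]
    me = float(l)
    for i in range(l):
        lam = max(ev[i], 0.0)
        if lam > 1.0:
            me -= lam - 1.0
    return me


@njit(cache=True)
def _stable_argsort(p):
    """Insertion-sort argsort; stable, so ties keep canonical label order."""
    n = p.size
    idx = np.arange(n)
    for i in range(1, n):
        key_i = idx[i]
        key = p[key_i]
        j = i - 1
        while j >= 0 and p[idx[j]] > key:
            idx[j + 1] = idx[j]
            j -= 1
        idx[j + 1] = key_i
    return idx


@njit(cache=True)
def _overall_p(pvals, omega):
    """Extended-Simes combined p-value: min over l of m_e p_(l) / m_e(l),
    where m_e(l) is the effective number among the l smallest p-values."""
    l_all = pvals.size
    order = _stable_argsort(pvals)
    me_full = np.empty(l_all)
    for l in range(1, l_all + 1):
        sub = np.empty((l, l))
        for i in range(l):
            for j in range(l):
                sub[i, j] = omega[order[i], order[j]]
        me_full[l - 1] = _effective_number(sub)
    me = me_full[l_all - 1]
    best = 1e300
    for l in range(1, l_all + 1):
        val = me * pvals[order[l - 1]] / me_full[l - 1]
        if val < best:
            best = val
    return min(best, 1.0)


@njit(cache=True)
def _overall_batch(pmat, omega):
    b = pmat.shape[0]
    out = np.empty(b)
    for i in range(b):
        out[i] = _overall_p(pmat[i], omega)
    return out
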