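"""Tail probabilities of weighted sums of 1-df chi-square variables.

The null distributions of the summary-statistic gene-based tests are of the
form Q = sum_i lambda_i * chi2_1. The survival function P(Q > q) is computed
exactly by numerical inversion of the Laplace transform of the survival
function, F_bar^(s) = (1 - M(s)) / s with M(s) = prod_i (1 + 2 lambda_i s)^(-1/2),
on a fixed Talbot contour. All branch points of M lie on the negative real
axis, which is exactly the geometry the Talbot contour is designed for.

Two regimes where contour quadrature loses accuracy in double precision are
handled by dedicated branches:

* q << E[Q] (survival probability near 1): Ruben's mixture-of-central-chi-square
  series, whose terms decay extremely fast for small quantiles;
* deep right tail (p < ~1e-7): Lugannani-Rice saddlepoint approximation,
  which is relatively accurate where the contour sum has exhausted its
  absolute accuracy (~5e-10).

A Liu-type four-cumulant moment-matching approximation is kept as a fallback
for the rare case the exact routine reports failure; its use is logged.

Everything in this module is numba-compiled because the simulation drivers
evaluate these functions tens of millions of times.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

_TALBOT_N = 32
# hand off to the saddlepoint once the Talbot absolute error floor (~5e-10)
# would dominate the relative error
_TAIL_SWITCH = 1e-7
_RUBEN_MAX_TERMS = 20000

P_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# regularized incomplete gamma (for central chi-square CDFs inside kernels)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _gammainc_p(a, x):
    """Regularized lower incomplete gamma P(a, x)."""
    if x <= 0.0:
        return 0.0
    if x < a + 1.0:
        # series representation
        ap = a
        term = 1.0 / a
        total = term
        for _ in range(2000):
            ap += 1.0
            term *= x / ap
            total += term
            if abs(term) < abs(total) * 1e-16:
                break
        return total * math.exp(-x + a * math.log(x) - math.lgamma(a))
    return 1.0 - _gammainc_q_cf(a, x)


@njit(cache=True)
def _gammainc_q_cf(a, x):
    """Regularized upper incomplete gamma Q(a, x) by Lentz continued fraction
    (valid for x >= a + 1)."""
    tiny = 1e-300
    b = x + 1.0 - a
    c = 1.0 / tiny
    d = 1.0 / b
    h = d
    for i in range(1, 2000):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < tiny:
            d = tiny
        c = b + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < 1e-16:
            break
    return h * math.exp(-x + a * math.log(x) - math.lgamma(a))


@njit(cache=True)
def _chi2_cdf(x, df):
    return _gammainc_p(0.5 * df, 0.5 * x)


@njit(cache=True)
def _chi2_sf(x, df):
    if x <= 0.0:
        return 1.0
    if x < df + 2.0:
        return 1.0 - _gammainc_p(0.5 * df, 0.5 * x)
    return _gammainc_q_cf(0.5 * df, 0.5 * x)


@njit(cache=True)
def _norm_ppf_upper(t):
    """x such that P(N(0,1) > x) = t, for t in (0, 1). Newton on erfc."""
    if t >= 0.5:
        sign = -1.0
        t = 1.0 - t
    else:
        sign = 1.0
    if t <= 0.0:
        return sign * 38.0
    # crude start then Newton with exact derivative
    x = math.sqrt(max(-2.0 * math.log(2.0 * t), 1e-12))
    for _ in range(60):
        f = 0.5 * math.erfc(x / math.sqrt(2.0)) - t
        pdf = math.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        if pdf <= 0.0:
            break
        step = f / pdf
        x += step
        if abs(step) < 1e-12 * (1.0 + abs(x)):
            break
    return sign * x


# ---------------------------------------------------------------------------
# Talbot contour inversion
# ---------------------------------------------------------------------------


@njit(cache=True)
def _talbot_sf(q, lam, n_nodes):
    """Survival function by fixed-Talbot inversion of (1 - M(s)) / s."""
    r = 2.0 * n_nodes / (5.0 * q)
    # theta = 0 node (real)
    prod = 1.0
    for i in range(lam.size):
        prod *= 1.0 / math.sqrt(1.0 + 2.0 * lam[i] * r)
    total = 0.5 * math.exp(r * q) * (1.0 - prod) / r
    for k in range(1, n_nodes):
        th = k * math.pi / n_nodes
        cot = math.cos(th) / math.sin(th)
        s = complex(r * th * cot, r * th)
        sigma = th + (th * cot - 1.0) * cot
        m = complex(1.0, 0.0)
        for i in range(lam.size):
            # principal-branch factor-by-factor sqrt keeps the right branch
            m *= 1.0 / np.sqrt(1.0 + 2.0 * lam[i] * s)
        val = np.exp(q * s) * ((1.0 - m) / s) * complex(1.0, sigma)
        total += val.real
    return total * r / n_nodes


@njit(cache=True)
def _talbot_pdf(q, lam, n_nodes):
    """Density by fixed-Talbot inversion of M(s)."""
    r = 2.0 * n_nodes / (5.0 * q)
    prod = 1.0
    for i in range(lam.size):
        prod *= 1.0 / math.sqrt(1.0 + 2.0 * lam[i] * r)
    total = 0.5 * math.exp(r * q) * prod
    for k in range(1, n_nodes):
        th = k * math.pi / n_nodes
        cot = math.cos(th) / math.sin(th)
        s = complex(r * th * cot, r * th)
        sigma = th + (th * cot - 1.0) * cot
        m = complex(1.0, 0.0)
        for i in range(lam.size):
            m *= 1.0 / np.sqrt(1.0 + 2.0 * lam[i] * s)
        val = np.exp(q * s) * m * complex(1.0, sigma)
        total += val.real
    return total * r / n_nodes


# ---------------------------------------------------------------------------
# Ruben series (small-quantile branch)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ruben_sf(q, lam, max_terms):
    """Survival function via Ruben's central chi-square series.

    Returns (value, converged). With beta < min(lam) all mixing weights are
    non-negative and sum to one, giving a rigorous truncation bound.
    """
    n = lam.size
    lmin = lam[0]
    lmax = lam[0]
    for i in range(n):
        if lam[i] < lmin:
            lmin = lam[i]
        if lam[i] > lmax:
            lmax = lam[i]
    beta = 0.90625 * lmin
    # the mixing weights decay geometrically at rate ~(1 - beta/lmax); bail
    # out immediately when the series cannot reach 1e-13 within the cap
    projected = 32.0 * lmax / beta
    if projected > max_terms:
        return 0.0, False
    a0 = 1.0
    for i in range(n):
        a0 *= math.sqrt(beta / lam[i])
    x = q / beta
    gk = np.empty(max_terms + 1)
    ak = np.empty(max_terms + 1)
    ak[0] = a0
    total_a = a0
    cdf = a0 * _chi2_cdf(x, n)
    for k in range(1, max_terms + 1):
        g = 0.0
        for i in range(n):
            g += (1.0 - beta / lam[i]) ** k
        gk[k] = g
        s = 0.0
        for j in range(k):
            s += gk[k - j] * ak[j]
        a = s / (2.0 * k)
        ak[k] = a
        total_a += a
        f = _chi2_cdf(x, n + 2 * k)
        cdf += a * f
        if (1.0 - total_a) * f < 1e-13:
            return 1.0 - cdf, True
    return 1.0 - cdf, False


# ---------------------------------------------------------------------------
# saddlepoint (deep-tail branch)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _saddle_sf(q, lam):
    """Lugannani-Rice saddlepoint survival approximation."""
    n = lam.size
    lmax = lam[0]
    mean = 0.0
    for i in range(n):
        if lam[i] > lmax:
            lmax = lam[i]
        mean += lam[i]
    if q <= mean:
        # saddlepoint at the mean degenerates; not used there in practice
        return 0.5
    # solve K'(s) = q for s in (0, 1/(2 lmax)) by bisection
    lo = 0.0
    hi = 0.5 / lmax - 1e-13 / lmax
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        kp = 0.0
        for i in range(n):
            kp += lam[i] / (1.0 - 2.0 * lam[i] * mid)
        if kp < q:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15 * hi:
            break
    s = 0.5 * (lo + hi)
    kval = 0.0
    kpp = 0.0
    for i in range(n):
        u = 1.0 - 2.0 * lam[i] * s
        kval += -0.5 * math.log(u)
        kpp += 2.0 * lam[i] * lam[i] / (u * u)
    w = math.sqrt(max(2.0 * (s * q - kval), 0.0))
    if w <= 0.0 or kpp <= 0.0:
        return 0.5
    v = s * math.sqrt(kpp)
    z = w + math.log(v / w) / w
    return 0.5 * math.erfc(z / math.sqrt(2.0))


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------


@njit(cache=True)
def _qf_sf(q, lam):
    """P(sum lam_i chi2_1 > q) for lam > 0. Returns (p, ok)."""
    n = lam.size
    if n == 0:
        return 1.0, False
    if q <= 0.0:
        return 1.0, True
    lmax = lam[0]
    lmin = lam[0]
    total = 0.0
    for i in range(n):
        if lam[i] > lmax:
            lmax = lam[i]
        if lam[i] < lmin:
            lmin = lam[i]
        total += lam[i]
    if lmax <= 0.0:
        return 1.0, False
    if (lmax - lmin) < 1e-13 * lmax:
        # all eigenvalues equal: scaled central chi-square, exact
        return _chi2_sf(q / lmax, n), True
    if q < 0.05 * total:
        p, ok = _ruben_sf(q, lam, _RUBEN_MAX_TERMS)
        if ok and p >= -1e-9 and p <= 1.0 + 1e-9:
            return min(max(p, 0.0), 1.0), True
    p = _talbot_sf(q, lam, _TALBOT_N)
    if p != p:  # NaN
        return 1.0, False
    if p < _TAIL_SWITCH:
        return _saddle_sf(q, lam), True
    if p > 1.0 + 1e-6:
        return 1.0, False
    return min(p, 1.0), True


@njit(cache=True)
def _qf_pdf(q, lam):
    if q <= 0.0:
        return 0.0
    return _talbot_pdf(q, lam, _TALBOT_N)


@njit(cache=True)
def _nc_qf_sf(q, lam, delta, n_nodes=24):
    """Survival function of a noncentral weighted chi-square sum,
    P(sum_i lam_i chi2_1(delta_i) > q), by fixed-Talbot inversion.

    The Laplace transform is
    prod_i (1 + 2 lam_i s)^(-1/2) exp(-s delta_i lam_i / (1 + 2 lam_i s)).
    Absolute accuracy ~1e-8 away from the extreme q << E[Q] regime, which
    is adequate for the conditional SKAT-O integrand this serves.
    """
    if q <= 0.0:
        return 1.0
    mean = 0.0
    for i in range(lam.size):
        mean += lam[i] * (1.0 + delta[i])
    if q < 1e-3 * mean:
        # far left of the distribution; the contour sum can overflow there
        # and the survival probability is 1 to far beyond double precision
        return 1.0
    r = 2.0 * n_nodes / (5.0 * q)
    # real node
    prod = 1.0
    expo = 0.0
    for i in range(lam.size):
        z = 1.0 + 2.0 * lam[i] * r
        prod *= 1.0 / math.sqrt(z)
        expo += -r * delta[i] * lam[i] / z
    total = 0.5 * math.exp(r * q) * (1.0 - prod * math.exp(expo)) / r
    for k in range(1, n_nodes):
        th = k * math.pi / n_nodes
        cot = math.cos(th) / math.sin(th)
        s = complex(r * th * cot, r * th)
        sigma = th + (th * cot - 1.0) * cot
        m = complex(1.0, 0.0)
        e = complex(0.0, 0.0)
        for i in range(lam.size):
            z = 1.0 + 2.0 * lam[i] * s
            m *= 1.0 / np.sqrt(z)
            e += -s * delta[i] * lam[i] / z
        val = np.exp(q * s) * ((1.0 - m * np.exp(e)) / s) * complex(1.0, sigma)
        total += val.real
    p = total * r / n_nodes
    if p != p:  # overflow/NaN: conservative limit by position relative to mean
        return 1.0 if q < mean else 0.0
    return min(max(p, 0.0), 1.0)


@njit(cache=True)
def _qf_quantile_upper(t, lam, q_init=-1.0, tol_log=1e-6):
    """q such that P(Q > q) = t, by safeguarded Newton in log space.

    ``q_init`` > 0 warm-starts the search (e.g. from the quantile of a
    related eigenvalue set); otherwise a Wilson-Hilferty moment-matched
    start is used. ``tol_log`` is the convergence tolerance on log P.
    """
    n = lam.size
    mean = 0.0
    var = 0.0
    for i in range(n):
        mean += lam[i]
        var += 2.0 * lam[i] * lam[i]
    if q_init > 0.0:
        q = q_init
    else:
        # Wilson-Hilferty start from a scale/df matched chi-square
        c = var / (2.0 * mean)
        df = 2.0 * mean * mean / var
        z = _norm_ppf_upper(t)
        h = 2.0 / (9.0 * df)
        q = c * df * (1.0 - h + z * math.sqrt(h)) ** 3
    if q <= 0.0:
        q = 1e-8 * mean
    lo = 0.0
    hi = -1.0  # unset
    logt = math.log(t)
    for _ in range(30):
        p, ok = _qf_sf(q, lam)
        if not ok:
            break
        if p > t:
            lo = max(lo, q)
        else:
            hi = q if hi < 0.0 else min(hi, q)
        err = math.log(max(p, P_FLOOR)) - logt
        if abs(err) < tol_log:
            return q
        pdf = _qf_pdf(q, lam)
        if pdf <= 0.0 or p <= 0.0:
            break
        step = err * p / pdf  # Newton on log sf
        qn = q + step
        if qn <= lo or (hi > 0.0 and qn >= hi):
            qn = 0.5 * (lo + hi) if hi > 0.0 else 2.0 * q
        if abs(qn - q) < 1e-12 * (1.0 + q):
            return qn
        q = qn
    # bisection rescue
    if hi < 0.0:
        hi = q
        for _ in range(200):
            p, _ok = _qf_sf(hi, lam)
            if p <= t:
                break
            hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        p, _ok = _qf_sf(mid, lam)
        if p > t:
            lo = mid
        else:
            hi = mid
        if abs(math.log(max(p, P_FLOOR)) - logt) < tol_log:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# python-level wrapper with Liu fallback
# ---------------------------------------------------------------------------


def _liu_sf(q, lam):
    """Liu et al. four-cumulant moment-matching approximation (fallback)."""
    from scipy.stats import ncx2

    lam = np.asarray(lam, dtype=float)
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2.0 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2
    mu_x = dof + delta
    sigma_x = math.sqrt(2.0 * (dof + 2.0 * delta))
    t_star = (q - c1) / math.sqrt(2.0 * c2)
    return float(ncx2.sf(t_star * sigma_x + mu_x, dof, delta))


def quad_form_pvalue(q, lambdas):
    """P(sum_i lambda_i chi2_1 > q), the tail probability of a quadratic form
    in standard normal variables.

    Parameters
    ----------
    q
        Observed value of the quadratic form (must be >= 0).
    lambdas
        Eigenvalue weights. Non-positive entries are dropped; at least one
        entry must be positive.

    Returns
    -------
    float
        The tail probability, floored at ``1e-300``. Exact inversion is used;
        a Liu-type moment-matching approximation is substituted (and logged)
        only if the exact routine reports failure.
    """
    lam = np.ascontiguousarray(np.asarray(lambdas, dtype=float).ravel())
    lam = lam[lam > 0.0]
    if lam.size == 0:
        raise ValueError("quad_form_pvalue requires at least one positive eigenvalue")
    q = float(q)
    if q < 0:
        raise ValueError("quadratic form statistic must be non-negative")
    p, ok = _qf_sf(q, lam)
    if not ok or not np.isfinite(p):
        logger.warning(
            "exact quadratic-form inversion failed (q=%g, %d eigenvalues); "
            "using Liu moment-matching fallback",
            q,
            lam.size,
        )
        p = _liu_sf(q, lam)
    return float(min(max(p, P_FLOOR), 1.0))
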