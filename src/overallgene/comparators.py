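"""Comparison methods: the Cauchy omnibus combination (OT) and the
summary-statistic TWAS tests (S-TWAS, S-PrediXcan).

These are the reference methods the extended-Simes combination is bench-
marked against. OT aggregates the same battery of p-values through the
Cauchy combination; S-TWAS and S-PrediXcan test a single weighted linear
combination of Z-scores against a standard normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .gene_tests import DegenerateTestError

__all__ = ["PredixcanInput", "cauchy_combine", "s_twas", "s_predixcan"]

_CLIP = 1e-15


@dataclass(frozen=True)
class PredixcanInput:
    """Per-SNP genotype standard deviations and the SD of predicted expression.

    When ``snp_sd`` is None, genotypes are treated as standardized
    (sigma_m = 1) and ``expr_sd`` may be auto-computed from the weights and
    LD as sqrt(w' diag(sd) R diag(sd) w).
    """

    snp_sd: np.ndarray | None = None
    expr_sd: float | None = None


def cauchy_combine(p):
    """Cauchy combination of p-values.

    Q is the mean of tan((0.5 - p_i) pi); the combined p-value is
    0.5 - arctan(Q) / pi. Inputs are clipped into [1e-15, 1 - 1e-15] to keep
    the tangent finite.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    p = np.clip(p, _CLIP, 1.0 - _CLIP)
    q = np.mean(np.tan((0.5 - p) * np.pi))
    return float(0.5 - math.atan(q) / math.pi)


def s_twas(Z, R, w):
    """S-TWAS: z = w'Z / sqrt(w'Rw), two-sided normal p-value.

    Returns (z_stat, p).
    """
    Z = np.asarray(Z, dtype=float).ravel()
    R = np.asarray(R, dtype=float)
    w = np.asarray(w, dtype=float).ravel()
    denom = float(w @ R @ w)
    if denom <= 1e-12:
        raise DegenerateTestError("weighted LD variance is zero")
    z = float(w @ Z) / math.sqrt(denom)
    return z, float(2.0 * norm.sf(abs(z)))


def s_predixcan(Z, pred_input, w, R=None):
    """S-PrediXcan: z = sum_m w_m sigma_m Z_m / sigma, two-sided normal p.

    With unit SNP standard deviations and an auto-computed expression SD
    this coincides with S-TWAS. Returns (z_stat, p).
    """
    Z = np.asarray(Z, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    snp_sd = pred_input.snp_sd
    if snp_sd is None:
        snp_sd = np.ones_like(w)
    else:
        snp_sd = np.asarray(snp_sd, dtype=float).ravel()
        if np.any(snp_sd <= 0):
            raise ValueError("SNP standard deviations must be positive")
    expr_sd = pred_input.expr_sd
    if expr_sd is None:
        if R is None:
            raise ValueError("need R to auto-compute the expression SD")
        ws = w * snp_sd
        var = float(ws @ np.asarray(R, dtype=float) @ ws)
        if var <= 1e-24:
            raise DegenerateTestError("predicted expression has zero variance")
        expr_sd = math.sqrt(var)
    if expr_sd <= 0:
        raise ValueError("expression SD must be positive")
    z = float(np.sum(w * snp_sd * Z)) / float(expr_sd)
    return z, float(2.0 * norm.sf(abs(z)))
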