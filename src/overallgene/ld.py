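"""Regularization of reference-panel LD matrices.

When the LD (correlation) matrix R of the variants in a gene is estimated
from a small external reference panel, sampling noise can inflate gene-based
test statistics. The correction shrinks R toward the identity,

    U = a R + (1 - a) I,    0 <= a <= 1,

with the tuning parameter a chosen by maximizing the likelihood of the
observed Z-vector under Z ~ MVN(0, U). Because U shares eigenvectors with R,
the likelihood is evaluated in R's eigenbasis, which makes the 1-D
optimization essentially free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import _estimate_a, _nll_eig

__all__ = ["CorrectedLD", "neg_log_likelihood", "estimate_tuning", "corrected_ld"]


@dataclass(frozen=True)
class CorrectedLD:
    """A reference LD matrix together with its shrinkage correction."""

    R: np.ndarray
    a_hat: float
    U: np.ndarray = field(repr=False)

    def __post_init__(self):
        if not 0.0 <= self.a_hat <= 1.0:
            raise ValueError(f"tuning parameter must lie in [0, 1], got {self.a_hat}")


def _check_corr(R):
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be a square matrix")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("R must have a unit diagonal")
    return R


def neg_log_likelihood(Z, R, a):
    """Negative log-likelihood (up to a constant) of Z ~ MVN(0, aR + (1-a)I).

    Returns 0.5 * (log det U + Z' U^-1 Z). When U is numerically singular
    (a = 1 with a rank-deficient R), a ridge of 1e-10 is applied for the
    evaluation only.
    """
    Z = np.asarray(Z, dtype=float).ravel()
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z contains non-finite entries")
    R = _check_corr(R)
    if Z.size != R.shape[0]:
        raise ValueError("Z and R dimensions disagree")
    if not 0.0 <= a <= 1.0:
        raise ValueError("a must lie in [0, 1]")
    evals, evecs = np.linalg.eigh(R)
    v2 = (evecs.T @ Z) ** 2
    return float(_nll_eig(float(a), np.ascontiguousarray(evals), np.ascontiguousarray(v2)))


def estimate_tuning(Z, R, tol=1e-4):
    """Maximum-likelihood estimate of the shrinkage parameter a in [0, 1].

    A 21-point grid scan seeds a golden-section search; the result is
    accurate to ``tol``. On a flat likelihood (e.g. R = I) ties are broken
    toward a = 1 so that a perfectly estimated LD matrix is not shrunk.
    """
    Z = np.asarray(Z, dtype=float).ravel()
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z contains non-finite entries")
    R = _check_corr(R)
    evals, evecs = np.linalg.eigh(R)
    v2 = (evecs.T @ Z) ** 2
    return float(
        _estimate_a(np.ascontiguousarray(evals), np.ascontiguousarray(v2), float(tol))
    )


def corrected_ld(R, a_hat):
    """The corrected matrix U = a_hat R + (1 - a_hat) I as a CorrectedLD."""
    R = _check_corr(R)
    if not 0.0 <= a_hat <= 1.0:
        raise ValueError("a_hat must lie in [0, 1]")
    U = a_hat * R + (1.0 - a_hat) * np.eye(R.shape[0])
    return CorrectedLD(R=R, a_hat=float(a_hat), U=U)
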