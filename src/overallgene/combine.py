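"""Combining correlated gene-based test p-values with the extended Simes
procedure, and estimating their null correlation by replication.

Given L p-values p_(1) <= ... <= p_(L) and the correlation matrix Omega of
the p-values under the null, the combined p-value is

    p_overall = min_l  m_e * p_(l) / m_e(l),

where m_e(l) = l - sum_i (lambda_i - 1) I(lambda_i > 1) is the effective
number of tests among the l smallest p-values (eigenvalues of the
corresponding Omega submatrix) and m_e = m_e(L). With independent tests this
reduces to the classical Simes procedure; with perfectly dependent tests it
returns the smallest p-value unchanged.

Omega is unknown analytically and is estimated once per gene by replication:
draw Z ~ MVN(0, R) under the null, rerun the full battery (including the
per-replicate shrinkage refit), and take the sample correlation of the
resulting p-value columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import _effective_number, _overall_batch, _pvalue_matrix
from .gene_tests import DEFAULT_RHO_GRID, WeightSet

logger = logging.getLogger(__name__)

__all__ = [
    "PValueCorrelation",
    "OverallResult",
    "effective_number",
    "overall_pvalue",
    "estimate_null_correlation",
    "omega_convergence",
]


@dataclass(frozen=True)
class PValueCorrelation:
    """Null correlation matrix of the L test p-values."""

    labels: tuple
    Omega: np.ndarray

    def __post_init__(self):
        om = self.Omega
        if om.shape != (len(self.labels), len(self.labels)):
            raise ValueError("Omega shape disagrees with labels")
        if not np.allclose(om, om.T, atol=1e-10):
            raise ValueError("Omega must be symmetric")
        if not np.allclose(np.diag(om), 1.0, atol=1e-10):
            raise ValueError("Omega must have a unit diagonal")
        if np.any(np.abs(om) > 1.0 + 1e-8):
            raise ValueError("Omega entries must lie in [-1, 1]")

    def to_frame(self):
        return pd.DataFrame(self.Omega, index=list(self.labels), columns=list(self.labels))

    @classmethod
    def from_frame(cls, frame):
        return cls(labels=tuple(frame.columns), Omega=np.ascontiguousarray(frame.to_numpy(float)))


@dataclass(frozen=True)
class OverallResult:
    p_overall: float
    m_e: float
    m_e_per_rank: np.ndarray
    ordering: tuple  # labels by ascending p-value


def effective_number(sub_corr):
    """Effective number of tests of a correlation matrix.

    l minus the excess above one of each eigenvalue; negative sampling
    eigenvalues are clipped at zero (and the clip logged) before use.
    """
    sub = np.ascontiguousarray(np.asarray(sub_corr, dtype=float))
    if sub.ndim != 2 or sub.shape[0] != sub.shape[1]:
        raise ValueError("need a square correlation matrix")
    ev = np.linalg.eigvalsh(sub)
    if ev[0] < -1e-10:
        logger.debug("clipping negative eigenvalue %.3g in effective-number computation", ev[0])
    return float(_effective_number(sub))


def overall_pvalue(p, Omega):
    """Extended-Simes combination of labeled p-values.

    Parameters
    ----------
    p
        Mapping label -> p-value, or a pandas Series indexed by label.
    Omega
        PValueCorrelation whose labels match p's as a set.
    """
    if isinstance(p, pd.Series):
        p = p.to_dict()
    labels = list(p.keys())
    if set(labels) != set(Omega.labels):
        raise ValueError("p-value labels and Omega labels disagree")
    # canonical order = Omega's label order; stable sort then fixes ties
    pv = np.array([float(p[lab]) for lab in Omega.labels])
    order = np.argsort(pv, kind="stable")
    l_all = pv.size
    me_per_rank = np.empty(l_all)
    for l in range(1, l_all + 1):
        idx = order[:l]
        me_per_rank[l - 1] = effective_number(Omega.Omega[np.ix_(idx, idx)])
    m_e = me_per_rank[-1]
    p_overall = float(min(np.min(m_e * pv[order] / me_per_rank), 1.0))
    return OverallResult(
        p_overall=p_overall,
        m_e=float(m_e),
        m_e_per_rank=me_per_rank,
        ordering=tuple(Omega.labels[i] for i in order),
    )


def _null_pvalue_matrix(R, weights, B, rng, grid, refit_a, a_fixed):
    """(B, L) matrix of null-replicate p-values (NaN for degenerate tests)."""
    R = np.asarray(R, dtype=float)
    evals, evecs = np.linalg.eigh(R)
    chol = evecs * np.sqrt(np.clip(evals, 0.0, None))
    zs = rng.standard_normal((B, R.shape[0])) @ chol.T
    pmat, a_hats = _pvalue_matrix(
        np.ascontiguousarray(zs),
        np.ascontiguousarray(evecs),
        np.ascontiguousarray(evals),
        np.ascontiguousarray(weights.W),
        np.ascontiguousarray(np.asarray(grid, dtype=float)),
        bool(refit_a),
        float(a_fixed),
        1e-4,
    )
    return pmat, a_hats


def estimate_null_correlation(R, weights, B=1000, seed=None, grid=None, refit_a=True, a_fixed=1.0):
    """Estimate Omega by B null replications.

    For each replicate, Z ~ MVN(0, R) is drawn, the shrinkage parameter is
    refit (the default; set refit_a=False to freeze it at ``a_fixed``), the
    full battery of p-values is computed, and Omega is the Pearson sample
    correlation of the p-value columns across replicates. Columns that are
    constant across replicates get zero correlation with a warning.
    """
    if B < 2:
        raise ValueError("need at least B = 2 replications")
    if not isinstance(weights, WeightSet):
        raise TypeError("weights must be a WeightSet")
    rho = DEFAULT_RHO_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    pmat, _ = _null_pvalue_matrix(R, weights, B, rng, rho, refit_a, a_fixed)
    labels = weights.test_labels()
    # isolated numerical failures lose their replicate; persistent failures
    # lose the test column
    bad_rows = ~np.isfinite(pmat).all(axis=1)
    if bad_rows.any() and bad_rows.mean() <= 0.05:
        logger.warning("dropping %d replicates with failed p-values", int(bad_rows.sum()))
        pmat = pmat[~bad_rows]
    keep = np.isfinite(pmat).all(axis=0)
    if not keep.all():
        logger.warning(
            "dropping degenerate tests from Omega: %s",
            ", ".join(lab for lab, k in zip(labels, keep) if not k),
        )
    pmat = pmat[:, keep]
    labels = [lab for lab, k in zip(labels, keep) if k]
    sd = pmat.std(axis=0)
    constant = sd <= 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = np.corrcoef(pmat, rowvar=False)
    if constant.any():
        logger.warning(
            "constant p-value columns across replicates (degenerate): %s",
            ", ".join(lab for lab, c in zip(labels, constant) if c),
        )
        omega[np.isnan(omega)] = 0.0
    np.fill_diagonal(omega, 1.0)
    omega = np.clip((omega + omega.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(omega, 1.0)
    return PValueCorrelation(labels=tuple(labels), Omega=np.ascontiguousarray(omega))


def omega_convergence(R, weights, B_grid, B_ref, seed=None, grid=None):
    """Distance of Omega estimates at increasing B from a large-B reference.

    Each B in ``B_grid`` reuses the first B replicates of the reference
    stream, so B = B_ref reproduces the reference exactly and the distances
    are monotone in expectation. Returns a DataFrame with one row per B.
    """
    B_grid = sorted(int(b) for b in B_grid)
    if B_ref < max(B_grid):
        raise ValueError("B_ref must be at least max(B_grid)")
    rho = DEFAULT_RHO_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    pmat, _ = _null_pvalue_matrix(R, weights, B_ref, rng, rho, True, 1.0)
    keep = np.isfinite(pmat).all(axis=0)
    pmat = pmat[:, keep]

    def corr_of(mat):
        with np.errstate(invalid="ignore", divide="ignore"):
            om = np.corrcoef(mat, rowvar=False)
        om[np.isnan(om)] = 0.0
        np.fill_diagonal(om, 1.0)
        return om

    ref = corr_of(pmat)
    rows = []
    for b in B_grid:
        om = corr_of(pmat[:b])
        diff = om - ref
        rows.append(
            {
                "B": b,
                "max_abs_diff": float(np.abs(diff).max()),
                "frobenius": float(np.linalg.norm(diff)),
            }
        )
    return pd.DataFrame(rows)


def overall_pvalue_batch(pmat, Omega):
    """Vector of extended-Simes p-values for a (B, L) p-value matrix."""
    return _overall_batch(np.ascontiguousarray(pmat), np.ascontiguousarray(Omega.Omega))
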