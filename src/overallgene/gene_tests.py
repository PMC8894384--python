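"""Weighted burden, SKAT, and SKAT-O tests from GWAS summary statistics.

All three tests operate on the per-gene Z-score vector under the null model
Z ~ MVN(0, U), where U is the (shrinkage-corrected) LD matrix, with an
optional diagonal weight matrix W_k derived from an eQTL study:

* burden (BT):  Q = (Z' W 1)^2, referred to a 1-df chi-square after scaling
  by its null variance 1' W U W 1;
* SKAT:         Q = (W Z)' (W Z), a quadratic form whose null is the mixture
  of 1-df chi-squares weighted by the eigenvalues of Sigma = W U W;
* SKAT-O:       min over rho of (1-rho) Q_SKAT + rho Q_BT, calibrated by the
  conditional-integration construction of the optimal-rho mixture null.

Raw eQTL weights are standardized to unit absolute sum so that only their
relative pattern across variants (and sign) matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kernels import _all_pvalues, _skato_p, _truncated_positive
from ._quadform import quad_form_pvalue  # noqa: F401  (re-exported)
from ._quadform import _chi2_sf

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_RHO_GRID",
    "WeightSet",
    "DegenerateTestError",
    "standardize_weights",
    "quad_form_pvalue",
    "bt_test",
    "skat_test",
    "skato_test",
    "all_tests",
]

# mirrors the canonical SKAT-O grid: rho = (0, 0.1, ..., 0.9)^2 plus 1
DEFAULT_RHO_GRID = np.array([0.0] + [(0.1 * i) ** 2 for i in range(1, 10)] + [1.0])

TESTS = ("BT", "SKAT", "SKATO")


class DegenerateTestError(ValueError):
    """A test statistic has no usable null distribution for this input."""


def standardize_weights(raw):
    """Standardize a raw weight vector to unit absolute sum.

    w_m = raw_m / sum_m |raw_m|; signs are preserved. An all-zero vector is
    degenerate (the study carries no information for this gene).
    """
    raw = np.asarray(raw, dtype=float).ravel()
    denom = np.abs(raw).sum()
    if denom <= 0.0:
        raise DegenerateTestError("all-zero weight vector cannot be standardized")
    return raw / denom


@dataclass(frozen=True)
class WeightSet:
    """K standardized eQTL weight vectors plus the unweighted baseline.

    ``W`` has shape (K+1, M); row 0 is all ones (the unweighted test), rows
    1..K have unit absolute sum. ``labels`` names each row; index 0 is
    "unweighted".
    """

    labels: tuple
    W: np.ndarray

    def __post_init__(self):
        if self.W.ndim != 2 or len(self.labels) != self.W.shape[0]:
            raise ValueError("labels and weight rows disagree")
        if not np.allclose(self.W[0], 1.0):
            raise ValueError("row 0 must be the unweighted all-ones vector")
        sums = np.abs(self.W[1:]).sum(axis=1)
        if sums.size and not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("weight rows 1..K must have unit absolute sum")

    @classmethod
    def from_raw(cls, raw, labels=None):
        """Build from an M x K matrix of raw per-study weights.

        Studies whose weight vector is all zero are dropped with a warning.
        """
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        if raw.shape[0] < raw.shape[1] and raw.ndim == 2 and labels is None:
            pass  # orientation is the caller's contract: rows = variants
        m, k = raw.shape
        if labels is None:
            labels = [f"study{i + 1}" for i in range(k)]
        rows = [np.ones(m)]
        names = ["unweighted"]
        for i in range(k):
            try:
                rows.append(standardize_weights(raw[:, i]))
                names.append(str(labels[i]))
            except DegenerateTestError:
                logger.warning("dropping all-zero weight study %r", labels[i])
        return cls(labels=tuple(names), W=np.ascontiguousarray(np.vstack(rows)))

    @property
    def n_studies(self):
        return self.W.shape[0] - 1

    @property
    def n_variants(self):
        return self.W.shape[1]

    def test_labels(self):
        """Canonical label order: (BT_k, SKAT_k, SKATO_k) for k = 0..K."""
        return [f"{t}_{lab}" for lab in self.labels for t in TESTS]


def _prep(Z, U, w):
    Z = np.asarray(Z, dtype=float).ravel()
    U = np.asarray(U, dtype=float)
    w = np.asarray(w, dtype=float).ravel()
    if U.shape != (Z.size, Z.size) or w.size != Z.size:
        raise ValueError("Z, U, and the weight vector must agree in size")
    return Z, U, w


def bt_test(Z, U, w):
    """Weighted burden test p-value.

    Q = (Z' W 1)^2 has null variance v = 1' W U W 1; Q / v is a 1-df
    chi-square under the null.
    """
    Z, U, w = _prep(Z, U, w)
    v = float(w @ U @ w)
    if v <= 1e-12:
        raise DegenerateTestError("burden null variance is zero (weights orthogonal to signal)")
    q = float(w @ Z) ** 2
    return max(float(_chi2_sf(q / v, 1.0)), 1e-300)


def skat_test(Z, U, w):
    """Weighted SKAT p-value: Q = Z' W^2 Z against the eigenvalues of W U W."""
    Z, U, w = _prep(Z, U, w)
    sigma = (w[:, None] * U) * w[None, :]
    evals = np.linalg.eigvalsh(sigma)
    if evals[-1] <= 0.0:
        raise DegenerateTestError("weighted null covariance has no positive eigenvalue")
    lam = _truncated_positive(np.ascontiguousarray(evals))
    q = float(np.sum((w * Z) ** 2))
    return quad_form_pvalue(q, lam)


def skato_test(Z, U, w, grid=None):
    """SKAT-O p-value over a rho grid (defaults to the canonical 11 points)."""
    Z, U, w = _prep(Z, U, w)
    rho = DEFAULT_RHO_GRID if grid is None else np.asarray(grid, dtype=float).ravel()
    if rho.size == 0 or np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("rho grid must be non-empty with values in [0, 1]")
    if np.any(np.diff(rho) <= 0) and rho.size > 1:
        raise ValueError("rho grid must be strictly increasing")
    if Z.size == 1:
        return bt_test(Z, U, w)
    if rho.size == 1:
        if rho[0] == 0.0:
            return skat_test(Z, U, w)
        if rho[0] == 1.0:
            return bt_test(Z, U, w)
    sigma = (w[:, None] * U) * w[None, :]
    evals, evecs = np.linalg.eigh(sigma)
    if evals[-1] <= 0.0:
        raise DegenerateTestError("weighted null covariance has no positive eigenvalue")
    q_skat = float(np.sum((w * Z) ** 2))
    q_bt = float(w @ Z) ** 2
    p = float(
        _skato_p(
            np.ascontiguousarray(sigma),
            np.ascontiguousarray(evals),
            np.ascontiguousarray(evecs),
            q_skat,
            q_bt,
            np.ascontiguousarray(rho),
        )
    )
    return max(p, 1e-300)


def all_tests(Z, U, weights, grid=None):
    """All L = 3(K+1) p-values in canonical label order.

    Returns (labels, p-values). Degenerate individual tests are dropped from
    the output (and logged), reducing L; the correlation-matrix handling
    downstream works on the surviving labels.
    """
    Z = np.asarray(Z, dtype=float).ravel()
    U = np.asarray(U, dtype=float)
    if not isinstance(weights, WeightSet):
        raise TypeError("weights must be a WeightSet")
    if weights.n_variants != Z.size:
        raise ValueError("weight length disagrees with Z")
    rho = DEFAULT_RHO_GRID if grid is None else np.asarray(grid, dtype=float).ravel()
    evals, evecs = np.linalg.eigh(U)
    # the kernel consumes R-eigenpairs and refits a; passing U's eigenpairs
    # with a frozen a = 1 evaluates the battery exactly at U
    pvals, _ = _all_pvalues(
        np.ascontiguousarray(Z),
        np.ascontiguousarray(evecs),
        np.ascontiguousarray(evals),
        np.ascontiguousarray(weights.W),
        np.ascontiguousarray(rho),
        False,
        1.0,
        1e-4,
    )
    labels = weights.test_labels()
    keep = np.isfinite(pvals)
    if not keep.all():
        dropped = [lab for lab, k in zip(labels, keep) if not k]
        logger.warning("dropping degenerate tests: %s", ", ".join(dropped))
    out_labels = [lab for lab, k in zip(labels, keep) if k]
    out_p = np.clip(pvals[keep], 1e-300, 1.0)
    return out_labels, out_p
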