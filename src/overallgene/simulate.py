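"""Synthetic data generation for the simulation studies.

The generative model mirrors a standard TWAS-style simulation design:

1. genotypes are drawn by sampling pairs of haplotypes from a pool
   (a synthetic pool generator based on a latent-Gaussian threshold model
   stands in for a real reference panel), removing variants with
   MAF < 0.05;
2. for each of K expression studies, a random subset of causal variants
   receives standard-normal weights, rescaled so that the genetic score
   X w explains a target fraction h_e^2 of expression variance:
   E_k = X w_k + eps_e, eps_e ~ N(0, 1 - h_e^2);
3. the phenotype aggregates the K expression components,
   Y = E beta + eps_p, eps_p ~ N(0, 1 - h_p^2), with per-study effects
   beta_k = beta_0 = sqrt(h_p^2 / K) arranged by scenario (uni- or
   bi-directional, optionally perturbed by tissue-relevance noise);
4. per-variant Z-scores are the OLS t-statistics of Y on each dosage
   column, i.e. exactly what a GWAS would release.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "SimulationConfig",
    "HaplotypePool",
    "CohortData",
    "synth_ld",
    "synth_haplotype_pool",
    "generate_genotypes",
    "generate_weights_and_expression",
    "generate_phenotype",
    "compute_z_scores",
]

SCENARIOS = ("uni", "bi", "uni_noise", "bi_noise")


@dataclass
class SimulationConfig:
    """Parameters of one simulation cell.

    h_e2 is the expression heritability (variance fraction of each
    expression trait explained by its genetic score), h_p2 the phenotypic
    heritability (variance fraction of the phenotype explained by the
    expression-mediated effects). beta0 = sqrt(h_p2 / K) is derived.
    """

    M: int = 23
    K: int = 4
    p_causal: float = 0.2
    h_e2: float = 0.2
    h_p2: float = 0.2
    n: int = 2000
    scenario: str = "uni"
    maf_floor: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not 0.0 < self.p_causal <= 1.0:
            raise ValueError("p_causal must lie in (0, 1]")
        for name in ("h_e2", "h_p2"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.scenario in ("uni_noise", "bi_noise") and self.K != 4:
            raise ValueError("the tissue-relevance noise scenarios are defined for K = 4")

    @property
    def beta0(self):
        return float(np.sqrt(self.h_p2 / self.K))

    @property
    def m_causal(self):
        return max(1, int(round(self.M * self.p_causal)))


@dataclass(frozen=True)
class HaplotypePool:
    """A pool of binary haplotypes; columns define variant frequencies."""

    H: np.ndarray
    frequencies: np.ndarray | None = None

    def __post_init__(self):
        if self.H.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if not np.isin(self.H, (0, 1)).all():
            raise ValueError("haplotypes must be binary")
        if self.frequencies is not None:
            f = self.frequencies
            if f.shape != (self.H.shape[0],) or np.any(f < 0):
                raise ValueError("frequencies must be non-negative, one per haplotype")

    @property
    def n_haplotypes(self):
        return self.H.shape[0]

    @property
    def n_variants(self):
        return self.H.shape[1]


@dataclass
class CohortData:
    """One simulated cohort: genotypes, expression, phenotype and truth."""

    X: np.ndarray
    E: np.ndarray
    Y: np.ndarray
    w_true: np.ndarray
    beta: np.ndarray
    kept_variants: np.ndarray


def synth_ld(M, structure="ar1", rho=0.5, block_size=5, seed=None):
    """Synthetic correlation matrix: ar1 (rho^|i-j|), block, or exchangeable.

    All three are positive semi-definite by construction; the exchangeable
    structure requires rho >= -1/(M-1). ``seed`` is accepted for interface
    uniformity with the stochastic generators but the output is
    deterministic.
    """
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    idx = np.arange(M)
    if structure == "ar1":
        R = rho ** np.abs(idx[:, None] - idx[None, :])
    elif structure == "block":
        blocks = idx // block_size
        R = np.where(blocks[:, None] == blocks[None, :], rho, 0.0)
        np.fill_diagonal(R, 1.0)
        if rho < 0 and block_size > 1 and rho < -1.0 / (block_size - 1):
            raise ValueError("block structure is not PSD for this rho")
    elif structure == "exchangeable":
        if M > 1 and rho < -1.0 / (M - 1):
            raise ValueError("exchangeable structure requires rho >= -1/(M-1)")
        R = np.full((M, M), float(rho))
        np.fill_diagonal(R, 1.0)
    else:
        raise ValueError(f"unknown LD structure {structure!r}")
    return np.ascontiguousarray(R, dtype=float)


def synth_haplotype_pool(M=23, n_hap=458, rho=0.7, maf_range=(0.02, 0.5), seed=None):
    """Synthetic haplotype pool from a latent-Gaussian threshold model.

    Latent vectors with ar1(rho) correlation are thresholded at the normal
    quantile of each variant's target allele frequency, producing binary
    haplotypes whose dosage correlations decay with distance like real
    short-range LD. Defaults emulate a pool of 458 haplotypes over 23
    variants.
    """
    rng = np.random.default_rng(seed)
    R = synth_ld(M, "ar1", rho)
    chol = np.linalg.cholesky(R + 1e-12 * np.eye(M))
    latent = rng.standard_normal((n_hap, M)) @ chol.T
    mafs = rng.uniform(maf_range[0], maf_range[1], size=M)
    H = (latent < norm.ppf(mafs)).astype(np.int8)
    return HaplotypePool(H=H)


def generate_genotypes(pool, n, maf_floor=0.05, seed=None):
    """Dosage matrix from two haplotypes per individual, MAF-filtered.

    Haplotypes are sampled with replacement according to the pool
    frequencies (uniform when absent). Variants whose sample MAF falls
    below ``maf_floor`` are removed; the kept indices are returned so that
    weights and LD can be subset consistently.
    """
    rng = np.random.default_rng(seed)
    if pool.n_haplotypes == 0:
        raise ValueError("empty haplotype pool")
    probs = pool.frequencies
    if probs is not None:
        probs = probs / probs.sum()
    picks = rng.choice(pool.n_haplotypes, size=(n, 2), replace=True, p=probs)
    X = pool.H[picks[:, 0]].astype(np.float64) + pool.H[picks[:, 1]].astype(np.float64)
    freq = X.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    kept = np.flatnonzero(maf >= maf_floor)
    if kept.size == 0:
        raise ValueError("no variant passes the MAF floor")
    return np.ascontiguousarray(X[:, kept]), kept


def generate_weights_and_expression(X, config, rng=None):
    """True eQTL weights and expression levels for K studies.

    Each study draws its own causal subset of size round(M p_causal)
    (minimum 1); causal weights are standard normal and rescaled so the
    sample variance of X w_k equals h_e2 exactly. Expression is
    E_k = X w_k + eps_e with eps_e ~ N(0, 1 - h_e2).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = X.shape
    m_causal = max(1, int(round(m * config.p_causal)))
    W = np.zeros((m, config.K))
    E = np.empty((n, config.K))
    for k in range(config.K):
        for attempt in range(100):
            causal = rng.choice(m, size=m_causal, replace=False)
            w = np.zeros(m)
            w[causal] = rng.standard_normal(m_causal)
            score = X @ w
            var = score.var()
            if var > 1e-12 or config.h_e2 == 0.0:
                break
        else:
            raise ValueError("could not draw a causal set with non-constant genetic score")
        if config.h_e2 > 0.0:
            w *= np.sqrt(config.h_e2 / var)
        else:
            w[:] = 0.0
        W[:, k] = w
        E[:, k] = X @ w + rng.normal(0.0, np.sqrt(1.0 - config.h_e2), size=n)
    return W, E


def _effect_sizes(config, rng):
    k = config.K
    b0 = config.beta0
    if config.h_p2 == 0.0:
        return np.zeros(k)
    if config.scenario == "uni":
        return np.full(k, b0)
    if config.scenario == "bi":
        half = k // 2
        beta = np.full(k, -b0)
        beta[:half] = b0
        return beta
    sd_hi = np.sqrt(0.1 * config.h_p2)  # most relevant tissue(s): less noise
    sd_lo = np.sqrt(0.5 * config.h_p2)
    if config.scenario == "uni_noise":
        return np.array(
            [
                b0 + rng.normal(0.0, sd_hi),
                b0 + rng.normal(0.0, sd_lo),
                b0 + rng.normal(0.0, sd_lo),
                b0 + rng.normal(0.0, sd_lo),
            ]
        )
    # bi_noise: studies 1 and 3 are the relevant tissues with opposite signs
    return np.array(
        [
            -b0 + rng.normal(0.0, sd_hi),
            -b0 + rng.normal(0.0, sd_lo),
            b0 + rng.normal(0.0, sd_hi),
            b0 + rng.normal(0.0, sd_lo),
        ]
    )


def expression_from_weights(X, w, h_e2, rng):
    """Expression for fixed true weights: E_k = X w_k + eps, eps ~ N(0, 1-h_e2).

    Used when the eQTL architecture of a gene is held fixed across
    replicate cohorts (the weights were rescaled to the target expression
    heritability on a reference cohort).
    """
    n = X.shape[0]
    w = np.atleast_2d(np.asarray(w, dtype=float))
    if w.shape[0] != X.shape[1]:
        raise ValueError("weight rows disagree with genotype columns")
    E = X @ w + rng.normal(0.0, np.sqrt(1.0 - h_e2), size=(n, w.shape[1]))
    return E


def generate_phenotype(E, config, rng=None):
    """Phenotype Y = E beta + eps_p and the effect vector beta.

    eps_p ~ N(0, 1 - h_p2); beta follows the configured direction scenario
    with beta0 = sqrt(h_p2 / K).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    E = np.asarray(E, dtype=float)
    if E.shape[1] != config.K:
        raise ValueError("expression matrix has wrong number of studies")
    beta = _effect_sizes(config, rng)
    Y = E @ beta + rng.normal(0.0, np.sqrt(1.0 - config.h_p2), size=E.shape[0])
    return Y, beta


Z_CAP = 1e8


def compute_z_scores(X, Y):
    """Per-variant OLS Z-scores of Y on each dosage column (with intercept).

    The t-statistic of simple linear regression equals
    r sqrt((n-2) / (1-r^2)) for sample correlation r. A perfect fit is
    capped at +/-1e8; constant columns yield NaN (callers drop them).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    n = X.shape[0]
    xc = X - X.mean(axis=0)
    yc = Y - Y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (sx * sy)
        z = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    z[np.abs(r) >= 1.0] = np.sign(r[np.abs(r) >= 1.0]) * Z_CAP
    z = np.clip(z, -Z_CAP, Z_CAP)
    z[sx == 0.0] = np.nan
    return z


def simulate_cohort(pool, config, rng=None):
    """Full generative pipeline for one cohort (genotypes through phenotype)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    X, kept = generate_genotypes(pool, config.n, config.maf_floor, seed=rng)
    W, E = generate_weights_and_expression(X, config, rng=rng)
    Y, beta = generate_phenotype(E, config, rng=rng)
    return CohortData(X=X, E=E, Y=Y, w_true=W, beta=beta, kept_variants=kept)
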