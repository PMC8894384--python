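"""End-to-end per-gene analysis: shrinkage correction, test battery,
combinations, and comparator tests."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .combine import PValueCorrelation, estimate_null_correlation, overall_pvalue
from .comparators import PredixcanInput, cauchy_combine, s_predixcan, s_twas
from .gene_tests import DEFAULT_RHO_GRID, WeightSet, all_tests
from .io import GeneInput
from .ld import corrected_ld, estimate_tuning

__all__ = ["GeneResult", "run_gene"]


@dataclass
class GeneResult:
    """All per-gene outputs: the battery, combined and comparator p-values."""

    gene_id: str
    M: int
    a_hat: float
    p_values: dict  # test label -> p (the 3(K+1) battery)
    p_overall: float
    p_OT: float
    p_s_twas: dict = field(default_factory=dict)  # study label -> p
    p_s_predixcan: dict = field(default_factory=dict)

    def __post_init__(self):
        for p in [self.p_overall, self.p_OT, *self.p_values.values(),
                  *self.p_s_twas.values(), *self.p_s_predixcan.values()]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("p-values must lie in [0, 1]")

    def to_row(self):
        row = {"gene_id": self.gene_id, "M": self.M, "a_hat": self.a_hat}
        row.update({lab: float(p) for lab, p in self.p_values.items()})
        row["p_overall"] = float(self.p_overall)
        row["p_OT"] = float(self.p_OT)
        for lab, p in self.p_s_twas.items():
            row[f"S-TWAS_{lab}"] = float(p)
        for lab, p in self.p_s_predixcan.items():
            row[f"S-PrediXcan_{lab}"] = float(p)
        return row


def run_gene(gene, omega=None, omega_B=1000, seed=None, grid=None, comparators_use_u=False):
    """Analyze one gene from its assembled inputs.

    Parameters
    ----------
    gene
        A GeneInput (Z-scores, LD matrix R, raw weights on a common order).
    omega
        Pre-estimated PValueCorrelation; estimated with ``omega_B``
        replications (requires ``seed``) when absent.
    comparators_use_u
        Evaluate S-TWAS / S-PrediXcan against the corrected U instead of R
        (the printed formulas use R; this flag substitutes U).
    """
    if not isinstance(gene, GeneInput):
        raise TypeError("gene must be a GeneInput")
    rho = DEFAULT_RHO_GRID if grid is None else np.asarray(grid, dtype=float)
    z = gene.z
    weights = WeightSet.from_raw(gene.raw_weights, labels=gene.weight_labels)
    a_hat = estimate_tuning(z, gene.R)
    corr = corrected_ld(gene.R, a_hat)
    labels, pvals = all_tests(z, corr.U, weights, grid=rho)
    if omega is None:
        omega = estimate_null_correlation(gene.R, weights, B=omega_B, seed=seed, grid=rho)
    if set(omega.labels) != set(labels):
        omega = _subset_omega(omega, labels)
    res_overall = overall_pvalue(dict(zip(labels, pvals)), omega)
    p_ot = cauchy_combine(pvals)
    r_cmp = corr.U if comparators_use_u else gene.R
    p_tw, p_px = {}, {}
    for k, lab in enumerate(weights.labels[1:], start=1):
        w_k = weights.W[k]
        p_tw[lab] = s_twas(z, r_cmp, w_k)[1]
        p_px[lab] = s_predixcan(z, PredixcanInput(), w_k, R=r_cmp)[1]
    return GeneResult(
        gene_id=gene.gene_id,
        M=z.size,
        a_hat=a_hat,
        p_values=dict(zip(labels, pvals)),
        p_overall=res_overall.p_overall,
        p_OT=p_ot,
        p_s_twas=p_tw,
        p_s_predixcan=p_px,
    )


def _subset_omega(omega, labels):
    idx = [omega.labels.index(lab) for lab in labels]
    sub = omega.Omega[np.ix_(idx, idx)]
    return PValueCorrelation(labels=tuple(labels), Omega=np.ascontiguousarray(sub))
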