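"""Tabular input/output and cross-source variant harmonization.

All inputs are plain tab-separated text: GWAS summary statistics
(ID/A1/A2 with Z or BETA+SE), a square LD matrix with an ID header (or a
dosage matrix to compute one from), and per-study eQTL weights. Variants
from the three sources are matched by ID and allele orientation, with the
LD file's variant order taken as canonical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "GeneInput",
    "FormatError",
    "EmptyGeneError",
    "read_summary_stats",
    "read_ld_matrix",
    "read_weights",
    "harmonize",
    "assemble_gene",
    "write_results",
    "read_results",
]

_BASES = {"A", "C", "G", "T"}
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class FormatError(ValueError):
    """An input file does not match the expected layout."""


class EmptyGeneError(ValueError):
    """No variant survives matching/filtering for a gene."""


@dataclass(frozen=True)
class VariantRecord:
    """One GWAS variant: ID, allele pair, and Z-score (possibly from beta/se)."""

    id: str
    effect_allele: str
    other_allele: str
    z: float

    def __post_init__(self):
        for a in (self.effect_allele, self.other_allele):
            if a not in _BASES:
                raise ValueError(f"allele must be one of A/C/G/T, got {a!r} for {self.id}")


@dataclass(frozen=True)
class GeneInput:
    """Everything needed to test one gene, on a common variant order."""

    gene_id: str
    variants: tuple
    R: np.ndarray
    raw_weights: np.ndarray
    weight_labels: tuple

    def __post_init__(self):
        m = len(self.variants)
        if m < 1:
            raise EmptyGeneError(f"gene {self.gene_id} has no variants")
        R = self.R
        if R.shape != (m, m):
            raise ValueError("LD matrix shape disagrees with variant count")
        if not np.allclose(R, R.T, atol=1e-8) or not np.allclose(np.diag(R), 1.0, atol=1e-8):
            raise FormatError("LD matrix must be symmetric with unit diagonal")
        if np.any(np.abs(R) > 1.0 + 1e-8):
            raise FormatError("LD entries must lie in [-1, 1]")
        if self.raw_weights.shape[0] != m:
            raise ValueError("weight rows disagree with variant count")

    @property
    def z(self):
        return np.array([v.z for v in self.variants])


def read_summary_stats(path, variant_subset=None):
    """Read GWAS summary statistics from a TSV with ID/A1/A2 and Z or BETA+SE.

    A1 is the effect allele. When both Z and BETA/SE are present, Z wins
    (logged). Duplicated IDs are dropped with a warning; ``variant_subset``
    restricts to the given IDs, preserving file order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.upper() for c in df.columns]
    needed = {"ID", "A1", "A2"}
    if not needed.issubset(df.columns):
        raise FormatError(f"summary statistics need columns {sorted(needed)}")
    has_z = "Z" in df.columns
    has_beta = "BETA" in df.columns and "SE" in df.columns
    if not has_z and not has_beta:
        raise FormatError("summary statistics need a Z column or BETA and SE columns")
    if has_z and has_beta:
        logger.info("both Z and BETA/SE present; using Z")
    dup = df["ID"].duplicated(keep=False)
    if dup.any():
        logger.warning("dropping %d duplicated variant IDs", int(dup.sum()))
        df = df[~dup]
    if variant_subset is not None:
        df = df[df["ID"].isin(set(variant_subset))]
    records = []
    for row in df.itertuples(index=False):
        rid = str(row.ID)
        if has_z and str(getattr(row, "Z", "")).strip() not in ("", "nan", "NA"):
            z = float(row.Z)
        else:
            beta = float(row.BETA)
            se = float(row.SE)
            if se <= 0:
                raise ValueError(f"non-positive standard error for variant {rid}")
            z = beta / se
        records.append(
            VariantRecord(id=rid, effect_allele=str(row.A1).upper(),
                          other_allele=str(row.A2).upper(), z=z)
        )
    return records


def read_ld_matrix(path, genotypes=False):
    """Read an LD matrix, or compute one from a dosage matrix.

    The matrix file is whitespace/tab-delimited with an ID header row. With
    ``genotypes=True`` the file holds an n x M dosage matrix (header row of
    variant IDs; values 0/1/2) and the Pearson correlation of its columns is
    returned; monomorphic columns are dropped with a warning.

    Returns (matrix, id list). A PLINK-style headerless square matrix is
    accepted too; its variants are named v1..vM in file order.
    """
    with open(path) as fh:
        first = fh.readline().split()

    def _numeric(tok):
        try:
            float(tok)
            return True
        except ValueError:
            return False

    if first and all(_numeric(t) for t in first):
        df = pd.read_csv(path, sep=r"\s+", engine="python", header=None)
        ids = [f"v{i + 1}" for i in range(df.shape[1])]
    else:
        df = pd.read_csv(path, sep=r"\s+", engine="python")
        ids = [str(c) for c in df.columns]
    mat = df.to_numpy(dtype=float)
    if genotypes:
        sd = mat.std(axis=0)
        keep = sd > 0
        if not keep.all():
            logger.warning("dropping %d monomorphic genotype columns", int((~keep).sum()))
            mat = mat[:, keep]
            ids = [i for i, k in zip(ids, keep) if k]
        if mat.shape[1] == 0:
            raise EmptyGeneError("all genotype columns are monomorphic")
        R = np.corrcoef(mat, rowvar=False)
        if R.ndim == 0:
            R = np.ones((1, 1))
        return np.ascontiguousarray(R), ids
    if mat.shape[0] != mat.shape[1]:
        raise FormatError(f"LD matrix is not square: {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-6):
        raise FormatError("LD matrix is asymmetric beyond 1e-6")
    if np.any(np.abs(mat) > 1.0 + 1e-8):
        raise FormatError("LD entries exceed 1 in absolute value")
    mat = (mat + mat.T) / 2.0
    return np.ascontiguousarray(mat), ids


def read_weights(path):
    """Read per-study eQTL weights: TSV with an ID column then one numeric
    column per study. Variants with any missing weight are dropped (logged),
    as are duplicated IDs. Returns (DataFrame indexed by ID, study labels).
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if not cols or cols[0].upper() != "ID":
        raise FormatError("weights file must start with an ID column")
    df = df.rename(columns={cols[0]: "ID"})
    df["ID"] = df["ID"].astype(str)
    dup = df["ID"].duplicated(keep=False)
    if dup.any():
        logger.warning("dropping %d duplicated weight IDs", int(dup.sum()))
        df = df[~dup]
    labels = [c for c in df.columns if c != "ID"]
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.warning("dropping %d variants with at least one missing weight", n0 - len(df))
    return df.set_index("ID"), labels


def harmonize(gwas, reference):
    """Align GWAS records to a reference's variant order and allele coding.

    Variants are matched by ID. When the effect/other alleles are swapped
    relative to the reference, the Z sign is flipped. Strand-ambiguous pairs
    (A/T, C/G) and unmatched or allele-mismatched variants are dropped and
    counted. Returns (aligned Z vector over the reference's kept order,
    kept reference indices, drop-count dict).
    """
    by_id = {rec.id: rec for rec in gwas}
    z_out, kept = [], []
    drops = {"unmatched": 0, "ambiguous": 0, "allele_mismatch": 0}
    for i, ref in enumerate(reference):
        rec = by_id.get(ref.id)
        if rec is None:
            drops["unmatched"] += 1
            continue
        pair = (rec.effect_allele, rec.other_allele)
        if pair in _AMBIGUOUS:
            drops["ambiguous"] += 1
            continue
        if pair == (ref.effect_allele, ref.other_allele):
            z_out.append(rec.z)
        elif pair == (ref.other_allele, ref.effect_allele):
            z_out.append(-rec.z)
        else:
            drops["allele_mismatch"] += 1
            continue
        kept.append(i)
    if not kept:
        raise EmptyGeneError("no variant survives harmonization")
    if any(drops.values()):
        logger.info("harmonization drops: %s", drops)
    return np.array(z_out), kept, drops


def assemble_gene(gene_id, sumstats, ld, ld_ids, weights_df, weight_labels,
                  reference_alleles=None):
    """Build a GeneInput on the LD file's canonical variant order.

    GWAS records and weights are reindexed to the LD ID order; variants
    missing from either source are dropped (with the LD matrix subset
    accordingly). ``reference_alleles`` optionally maps ID ->
    (effect, other) for sign harmonization; without it the GWAS coding is
    taken as the reference.
    """
    by_id = {rec.id: rec for rec in sumstats}
    keep_idx, variants, weight_rows = [], [], []
    for i, vid in enumerate(ld_ids):
        rec = by_id.get(vid)
        if rec is None or vid not in weights_df.index:
            continue
        if reference_alleles is not None:
            ea, oa = reference_alleles[vid]
            pair = (rec.effect_allele, rec.other_allele)
            if pair in _AMBIGUOUS:
                continue
            if pair == (oa, ea):
                rec = VariantRecord(rec.id, ea, oa, -rec.z)
            elif pair != (ea, oa):
                continue
        keep_idx.append(i)
        variants.append(rec)
        weight_rows.append(weights_df.loc[vid, weight_labels].to_numpy(dtype=float))
    if not keep_idx:
        raise EmptyGeneError(f"gene {gene_id}: no variant shared by all sources")
    keep_idx = np.array(keep_idx)
    return GeneInput(
        gene_id=gene_id,
        variants=tuple(variants),
        R=np.ascontiguousarray(ld[np.ix_(keep_idx, keep_idx)]),
        raw_weights=np.vstack(weight_rows),
        weight_labels=tuple(weight_labels),
    )


def write_results(results, path):
    """Write per-gene results as a TSV, one row per gene.

    Column order is fixed and p-values use scientific notation with six
    significant digits, so identical inputs produce byte-identical files.
    """
    results = list(results)
    if results:
        all_cols = list(results[0].to_row().keys())
    else:
        all_cols = ["gene_id", "M", "a_hat", "p_overall", "p_OT"]
    with open(path, "w") as fh:
        fh.write("\t".join(all_cols) + "\n")
        for res in results:
            row = res.to_row()
            cells = []
            for c in all_cols:
                v = row[c]
                if isinstance(v, float):
                    cells.append(f"{v:.6e}")
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_results(path):
    """Re-parse a results file written by write_results."""
    return pd.read_csv(path, sep="\t")
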