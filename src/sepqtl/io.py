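"""Cohort I/O: genotype loading, LD, and covariate assembly.

Genotypes are stored as minor-allele dosages (0/1/2) per individual; the
minor allele is defined within the loaded cohort, so sites whose ALT
frequency exceeds 0.5 are flipped on input.  Expression is a genes x samples
matrix of normalised log expression with per-gene TSS annotation.  The
sample frame carries the fixed covariates shared by all association stages:
seven genotype principal components, twenty hidden expression factors,
inverse-normal-transformed cell proportions, SRS1 status and diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "read_genotypes",
    "read_expression",
    "load_cohort",
    "ld_r2",
    "rank_int",
    "build_covariates",
    "covariate_matrix",
    "STANDARD_COVARIATES",
]

CELL_TYPES = ["neutrophils", "lymphocytes", "monocytes"]


class FormatError(ValueError):
    pass


class EmptyResultError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs minor-allele dosage with SNP metadata.

    ``snp_meta`` is indexed by SNP id with columns chrom, pos, ref, alt, maf;
    ``ref``/``alt`` here are the VCF alleles, while ``dosage`` always counts
    the minor allele in this cohort (``flipped`` marks sites where that is
    the VCF REF allele).
    """

    dosage: np.ndarray
    snp_meta: pd.DataFrame
    individual_ids: list

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage)
        if self.dosage.shape != (len(self.individual_ids), len(self.snp_meta)):
            raise FormatError("dosage shape does not match metadata")

    @property
    def n_individuals(self):
        return self.dosage.shape[0]

    @property
    def n_snps(self):
        return self.dosage.shape[1]

    @property
    def snp_ids(self):
        return list(self.snp_meta.index)

    def column(self, snp_id) -> np.ndarray:
        return self.dosage[:, self.snp_meta.index.get_loc(snp_id)]

    def individual_index(self):
        return {iid: i for i, iid in enumerate(self.individual_ids)}


@dataclass
class ExpressionMatrix:
    """Genes x samples normalised log expression with TSS annotation."""

    values: pd.DataFrame  # genes x samples
    gene_meta: pd.DataFrame  # index gene id; columns chrom, tss

    def __post_init__(self):
        if not self.values.index.is_unique:
            raise FormatError("gene ids must be unique")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise FormatError("expression contains non-finite values")

    @property
    def genes(self):
        return list(self.values.index)

    @property
    def sample_ids(self):
        return list(self.values.columns)


def read_genotypes(vcf_path, maf_min: float = 0.01) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF as minor-allele dosages.

    Multi-allelic records and sites with cohort MAF below ``maf_min`` are
    dropped; sites where the ALT allele is the major allele are flipped so
    that dosage counts the minor allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    individual_ids = list(vcf.samples)
    rows = []
    meta = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic only
        gts = var.gt_types  # 0=hom ref, 1=het, 2=hom alt with gts012
        if np.any(gts == 3):
            raise FormatError(f"missing genotype at {var.ID or var.POS}")
        dos = gts.astype(np.int8)
        alt_freq = dos.sum() / (2.0 * len(dos))
        flipped = alt_freq > 0.5
        if flipped:
            dos = 2 - dos
        maf = min(alt_freq, 1.0 - alt_freq)
        if maf < maf_min:
            continue
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        rows.append(dos)
        meta.append((snp_id, var.CHROM, var.POS, var.REF, var.ALT[0], maf, flipped))
    if not rows:
        raise EmptyResultError("no records pass the biallelic/MAF filters")
    snp_meta = pd.DataFrame(
        meta, columns=["snp", "chrom", "pos", "ref", "alt", "maf", "flipped"]
    ).set_index("snp")
    return GenotypeMatrix(np.array(rows, dtype=np.int8).T, snp_meta, individual_ids)


def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.size < 3:
        raise ValueError("dosage vectors must share length >= 3")
    if np.std(g1) == 0 or np.std(g2) == 0:
        raise ValueError("LD undefined for a monomorphic dosage vector")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


def rank_int(x, c: float = 3.0 / 8.0):
    """Rank-based inverse normal transform with the Blom offset.

    Missing values are imputed with the non-missing median BEFORE the
    transform; ties receive average ranks.
    """
    x = np.asarray(x, dtype=float).copy()
    miss = ~np.isfinite(x)
    if miss.all():
        raise ValueError("all values missing")
    if miss.any():
        x[miss] = np.nanmedian(x[~miss])
    ranks = stats.rankdata(x, method="average")
    n = len(x)
    return stats.norm.ppf((ranks - c) / (n - 2 * c + 1))


def read_expression(expr_path, gene_meta_path) -> ExpressionMatrix:
    """TSV expression (genes x samples) plus BED-like gene annotation."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(gene_meta_path, sep="\t", index_col=0)
    meta.index.name = "gene"
    meta["chrom"] = meta["chrom"].astype(str)
    return ExpressionMatrix(values, meta[["chrom", "tss"]])


def load_cohort(cohort_dir, maf_min: float = 0.0):
    """Read a cohort directory (VCF + TSVs) back into memory.

    Returns ``(genotypes, expression, samples)``.
    """
    from pathlib import Path

    d = Path(cohort_dir)
    geno = read_genotypes(d / "genotypes.vcf", maf_min=maf_min)
    expr = read_expression(d / "expression.tsv", d / "genes.tsv")
    samples = pd.read_csv(d / "samples.tsv", sep="\t")
    return geno, expr, samples


# fixed covariates entering every association model
STANDARD_COVARIATES = (
    [f"geno_pc{i + 1}" for i in range(7)]
    + [f"factor{i + 1}" for i in range(20)]
    + [f"int_{c}" for c in CELL_TYPES]
    + ["srs1", "diagnosis_fp"]
)


def build_covariates(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    n_hidden: int = 20,
    n_compute: int = 30,
    holdout=None,
) -> pd.DataFrame:
    """Augment the sample frame with INT cell proportions and hidden factors.

    Cell proportions are median-imputed then inverse-normal transformed.
    Hidden factors are the top principal components of the expression matrix
    after regressing the held-out known covariates out of each gene; they
    stand in for a Bayesian factor model and are standardised to unit
    variance.  ``n_compute`` components are computed and the first
    ``n_hidden`` retained.
    """
    samples = samples.copy()
    n_samples = len(samples)
    if n_hidden >= n_samples:
        raise ValueError("n_hidden must be smaller than the sample count")
    for cell in CELL_TYPES:
        if cell in samples:
            samples[f"int_{cell}"] = rank_int(samples[cell].to_numpy())
    if holdout is None:
        holdout = [
            c
            for c in [f"int_{t}" for t in CELL_TYPES]
            + ["srs1", "diagnosis_fp"]
            + [f"geno_pc{i + 1}" for i in range(7)]
            if c in samples
        ]
    missing = [c for c in holdout if c not in samples]
    if missing:
        raise ValueError(f"holdout covariates absent from sample frame: {missing}")

    Y = expr.values.loc[:, samples["sample_id"]].to_numpy(dtype=float)
    # residualise each gene on the held-out covariates (with intercept)
    C = np.column_stack(
        [np.ones(n_samples)] + [samples[c].to_numpy(dtype=float) for c in holdout]
    )
    coef, *_ = np.linalg.lstsq(C, Y.T, rcond=None)
    R = Y.T - C @ coef  # samples x genes residuals
    R = R - R.mean(axis=0)
    k = min(n_compute, n_samples - 1, R.shape[1])
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    scores = U[:, :k] * s[:k]
    scores = scores[:, : min(n_hidden, k)]
    scores = scores / scores.std(axis=0, ddof=0)
    for i in range(scores.shape[1]):
        samples[f"factor{i + 1}"] = scores[:, i]
    return samples


def covariate_matrix(samples: pd.DataFrame, exclude=(), extra=None):
    """Standard fixed-effect design (with intercept) from an augmented frame.

    Returns ``(X, names)``.  ``exclude`` removes named covariates (e.g. an
    environment already entering as an interaction term); ``extra`` appends
    additional columns as ``{name: vector}``.
    """
    cols = [c for c in STANDARD_COVARIATES if c in samples and c not in exclude]
    names = ["intercept"] + cols
    mats = [np.ones(len(samples))] + [samples[c].to_numpy(dtype=float) for c in cols]
    if extra:
        for name, vec in extra.items():
            names.append(name)
            mats.append(np.asarray(vec, dtype=float))
    return np.column_stack(mats), names
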