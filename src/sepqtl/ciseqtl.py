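"""cis-eQTL scan with hierarchical multiple testing and conditional signals.

For every gene, SNPs within 1 Mb of the TSS are tested for an additive
dosage effect on expression with the random-intercept LMM (p from a 1-df
LRT).  Multiple testing is hierarchical: the per-gene peak p-value is
Bonferroni-adjusted by an effective test count estimated from the
eigenvalues of the (shrunk) local dosage correlation matrix, the adjusted
peaks are BH-corrected across genes, and the largest passing adjusted peak
q* defines a per-gene nominal threshold q*/M_eff for additional SNPs.
Independent signals per eGene come from forward stepwise inclusion of
conditioning SNPs followed by backward re-selection and a final joint fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import LedoitWolf
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GenotypeMatrix, covariate_matrix
from .lmm import ProfiledScan, RandomInterceptLM, lrt_nested

__all__ = [
    "GeneScanResult",
    "EqtlSignal",
    "map_cis_gene",
    "effective_tests",
    "hierarchical_fdr",
    "conditional_signals",
    "scan_all_genes",
]


@dataclass
class GeneScanResult:
    gene: str
    table: pd.DataFrame  # snp, pos, beta, se, p
    m_eff: int
    p_local_peak: float
    q_global: float = np.nan
    p_threshold_gene: float = np.nan

    @property
    def peak_snp(self) -> str:
        return self.table.loc[self.table["p"].idxmin(), "snp"]


@dataclass
class EqtlSignal:
    gene: str
    lead_snp: str
    rank: int
    beta_joint: float
    se_joint: float
    p_joint: float
    discovery_p: float


def _gene_window_snps(gene, geno: GenotypeMatrix, expr: ExpressionMatrix, window_bp):
    meta = expr.gene_meta.loc[gene]
    snps = geno.snp_meta
    mask = (snps["chrom"] == meta["chrom"]) & (
        (snps["pos"] - meta["tss"]).abs() <= window_bp
    )
    return snps.index[mask].tolist()


def _scan(gene, snp_ids, geno, expr, samples, extra_covariate_snps):
    """LRT scan of candidate SNPs for one gene; returns a stats table."""
    ind_of = samples["individual_id"].map(geno.individual_index()).to_numpy()
    y = expr.values.loc[gene, samples["sample_id"]].to_numpy(dtype=float)
    groups = samples["individual_id"].to_numpy()
    extra = {}
    for s in extra_covariate_snps or []:
        extra[f"cond_{s}"] = geno.column(s).astype(float)[ind_of]
    X0, names0 = covariate_matrix(samples, extra=extra)
    scanner = ProfiledScan(y, X0, groups)
    G = np.column_stack([geno.column(s).astype(float)[ind_of] for s in snp_ids])
    recs = scanner.scan(G, names=snp_ids)
    tab = pd.DataFrame(
        [(r["name"], r["beta"], r["se"], r["p"]) for r in recs],
        columns=["snp", "beta", "se", "p"],
    )
    tab["pos"] = geno.snp_meta.loc[tab["snp"], "pos"].to_numpy()
    # deterministic tie-break: equal p -> smaller genomic position first
    tab = tab.sort_values(["p", "pos"], kind="mergesort").reset_index(drop=True)
    return tab


def map_cis_gene(
    gene: str,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    window_bp: int = 1_000_000,
    extra_covariate_snps=None,
    var_explained: float = 0.99,
    partition_size: int = 200,
) -> GeneScanResult | None:
    """Scan all SNPs within ``window_bp`` of the gene's TSS.

    Returns ``None`` when no SNP falls in the window (gene skipped
    downstream).
    """
    snp_ids = _gene_window_snps(gene, geno, expr, window_bp)
    if not snp_ids:
        return None
    tab = _scan(gene, snp_ids, geno, expr, samples, extra_covariate_snps)
    cols = [geno.snp_meta.index.get_loc(s) for s in snp_ids]
    m_eff = effective_tests(
        geno.dosage[:, cols].astype(float), var_explained, partition_size
    )
    p_peak = min(1.0, float(tab["p"].min()) * m_eff)
    return GeneScanResult(gene, tab, m_eff, p_peak)


def effective_tests(
    window_dosages: np.ndarray,
    var_explained: float = 0.99,
    partition_size: int = 200,
) -> int:
    """Effective number of independent tests among correlated SNPs.

    Consecutive partitions of at most ``partition_size`` SNPs; per
    partition, the dosage correlation matrix is shrunk (Ledoit-Wolf) and
    the effective count is the smallest number of leading eigenvalues
    whose cumulative fraction reaches ``var_explained``.  Sums over
    partitions, capped at the SNP count.
    """
    G = np.asarray(window_dosages, dtype=float)
    n_snps = G.shape[1]
    if n_snps == 0:
        raise ValueError("no SNPs supplied")
    total = 0
    for start in range(0, n_snps, partition_size):
        block = G[:, start : start + partition_size]
        sd = block.std(axis=0)
        block = (block - block.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        k = block.shape[1]
        if k == 1:
            total += 1
            continue
        lw = LedoitWolf(assume_centered=True).fit(block)
        C = lw.covariance_
        d = np.sqrt(np.clip(np.diag(C), 1e-12, None))
        C = C / np.outer(d, d)
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        evals = np.clip(evals, 0.0, None)
        frac = np.cumsum(evals) / evals.sum()
        total += int(np.searchsorted(frac, var_explained) + 1)
    return min(total, n_snps)


def hierarchical_fdr(scans: list, fdr: float = 0.05):
    """BH across gene-level Bonferroni peaks; derive per-gene thresholds.

    Returns ``(egene_ids, scans)`` with ``q_global`` and (for eGenes)
    ``p_threshold_gene`` filled in: the largest adjusted peak p among
    passing genes, divided by each gene's effective test count.
    """
    scans = [s for s in scans if s is not None]
    if not scans:
        return [], scans
    pvals = np.array([s.p_local_peak for s in scans])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    egenes = []
    for s, q in zip(scans, qvals):
        s.q_global = float(q)
        if q < fdr:
            egenes.append(s.gene)
    if egenes:
        q_star = max(s.p_local_peak for s in scans if s.q_global < fdr)
        for s in scans:
            if s.q_global < fdr:
                s.p_threshold_gene = q_star / s.m_eff
    return egenes, scans


def conditional_signals(
    gene: str,
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    p_threshold_gene: float,
    window_bp: int = 1_000_000,
    max_iter: int = 20,
) -> list:
    """Forward-stepwise / backward-selection independent signal discovery.

    Forward: rescan conditioning on all previously found leads; accept the
    new peak while its nominal p stays below the (fixed) per-gene
    threshold.  Backward: re-test each signal conditioning on all other
    leads, keeping the most significant passing SNP as that signal's lead
    or dropping the signal.  Final: a single joint model with all retained
    leads provides joint effects; per-lead p from a 1-df LRT dropping that
    lead.
    """
    snp_ids = _gene_window_snps(gene, geno, expr, window_bp)
    if not snp_ids:
        return []

    def peak(leads):
        tab = _scan(gene, snp_ids, geno, expr, samples, leads)
        top = tab.iloc[0]
        return str(top["snp"]), float(top["p"])

    # forward pass
    leads: list = []
    discovery_p: dict = {}
    for _ in range(max_iter):
        snp, p = peak(leads)
        if p >= p_threshold_gene or snp in leads:
            break
        leads.append(snp)
        discovery_p[snp] = p
    if not leads:
        return []

    # backward pass
    retained = []
    for lead in leads:
        others = [s for s in leads if s != lead]
        snp, p = peak(others)
        if p < p_threshold_gene:
            retained.append((snp, discovery_p.get(lead, p), p))
    # deduplicate while preserving discovery order (perfect-LD collapses)
    seen = set()
    final = []
    for snp, dp, bp in retained:
        if snp not in seen:
            seen.add(snp)
            final.append((snp, dp, bp))
    if not final:
        return []

    # joint model
    ind_of = samples["individual_id"].map(geno.individual_index()).to_numpy()
    y = expr.values.loc[gene, samples["sample_id"]].to_numpy(dtype=float)
    groups = samples["individual_id"].to_numpy()
    X0, names0 = covariate_matrix(samples)
    lead_cols = {s: geno.column(s).astype(float)[ind_of] for s, _, _ in final}
    Xj = np.column_stack([X0] + [lead_cols[s] for s, _, _ in final])
    names = names0 + [s for s, _, _ in final]
    joint = RandomInterceptLM(y, Xj, groups, xnames=names).fit()
    signals = []
    for r, (snp, dp, _) in enumerate(final, start=1):
        j = names.index(snp)
        if np.isnan(joint.params[j]):
            continue  # collinear lead dropped with warning upstream
        drop_cols = [c for c in range(Xj.shape[1]) if c != j]
        reduced = RandomInterceptLM(y, Xj[:, drop_cols], groups).fit()
        _, p_joint = lrt_nested(joint, reduced, df=1)
        signals.append(
            EqtlSignal(
                gene=gene,
                lead_snp=snp,
                rank=r,
                beta_joint=float(joint.params[j]),
                se_joint=float(joint.bse[j]),
                p_joint=p_joint,
                discovery_p=dp,
            )
        )
    for r, sig in enumerate(signals, start=1):
        sig.rank = r
    return signals


def scan_all_genes(
    geno, expr, samples, window_bp: int = 1_000_000, fdr: float = 0.05,
    conditional: bool = True, max_iter: int = 20,
):
    """Full scan: per-gene mapping, hierarchical FDR, conditional signals.

    Returns ``(scans, egenes, signals)``.
    """
    scans = []
    for gene in expr.genes:
        scans.append(map_cis_gene(gene, geno, expr, samples, window_bp))
    egenes, scans = hierarchical_fdr(scans, fdr=fdr)
    signals = []
    if conditional:
        thr = {s.gene: s.p_threshold_gene for s in scans if s is not None}
        for gene in egenes:
            signals.extend(
                conditional_signals(
                    gene, geno, expr, samples, thr[gene], window_bp, max_iter
                )
            )
    return scans, egenes, signals


def signals_table(signals) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": s.gene, "snp": s.lead_snp, "rank": s.rank,
                "beta": s.beta_joint, "se": s.se_joint, "p": s.p_joint,
                "discovery_p": s.discovery_p,
            }
            for s in signals
        ]
    )
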