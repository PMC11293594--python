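"""Module QTLs: eigengene association, replication, sensitivity, mediation
and approximate-Bayes-factor colocalization.

Lead cis-eSNPs with more than three minor-allele homozygotes are tested
against every module eigengene with the standard covariate LMM; the
genome-wide significance threshold is the Bonferroni bound
alpha / (n_SNPs x n_modules) and loci are 1 Mb windows around significant
SNPs merged per module.  Replication recomputes eigengenes on a second
expression platform (>= 5 measured genes) and retests the lead SNP in
independent samples with sign-concordance bookkeeping.  The sensitivity
analysis removes member genes that are cis-eGenes of any modQTL SNP and
asks whether the association survives — separating trans networks from
cis-only artifacts.  Mediation uses the quasi-Bayesian product-of-
coefficients machinery (draws from the fitted coefficients' asymptotic
normal; ACME = a*b, ADE = c'); colocalization uses Wakefield approximate
Bayes factors with the usual five hypotheses and default priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import covariate_matrix
from .lmm import ProfiledScan
from .coexpr import module_eigengenes

__all__ = [
    "bonferroni_threshold",
    "map_modqtl",
    "merge_loci",
    "replicate_modqtl",
    "sensitivity_analysis",
    "mediation_analysis",
    "coloc_abf",
    "MediationResult",
    "ColocResult",
]


def bonferroni_threshold(n_snps: int, n_modules: int,
                         alpha: float = 0.05) -> float:
    """Genome-wide modQTL threshold alpha / (n_snps * n_modules)."""
    if n_snps < 1 or n_modules < 1:
        raise ValueError("counts must be positive")
    return alpha / (n_snps * n_modules)


def eligible_snps(geno, candidate_snps, min_hom: int = 3) -> list:
    """SNPs with more than ``min_hom`` minor-allele homozygotes."""
    out = []
    for snp in candidate_snps:
        if int(np.sum(geno.column(snp) == 2)) > min_hom:
            out.append(snp)
    return out


def map_modqtl(
    eigengenes: pd.DataFrame,
    candidate_snps,
    samples: pd.DataFrame,
    geno,
    alpha: float = 0.05,
    min_hom: int = 3,
):
    """LMM scan of candidate SNPs against every module eigengene.

    ``eigengenes`` is modules x samples.  Returns ``(table, threshold,
    loci)``; the table has one row per (SNP, module) with beta, se, p and
    the Bonferroni pass flag.
    """
    snps = eligible_snps(geno, candidate_snps, min_hom)
    if not snps:
        raise ValueError("no candidate SNP passes the homozygote filter")
    threshold = bonferroni_threshold(len(snps), len(eigengenes.index), alpha)
    ind_of = samples["individual_id"].map(geno.individual_index()).to_numpy()
    groups = samples["individual_id"].to_numpy()
    X0, _ = covariate_matrix(samples)
    G = np.column_stack([geno.column(s).astype(float)[ind_of] for s in snps])
    recs = []
    for mod in eigengenes.index:
        y = eigengenes.loc[mod, samples["sample_id"]].to_numpy(dtype=float)
        scanner = ProfiledScan(y, X0, groups)
        for r in scanner.scan(G, names=snps):
            recs.append((mod, r["name"], r["beta"], r["se"], r["p"]))
    tab = pd.DataFrame(recs, columns=["module", "snp", "beta", "se", "p"])
    tab["passes_bonferroni"] = tab["p"] < threshold
    tab["pos"] = geno.snp_meta.loc[tab["snp"], "pos"].to_numpy()
    tab["chrom"] = geno.snp_meta.loc[tab["snp"], "chrom"].to_numpy()
    loci = merge_loci(tab[tab["passes_bonferroni"]])
    tab = tab.merge(loci[["module", "snp", "locus_id"]],
                    on=["module", "snp"], how="left")
    return tab, threshold, loci


def merge_loci(sig_tab: pd.DataFrame, window_bp: int = 500_000) -> pd.DataFrame:
    """1 Mb windows (+-window_bp) around significant SNPs, merged per module."""
    rows = []
    for module, sub in sig_tab.groupby("module"):
        for chrom, subc in sub.groupby("chrom"):
            subc = subc.sort_values("pos")
            locus_start = locus_end = None
            members = []
            count = 0
            for _, r in subc.iterrows():
                lo, hi = r["pos"] - window_bp, r["pos"] + window_bp
                if locus_end is None or lo > locus_end:
                    if members:
                        count += 1
                        rows.extend(
                            (module, s, f"{module}:{chrom}:{count}")
                            for s in members
                        )
                    locus_start, locus_end, members = lo, hi, [r["snp"]]
                else:
                    locus_end = max(locus_end, hi)
                    members.append(r["snp"])
            if members:
                count += 1
                rows.extend(
                    (module, s, f"{module}:{chrom}:{count}") for s in members
                )
    return pd.DataFrame(rows, columns=["module", "snp", "locus_id"])


def replicate_modqtl(
    module_genes: dict,
    platform_b: pd.DataFrame,
    overlap_samples: pd.DataFrame,
    independent_samples: pd.DataFrame,
    leads: pd.DataFrame,
    geno_b,
    eigengenes_a: pd.DataFrame,
    min_genes: int = 5,
):
    """Replication of lead modQTLs on a second expression platform.

    ``platform_b`` is genes x samples for the replication platform;
    ``overlap_samples`` / ``independent_samples`` are sample frames for the
    cross-platform correlation and the independent retest; ``leads`` has
    columns (module, snp, beta) from discovery.  Returns a tidy table with
    cross-platform Spearman rho, replication beta and p, and the
    direction-concordance flag sign(beta_A) * sign(rho) * sign(beta_B) = 1.
    """
    recs = []
    for _, lead in leads.iterrows():
        mod, snp, beta_a = lead["module"], lead["snp"], lead["beta"]
        genes = [g for g in module_genes[mod] if g in platform_b.index]
        if len(genes) < min_genes:
            recs.append((mod, snp, False, np.nan, np.nan, np.nan, np.nan, None))
            continue
        labels = pd.Series(1, index=pd.Index(genes))
        # eigengene on platform B over all its samples
        eb, _ = module_eigengenes(platform_b.loc[genes], labels)
        eb = eb.loc[1]
        rho = np.nan
        if len(overlap_samples):
            ids = overlap_samples["sample_id"]
            ea = eigengenes_a.loc[mod, ids].to_numpy(dtype=float)
            rho = float(stats.spearmanr(ea, eb.loc[ids].to_numpy()).statistic)
        beta_b = p_b = np.nan
        concordant = None
        if len(independent_samples):
            ind_of = independent_samples["individual_id"].map(
                geno_b.individual_index()
            ).to_numpy()
            y = eb.loc[independent_samples["sample_id"]].to_numpy(dtype=float)
            X0, _ = covariate_matrix(independent_samples)
            scanner = ProfiledScan(
                y, X0, independent_samples["individual_id"].to_numpy()
            )
            g = geno_b.column(snp).astype(float)[ind_of]
            r = scanner.scan(g)[0]
            beta_b, p_b = r["beta"], r["p"]
            if np.isfinite(rho) and np.isfinite(beta_b):
                concordant = bool(
                    np.sign(beta_a) * np.sign(rho) * np.sign(beta_b) > 0
                )
        recs.append((mod, snp, True, rho, beta_b, p_b,
                     float(p_b < 0.05) if np.isfinite(p_b) else np.nan,
                     concordant))
    return pd.DataFrame(
        recs,
        columns=["module", "snp", "replicable", "rho", "beta_b", "p_b",
                 "replicated", "direction_concordant"],
    )


def sensitivity_analysis(
    module_id,
    labels: pd.Series,
    data: pd.DataFrame,
    lead_snp: str,
    cis_egene_map: dict,
    samples: pd.DataFrame,
    geno,
    threshold: float,
    sample_level_data: pd.DataFrame | None = None,
):
    """Re-test a modQTL after excluding cis-eGene members.

    ``cis_egene_map`` maps each modQTL SNP to the set of genes for which it
    is a lead cis-eSNP; member genes that are cis-eGenes of any such SNP
    are removed, the eigengene recomputed on ``sample_level_data`` (or
    ``data``), and the lead SNP retested.  Returns ``(p, robust flag,
    n_removed, eigengene)``; robust means the association stays below the
    genome-wide threshold.
    """
    members = labels.index[labels == module_id].tolist()
    excluded = set()
    for snp, genes in cis_egene_map.items():
        excluded |= set(genes)
    keep = [g for g in members if g not in excluded]
    n_removed = len(members) - len(keep)
    if len(keep) < 2:
        return np.nan, None, n_removed, None  # indeterminate, flagged
    mat = sample_level_data if sample_level_data is not None else data
    eg, _ = module_eigengenes(mat.loc[keep], pd.Series(1, index=pd.Index(keep)))
    e = eg.loc[1]
    ind_of = samples["individual_id"].map(geno.individual_index()).to_numpy()
    y = e.loc[samples["sample_id"]].to_numpy(dtype=float)
    X0, _ = covariate_matrix(samples)
    scanner = ProfiledScan(y, X0, samples["individual_id"].to_numpy())
    g = geno.column(lead_snp).astype(float)[ind_of]
    r = scanner.scan(g)[0]
    return float(r["p"]), bool(r["p"] < threshold), n_removed, e


@dataclass
class MediationResult:
    snp: str
    mediator: str
    acme: float
    ade: float
    total: float
    prop_mediated: float
    acme_ci: tuple
    ade_ci: tuple
    total_ci: tuple
    acme_p: float
    ade_p: float
    n_sims: int

    def summary(self) -> str:
        return (
            f"Mediation {self.snp} -> {self.mediator} -> outcome\n"
            f"  ACME  {self.acme:+.4f}  CI {self.acme_ci}  p={self.acme_p:.4g}\n"
            f"  ADE   {self.ade:+.4f}  CI {self.ade_ci}  p={self.ade_p:.4g}\n"
            f"  Total {self.total:+.4f}  CI {self.total_ci}\n"
            f"  Proportion mediated {self.prop_mediated:.3f} "
            f"({self.n_sims} simulations)"
        )


def _ols(y, X):
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.pinv(X.T @ X)
    return beta, cov


def mediation_analysis(
    snp_dosage,
    mediator_expr,
    outcome,
    covariates: np.ndarray | None = None,
    n_sims: int = 1000,
    seed: int = 0,
    snp_name: str = "snp",
    mediator_name: str = "mediator",
) -> MediationResult:
    """Quasi-Bayesian mediation of SNP -> mediator -> outcome.

    Fits linear models M ~ G + C and Y ~ G + M + C, draws coefficient
    vectors from their asymptotic normals, and per draw computes
    ACME = a*b and ADE = c'.  Point estimates are simulation means with
    percentile confidence intervals and two-sided empirical p-values;
    effects are per one additional copy of the minor allele.
    """
    g = np.asarray(snp_dosage, dtype=float)
    m = np.asarray(mediator_expr, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(g)
    C = (np.asarray(covariates, dtype=float)
         if covariates is not None else np.empty((n, 0)))
    r_gm = np.corrcoef(g, m)[0, 1] ** 2
    if r_gm > 0.99:
        raise ValueError("mediator and treatment nearly collinear; unidentified")
    Xm = np.column_stack([np.ones(n), g, C])
    Xy = np.column_stack([np.ones(n), g, m, C])
    bm, cov_m = _ols(m, Xm)
    by, cov_y = _ols(y, Xy)
    rng = np.random.default_rng(seed)
    draws_m = rng.multivariate_normal(bm, cov_m, size=n_sims)
    draws_y = rng.multivariate_normal(by, cov_y, size=n_sims)
    a = draws_m[:, 1]  # G -> M
    b = draws_y[:, 2]  # M -> Y
    cprime = draws_y[:, 1]  # direct
    acme = a * b
    total = acme + cprime

    def ci(x):
        return (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))

    def pval(x):
        pos = float(np.mean(x > 0))
        return max(2 * min(pos, 1 - pos), 1.0 / n_sims)

    tot_mean = float(total.mean())
    prop = float(np.mean(acme) / tot_mean) if tot_mean != 0 else np.nan
    return MediationResult(
        snp=snp_name,
        mediator=mediator_name,
        acme=float(acme.mean()),
        ade=float(cprime.mean()),
        total=tot_mean,
        prop_mediated=prop,
        acme_ci=ci(acme),
        ade_ci=ci(cprime),
        total_ci=ci(total),
        acme_p=pval(acme),
        ade_p=pval(cprime),
        n_sims=n_sims,
    )


@dataclass
class ColocResult:
    pp: np.ndarray  # PP0..PP4
    labf1: np.ndarray
    labf2: np.ndarray
    priors: tuple
    W: float
    n_snps: int

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    def summary(self) -> str:
        names = ["PP0", "PP1", "PP2", "PP3", "PP4"]
        body = "  ".join(f"{n}={v:.4f}" for n, v in zip(names, self.pp))
        return f"Colocalization over {self.n_snps} SNPs: {body}"


def _logsumexp(x):
    x = np.asarray(x, dtype=float)
    m = np.max(x)
    return m + np.log(np.sum(np.exp(x - m)))


def wakefield_labf(beta, se, W: float) -> np.ndarray:
    """Per-SNP log approximate Bayes factor against the null.

    log ABF = 0.5 log(V / (V + W)) + z^2 W / (2 (V + W)) with V = se^2.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    V = se**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(V / (V + W)) + z2 * W / (2.0 * (V + W))


def coloc_abf(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    W: float = 0.15**2,
) -> ColocResult:
    """Single-causal-variant colocalization of two association traits.

    ``stats1``/``stats2`` carry per-SNP ``beta`` and ``se`` on a shared,
    allele-aligned SNP index.  Returns posterior probabilities for the
    five hypotheses (no association; trait-1 only; trait-2 only; two
    distinct variants; one shared variant).
    """
    common = stats1.index.intersection(stats2.index)
    if len(common) < 2:
        raise ValueError("need at least two shared SNPs")
    l1 = wakefield_labf(stats1.loc[common, "beta"], stats1.loc[common, "se"], W)
    l2 = wakefield_labf(stats2.loc[common, "beta"], stats2.loc[common, "se"], W)
    s1 = _logsumexp(l1)
    s2 = _logsumexp(l2)
    s12 = _logsumexp(l1 + l2)
    # sum over pairs i != j of exp(l1_i + l2_j)
    both = s1 + s2
    cross = both + np.log1p(-np.exp(s12 - both)) if s12 < both else -np.inf
    logpost = np.array([
        0.0,
        np.log(p1) + s1,
        np.log(p2) + s2,
        np.log(p1) + np.log(p2) + cross,
        np.log(p12) + s12,
    ])
    pp = np.exp(logpost - _logsumexp(logpost))
    pp /= pp.sum()
    return ColocResult(pp, np.asarray(l1), np.asarray(l2), (p1, p2, p12), W,
                       len(common))
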