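"""Synthetic sepsis-cohort generator with recorded ground truth.

Emulates the data a repeated-measures blood eQTL study consumes: HWE
genotypes with block-autoregressive LD, 1-3 serial expression samples per
individual, planted additive cis effects, genotype-by-context interactions,
latent co-expression modules (optionally driven in trans by a SNP through a
cis mediator gene), SRS/diagnosis labels, Dirichlet cell proportions and
exponential survival.  Every planted parameter is recorded in a
:class:`TruthTable` so downstream stages have a parameter-recovery surface.

The observation model for sample s of individual i, gene g is

    y = mu_g + sum_k beta_k G_ik + sum_e (beta_E E_s + beta_GxE G_ik E_s)
        + loading_g F_m(s) + u_i + eps_s

with u_i ~ N(0, s2_u) and eps ~ N(0, s2_e).  For a module with a planted
trans driver, the mediator gene receives a cis effect from the driver SNP
and the module factor is F = f * standardised(mediator) + sqrt(1-f^2) * z,
so f = 1 gives complete mediation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CELL_TYPES, ExpressionMatrix, GenotypeMatrix

__all__ = [
    "TruthTable",
    "CohortBundle",
    "simulate_genotypes",
    "simulate_cohort",
    "write_cohort",
    "default_design",
]


class ConfigError(ValueError):
    pass


@dataclass
class TruthTable:
    """Planted effects: what the cohort's generator actually put in."""

    cis_effects: pd.DataFrame  # gene, snp, beta, signal_rank
    interaction_effects: pd.DataFrame  # gene, snp, env, beta_env, beta_gxe
    module_truth: list  # dicts: module_id, member_genes, driver_snp, ...
    variance_components: pd.DataFrame  # gene, sigma2_u, sigma2_e

    def validate(self, geno: GenotypeMatrix, genes):
        gene_set, snp_set = set(genes), set(geno.snp_ids)
        for df in (self.cis_effects, self.interaction_effects):
            for _, row in df.iterrows():
                if row["gene"] not in gene_set or row["snp"] not in snp_set:
                    raise ConfigError(f"unknown gene/snp in truth: {dict(row)}")
        for mod in self.module_truth:
            if not 0.0 <= mod.get("mediation_fraction", 0.0) <= 1.0:
                raise ConfigError("mediation_fraction must lie in [0, 1]")
        if len(self.cis_effects) and (self.cis_effects["signal_rank"] < 1).any():
            raise ConfigError("signal_rank must be >= 1")


@dataclass
class CohortBundle:
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    samples: pd.DataFrame
    truth: TruthTable
    seed: int


def simulate_genotypes(
    n_individuals: int,
    n_snps: int,
    maf_range=(0.05, 0.5),
    ld_rho: float = 0.0,
    block_size: int = 50,
    seed: int = 0,
    chrom: str = "1",
    spacing: int = 5000,
) -> GenotypeMatrix:
    """HWE genotypes with first-order haplotype-copying LD within blocks.

    Two haplotypes per individual; within an LD block each SNP's allele
    copies the previous SNP's allele with probability ``ld_rho``, otherwise
    it is redrawn at its own MAF.  Dosage counts the cohort minor allele.
    """
    if n_individuals < 2:
        raise ConfigError("need at least two individuals")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ConfigError("maf_range must be a non-empty interval in (0, 0.5]")
    if not 0 <= ld_rho < 1:
        raise ConfigError("ld_rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_snps)
    haps = np.empty((2 * n_individuals, n_snps), dtype=np.int8)
    for j in range(n_snps):
        fresh = rng.random(2 * n_individuals) < mafs[j]
        if j % block_size == 0 or ld_rho == 0.0:
            haps[:, j] = fresh
        else:
            copy = rng.random(2 * n_individuals) < ld_rho
            haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
    dosage = (haps[0::2] + haps[1::2]).astype(np.int8)
    # orient to the observed minor allele so VCF round trips exactly
    freq = dosage.sum(axis=0) / (2.0 * n_individuals)
    flip = freq > 0.5
    dosage[:, flip] = 2 - dosage[:, flip]
    maf_obs = np.minimum(freq, 1 - freq)
    ids = [f"snp{j:05d}" for j in range(n_snps)]
    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n_snps + 1) * spacing,
            "ref": "A",
            "alt": "G",
            "maf": maf_obs,
            "flipped": False,
        },
        index=pd.Index(ids, name="snp"),
    )
    individual_ids = [f"ind{i:04d}" for i in range(n_individuals)]
    return GenotypeMatrix(dosage, meta, individual_ids)


def default_design() -> dict:
    """Baseline cohort settings; values emulate the study conditions."""
    return {
        "n_genes": 100,
        "samples_per_individual_probs": [0.55, 0.25, 0.20],  # 1, 2 or 3 visits
        "sigma_u": 0.5,  # individual random-intercept SD
        "sigma_e": 0.5,  # residual SD
        "srs1_prob": 0.35,
        "diagnosis_fp_prob": 0.4,
        "female_prob": 0.4,
        "cell_alpha": [12.0, 4.0, 2.0],  # neutrophil-dominant blood
        "srs_cell_shift": 4.0,  # added to neutrophil alpha in SRS1
        "cell_missing_rate": 0.01,
        "module_sample_noise": 0.3,
        "survival_base_rate": 0.012,  # events/day; ~28% events by day 28
        "survival_beta": 0.0,  # log-hazard per unit module factor
        "survival_module": None,
        "beta_env_default": 0.3,
        "tss_jitter": 100,
        # pervasive shared expression variation (technical batches, cell
        # composition): what the hidden-factor covariates are meant to absorb
        "n_background_factors": 25,
        "background_loading_sd": 0.25,
    }


def _truth_frames(truth_config, beta_env_default):
    cis = pd.DataFrame(
        truth_config.get("cis_effects", []),
        columns=["gene", "snp", "beta", "signal_rank"],
    )
    if len(cis):
        dup = cis.duplicated(subset=["gene", "snp"], keep=False)
        if dup.any():
            raise ConfigError("conflicting cis effects for the same gene/SNP pair")
    inter = pd.DataFrame(
        truth_config.get("interaction_effects", []),
        columns=["gene", "snp", "env", "beta_env", "beta_gxe"],
    )
    if len(inter):
        inter["beta_env"] = inter["beta_env"].fillna(beta_env_default)
    modules = list(truth_config.get("modules", []))
    return cis, inter, modules


def simulate_cohort(
    geno: GenotypeMatrix, design: dict | None = None,
    truth_config: dict | None = None, seed: int = 0,
) -> CohortBundle:
    """Draw a full cohort over ``geno`` with the requested planted effects."""
    cfg = default_design()
    cfg.update(design or {})
    truth_config = truth_config or {}
    rng = np.random.default_rng(seed)
    n_ind = geno.n_individuals
    n_genes = int(cfg["n_genes"])
    genes = [f"G{g:04d}" for g in range(n_genes)]

    cis, inter, modules = _truth_frames(truth_config, cfg["beta_env_default"])
    gene_set, snp_set = set(genes), set(geno.snp_ids)
    for df in (cis, inter):
        for _, row in df.iterrows():
            if row["gene"] not in gene_set or row["snp"] not in snp_set:
                raise ConfigError(f"unknown gene/snp in truth: {dict(row)}")
    for mod in modules:
        bad = [g for g in mod["member_genes"] if g not in gene_set]
        if bad or (mod.get("mediator_gene") not in (None, *gene_set)):
            raise ConfigError(f"unknown module genes: {bad}")
        if mod.get("driver_snp") not in (None, *snp_set):
            raise ConfigError(f"unknown driver SNP {mod.get('driver_snp')}")
        if not 0.0 <= float(mod.get("mediation_fraction", 0.0)) <= 1.0:
            raise ConfigError("mediation_fraction must lie in [0, 1]")

    # --- samples ------------------------------------------------------------
    n_per = rng.choice([1, 2, 3], size=n_ind, p=cfg["samples_per_individual_probs"])
    timepoints = [1, 3, 5]
    rows = []
    for i, iid in enumerate(geno.individual_ids):
        srs1 = int(rng.random() < cfg["srs1_prob"])
        diag = int(rng.random() < cfg["diagnosis_fp_prob"])
        sex = int(rng.random() < cfg["female_prob"])
        for k in range(n_per[i]):
            rows.append((f"{iid}_t{timepoints[k]}", iid, timepoints[k], srs1, diag, sex))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "individual_id", "time_point",
                       "srs1", "diagnosis_fp", "sex_female"],
    )
    n_samp = len(samples)
    ind_of = samples["individual_id"].map(geno.individual_index()).to_numpy()

    # cell proportions: Dirichlet, neutrophil alpha raised in SRS1
    alpha = np.asarray(cfg["cell_alpha"], dtype=float)
    props = np.empty((n_samp, 3))
    for s in range(n_samp):
        a = alpha.copy()
        if samples["srs1"].iat[s]:
            a[0] += cfg["srs_cell_shift"]
        props[s] = rng.dirichlet(a)
    miss = rng.random(n_samp) < cfg["cell_missing_rate"]
    props[miss] = np.nan
    for c, cell in enumerate(CELL_TYPES):
        samples[cell] = props[:, c]

    # ancestry axes: independent per-individual scores, as genome-wide PCs
    # would be (PCs of the small simulated SNP panel itself would be
    # collinear with individual test SNPs, which genome-scale PCs are not)
    pcs = rng.normal(size=(n_ind, 7))
    for k in range(7):
        samples[f"geno_pc{k + 1}"] = pcs[ind_of, k]

    # --- expression ---------------------------------------------------------
    s2u = float(cfg["sigma_u"]) ** 2
    s2e = float(cfg["sigma_e"]) ** 2
    mu = rng.normal(6.0, 1.0, size=n_genes)
    gi = {g: k for k, g in enumerate(genes)}
    u = rng.normal(0.0, cfg["sigma_u"], size=(n_genes, n_ind))
    eps = rng.normal(0.0, cfg["sigma_e"], size=(n_genes, n_samp))
    Y = mu[:, None] + u[:, ind_of] + eps
    n_bg = int(cfg["n_background_factors"])
    if n_bg:
        H = rng.normal(size=(n_bg, n_ind))[:, ind_of]
        H = H + 0.3 * rng.normal(size=(n_bg, n_samp))
        L = rng.normal(0.0, cfg["background_loading_sd"], size=(n_genes, n_bg))
        Y += L @ H

    env_vectors = {
        "srs1": samples["srs1"].to_numpy(float),
        "diagnosis": samples["diagnosis_fp"].to_numpy(float),
        "sex": samples["sex_female"].to_numpy(float),
        "neutrophils": np.nan_to_num(props[:, 0], nan=np.nanmedian(props[:, 0])),
        "lymphocytes": np.nan_to_num(props[:, 1], nan=np.nanmedian(props[:, 1])),
        "monocytes": np.nan_to_num(props[:, 2], nan=np.nanmedian(props[:, 2])),
    }

    for _, row in cis.iterrows():
        g = geno.column(row["snp"]).astype(float)[ind_of]
        Y[gi[row["gene"]]] += float(row["beta"]) * g
    for _, row in inter.iterrows():
        g = geno.column(row["snp"]).astype(float)[ind_of]
        e = env_vectors[row["env"]]
        Y[gi[row["gene"]]] += float(row["beta_env"]) * e + float(row["beta_gxe"]) * g * e

    # latent co-expression modules, optionally SNP-driven through a mediator
    module_truth = []
    factors = {}
    for mod in modules:
        mod = dict(mod)
        members = list(mod["member_genes"])
        f = float(mod.get("mediation_fraction", 0.0))
        driver, mediator = mod.get("driver_snp"), mod.get("mediator_gene")
        if driver is not None and mediator is not None:
            beta_med = float(mod.get("driver_beta", 0.8))
            g = geno.column(driver).astype(float)[ind_of]
            Y[gi[mediator]] += beta_med * g
            med = Y[gi[mediator]]
            med_std = (med - med.mean()) / max(med.std(), 1e-12)
            F = f * med_std + np.sqrt(max(0.0, 1 - f * f)) * rng.normal(size=n_samp)
        else:
            Fi = rng.normal(size=n_ind)
            F = Fi[ind_of] + cfg["module_sample_noise"] * rng.normal(size=n_samp)
            F = (F - F.mean()) / max(F.std(), 1e-12)
        loading = float(mod.get("loading", 0.8))
        for m in members:
            if mediator is not None and m == mediator:
                continue  # the mediator's module link is the factor itself
            Y[gi[m]] += loading * F
        factors[mod.get("module_id", len(module_truth) + 1)] = F
        module_truth.append(
            {
                "module_id": mod.get("module_id", len(module_truth) + 1),
                "member_genes": members,
                "driver_snp": driver,
                "mediator_gene": mediator,
                "mediation_fraction": f,
                "loading": loading,
                "driver_beta": float(mod.get("driver_beta", 0.8))
                if driver is not None else np.nan,
            }
        )

    # --- survival: exponential, optionally linked to a module factor --------
    loghaz = np.full(n_ind, np.log(cfg["survival_base_rate"]))
    if cfg["survival_beta"] and cfg["survival_module"] in factors:
        F = factors[cfg["survival_module"]]
        last = samples.groupby("individual_id", sort=False)["time_point"].idxmax()
        per_ind = np.zeros(n_ind)
        for iid, idx in last.items():
            per_ind[geno.individual_index()[iid]] = F[idx]
        loghaz = loghaz + cfg["survival_beta"] * per_ind
    t = rng.exponential(1.0 / np.exp(loghaz))
    event = (t <= 28.0).astype(int)
    t = np.minimum(t, 28.0)
    samples["surv_time"] = t[ind_of]
    samples["surv_event"] = event[ind_of]

    # --- gene annotation: TSS near the SNP grid so cis windows have SNPs ----
    span = int(geno.snp_meta["pos"].max())
    tss = np.linspace(1, span, n_genes).astype(int)
    tss = tss + rng.integers(-cfg["tss_jitter"], cfg["tss_jitter"] + 1, size=n_genes)
    gene_meta = pd.DataFrame(
        {"chrom": geno.snp_meta["chrom"].iloc[0], "tss": np.maximum(tss, 1)},
        index=pd.Index(genes, name="gene"),
    )
    expr = ExpressionMatrix(
        pd.DataFrame(Y, index=genes, columns=samples["sample_id"]), gene_meta
    )
    varcomp = pd.DataFrame({"gene": genes, "sigma2_u": s2u, "sigma2_e": s2e})
    truth = TruthTable(cis, inter, module_truth, varcomp)
    truth.validate(geno, genes)
    return CohortBundle(geno, expr, samples, truth, seed)


def write_cohort(bundle: CohortBundle, out_dir) -> dict:
    """Write VCF + TSVs; the VCF ALT allele is the cohort minor allele."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geno = bundle.genotypes
    vcf_path = out / "genotypes.vcf"
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(geno.snp_meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.individual_ids) + "\n"
        )
        for j, (snp, row) in enumerate(geno.snp_meta.iterrows()):
            gts = "\t".join(gt_codes[int(d)] for d in geno.dosage[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{snp}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )
    expr_path = out / "expression.tsv"
    bundle.expression.values.to_csv(expr_path, sep="\t", index_label="gene")
    genes_path = out / "genes.tsv"
    bundle.expression.gene_meta.to_csv(genes_path, sep="\t", index_label="gene")
    samples_path = out / "samples.tsv"
    bundle.samples.to_csv(samples_path, sep="\t", index=False)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    bundle.truth.cis_effects.to_csv(truth_dir / "cis_effects.tsv", sep="\t", index=False)
    bundle.truth.interaction_effects.to_csv(
        truth_dir / "interaction_effects.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {**m, "member_genes": ",".join(m["member_genes"])}
            for m in bundle.truth.module_truth
        ]
    ).to_csv(truth_dir / "module_truth.tsv", sep="\t", index=False)
    bundle.truth.variance_components.to_csv(
        truth_dir / "variance_components.tsv", sep="\t", index=False
    )
    return {
        "vcf": str(vcf_path),
        "expression": str(expr_path),
        "genes": str(genes_path),
        "samples": str(samples_path),
        "truth_dir": str(truth_dir),
        "seed": bundle.seed,
    }
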