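"""Genotype-by-context interaction tests for independent eQTL signals.

Each signal SNP is tested for an interaction between dosage and a context
variable — SRS1 status, diagnosis (CAP vs FP), sex, or an INT-transformed
cell proportion — with the usual covariates, any other independent signals
for the same gene as conditioning terms, and a random intercept per
individual.  The interaction p comes from a 1-df LRT on the G:E term.
Eligibility requires at least two minor-allele-homozygote individuals in
each level of a binary context, or in each half of a continuous context
split at the median (ties to the lower half).  Significant interactions are
"magnifiers" when the interaction has the same sign as the genotype main
effect and "dampeners" otherwise.  A label-permutation null calibrates the
count of significant interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import covariate_matrix
from .lmm import RandomInterceptLM, lrt_nested

__all__ = [
    "InteractionResult",
    "EnvSpec",
    "test_interaction",
    "classify_results",
    "permutation_null",
]

BINARY_ENVS = {"srs1": "srs1", "diagnosis": "diagnosis_fp", "sex": "sex_female"}
CONTINUOUS_ENVS = {
    "neutrophils": "int_neutrophils",
    "lymphocytes": "int_lymphocytes",
    "monocytes": "int_monocytes",
}


@dataclass
class EnvSpec:
    """A context variable: its name and sample-frame column."""

    name: str

    @property
    def column(self) -> str:
        if self.name in BINARY_ENVS:
            return BINARY_ENVS[self.name]
        if self.name in CONTINUOUS_ENVS:
            return CONTINUOUS_ENVS[self.name]
        raise ValueError(f"unknown environment {self.name!r}")

    @property
    def binary(self) -> bool:
        return self.name in BINARY_ENVS


@dataclass
class InteractionResult:
    gene: str
    lead_snp: str
    env_name: str
    eligible: bool
    beta_g: float = np.nan
    beta_gxe: float = np.nan
    se_gxe: float = np.nan
    p_interaction: float = np.nan
    q_bh: float = np.nan
    klass: str = "none"  # magnifier / dampener / none


def _eligible(dose_samp, env_samp, ind_ids, binary: bool) -> bool:
    """>=2 distinct minor-allele-homozygote individuals per level.

    Levels are the two values of a binary context, or the halves of a
    continuous context split at the sample median (ties to the lower half).
    """
    hom = dose_samp == 2
    if binary:
        levels = [env_samp == 0, env_samp == 1]
    else:
        med = np.median(env_samp)
        levels = [env_samp <= med, env_samp > med]
    for lv in levels:
        if len(set(ind_ids[hom & lv])) < 2:
            return False
    return True


def test_interaction(
    signal,
    env: EnvSpec,
    geno,
    expr,
    samples: pd.DataFrame,
    other_leads=(),
    sex_check_threshold: float = 0.05,
) -> InteractionResult:
    """Fit the G + E + G:E model for one signal and one context."""
    ind_of = samples["individual_id"].map(geno.individual_index()).to_numpy()
    g = geno.column(signal.lead_snp).astype(float)[ind_of]
    e = samples[env.column].to_numpy(dtype=float)
    res = InteractionResult(signal.gene, signal.lead_snp, env.name, eligible=True)
    ok = np.isfinite(e)
    if not _eligible(
        g[ok], e[ok], samples["individual_id"].to_numpy()[ok], env.binary
    ):
        res.eligible = False
        return res

    y = expr.values.loc[signal.gene, samples["sample_id"]].to_numpy(dtype=float)
    groups = samples["individual_id"].to_numpy()
    extra = {
        f"cond_{s}": geno.column(s).astype(float)[ind_of] for s in other_leads
    }
    # E enters explicitly; drop it from the covariate stack if already there
    X0, names0 = covariate_matrix(samples, exclude={env.column}, extra=extra)

    if env.name == "sex":
        # sex is not a standard covariate: require the main eQTL to remain
        # significant once sex is added before testing the interaction
        Xs = np.column_stack([X0, e])
        base = RandomInterceptLM(y, Xs, groups).fit()
        with_g = RandomInterceptLM(y, np.column_stack([Xs, g]), groups).fit()
        _, p_main = lrt_nested(with_g, base, df=1)
        if p_main >= sex_check_threshold:
            res.eligible = False
            return res

    X_null = np.column_stack([X0, g, e])
    names = names0 + ["dosage", "env"]
    null_fit = RandomInterceptLM(y, X_null, groups, xnames=names).fit()
    X_full = np.column_stack([X_null, g * e])
    full_fit = RandomInterceptLM(
        y, X_full, groups, xnames=names + ["dosage_x_env"]
    ).fit()
    if np.isnan(full_fit.params[-1]):
        res.eligible = False
        return res
    _, p = lrt_nested(full_fit, null_fit, df=1)
    res.beta_g = float(full_fit.params[names.index("dosage")])
    res.beta_gxe = float(full_fit.params[-1])
    res.se_gxe = float(full_fit.bse[-1])
    res.p_interaction = p
    return res


def classify_results(results, fdr: float = 0.05):
    """BH within one context family, then magnifier/dampener quadrant rule."""
    tested = [r for r in results if r.eligible and np.isfinite(r.p_interaction)]
    if tested:
        _, q, _, _ = multipletests(
            [r.p_interaction for r in tested], method="fdr_bh"
        )
        for r, qv in zip(tested, q):
            r.q_bh = float(qv)
            if qv < fdr:
                same = np.sign(r.beta_g) == np.sign(r.beta_gxe)
                r.klass = "magnifier" if same else "dampener"
            else:
                r.klass = "none"
    return results


def results_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene, "snp": r.lead_snp, "env": r.env_name,
                "eligible": r.eligible, "beta_g": r.beta_g,
                "beta_gxe": r.beta_gxe, "se_gxe": r.se_gxe,
                "p": r.p_interaction, "q": r.q_bh, "class": r.klass,
            }
            for r in results
        ]
    )


def _run_family(signals, env, geno, expr, samples, fdr):
    by_gene: dict = {}
    for s in signals:
        by_gene.setdefault(s.gene, []).append(s)
    out = []
    for s in signals:
        others = [t.lead_snp for t in by_gene[s.gene] if t.lead_snp != s.lead_snp]
        out.append(test_interaction(s, env, geno, expr, samples, others))
    return classify_results(out, fdr=fdr)


def run_interactions(signals, env_name, geno, expr, samples, fdr: float = 0.05):
    """Test every independent signal against one context; BH within family."""
    return _run_family(signals, EnvSpec(env_name), geno, expr, samples, fdr)


def permutation_null(
    signals,
    env_name: str,
    geno,
    expr,
    samples: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    fdr: float = 0.05,
):
    """Empirical p for the observed count of significant interactions.

    SRS is permuted across samples; diagnosis across patients (constant
    within patient).  Returns ``(p_empirical, observed_count, null_counts)``
    with the add-one estimator (1 + #{null >= obs}) / (n_perm + 1).
    """
    if env_name not in ("srs1", "diagnosis"):
        raise ValueError("permutation null defined for srs1 or diagnosis only")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    env = EnvSpec(env_name)
    rng = np.random.default_rng(seed)
    observed = sum(
        r.klass != "none"
        for r in _run_family(signals, env, geno, expr, samples, fdr)
    )
    one_per_ind = (
        samples["individual_id"].value_counts().max() == 1
    )
    if one_per_ind:
        null_counts = _permute_ols(
            signals, env, geno, expr, samples, n_perm, rng, fdr
        )
    else:
        null_counts = np.empty(n_perm, dtype=int)
        col = env.column
        for b in range(n_perm):
            perm = samples.copy()
            if env_name == "srs1":
                perm[col] = rng.permutation(perm[col].to_numpy())
            else:
                per_ind = perm.groupby("individual_id", sort=False)[col].first()
                shuffled = pd.Series(
                    rng.permutation(per_ind.to_numpy()), index=per_ind.index
                )
                perm[col] = perm["individual_id"].map(shuffled).to_numpy()
            null_counts[b] = sum(
                r.klass != "none"
                for r in _run_family(signals, env, geno, expr, perm, fdr)
            )
    p = (1.0 + np.sum(null_counts >= observed)) / (n_perm + 1.0)
    return float(p), int(observed), null_counts


def _permute_ols(signals, env, geno, expr, samples, n_perm, rng, fdr):
    """Vectorised permutation loop for the one-sample-per-individual case.

    With singleton groups the LMM pins the individual variance to zero and
    the LRT reduces to an OLS residual-sum comparison, computed here by
    incremental projection so each permutation costs O(n) per signal.
    """
    from scipy.stats import chi2

    ind_of = samples["individual_id"].map(geno.individual_index()).to_numpy()
    inds = samples["individual_id"].to_numpy()
    n = len(samples)
    by_gene: dict = {}
    for s in signals:
        by_gene.setdefault(s.gene, []).append(s)
    pre = []
    for s in signals:
        others = [t.lead_snp for t in by_gene[s.gene] if t.lead_snp != s.lead_snp]
        extra = {f"cond_{o}": geno.column(o).astype(float)[ind_of]
                 for o in others}
        X0, _ = covariate_matrix(samples, exclude={env.column}, extra=extra)
        g = geno.column(s.lead_snp).astype(float)[ind_of]
        Q, _ = np.linalg.qr(np.column_stack([X0, g]))
        y = expr.values.loc[s.gene, samples["sample_id"]].to_numpy(dtype=float)
        ry = y - Q @ (Q.T @ y)
        pre.append((g, Q, ry, float(ry @ ry)))
    e_obs = samples[env.column].to_numpy(dtype=float)
    null_counts = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        e = rng.permutation(e_obs)
        ps = []
        for g, Q, ry, rss_base in pre:
            if not _eligible(g, e, inds, env.binary):
                continue
            ep = e - Q @ (Q.T @ e)
            nrm = np.linalg.norm(ep)
            if nrm < 1e-10:
                continue
            ep /= nrm
            rss0 = rss_base - float(ry @ ep) ** 2
            ge = g * e
            w = ge - Q @ (Q.T @ ge)
            w -= (w @ ep) * ep
            nw = np.linalg.norm(w)
            if nw < 1e-10:
                continue
            w /= nw
            rss1 = max(rss0 - float(ry @ w) ** 2, 1e-300)
            stat = n * np.log(rss0 / rss1)
            ps.append(float(chi2.sf(stat, 1)))
        if ps:
            _, q, _, _ = multipletests(ps, method="fdr_bh")
            null_counts[b] = int(np.sum(q < fdr))
        else:
            null_counts[b] = 0
    return null_counts
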