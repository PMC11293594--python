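"""Candidate upstream regulators of context-dependent eQTLs.

Two complementary lines of evidence:

* motif alteration — a transparent allele-aware PWM scanner decides, for a
  SNP and its LD proxies (r^2 >= 0.8), whether either allele creates or
  destroys a predicted binding site (log-odds score over both strands and
  all windows overlapping the SNP, hit when the score reaches a fraction of
  the maximum achievable PWM score); per independent eQTL signal each motif
  is collapsed to altered (>=1 site) or not, and one-sided Fisher tests ask
  whether alteration is enriched among signals with a significant context
  interaction, with a label-permutation null for the count of enriched
  motifs;

* regulon activity — per-sample TF activity scores from curated regulons
  (evidence A-C, >=5 targets), tested for differential activity between
  SRS groups with the random-intercept LMM and correlated with estimated
  cell proportions (Spearman, first sample per patient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lmm import RandomInterceptLM, lrt_nested
from .io import ld_r2

__all__ = [
    "load_jaspar_pwms",
    "read_gmt",
    "scan_motif_alteration",
    "ld_proxies",
    "alteration_matrix",
    "motif_enrichment",
    "load_regulons",
    "regulon_activity",
    "differential_activity",
    "activity_cell_correlation",
    "set_enrichment",
]

_COMP = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def load_jaspar_pwms(path) -> dict:
    """Parse a JASPAR-format matrix file into {name: 4 x L count array}."""
    from Bio import motifs

    with open(path) as fh:
        parsed = motifs.parse(fh, "jaspar")
    out = {}
    for m in parsed:
        name = m.name or m.matrix_id
        out[name] = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
    return out


def read_gmt(path) -> dict:
    """GMT gene sets: {set_name: set of genes}."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def _log_odds(counts: np.ndarray, pseudocount: float = 0.25) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    probs = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
    return np.log2(probs / 0.25)


def _best_score(seq: str, snp_idx: int, lom: np.ndarray) -> float:
    """Best log-odds over both strands and all windows covering snp_idx."""
    L = lom.shape[1]
    best = -np.inf
    for strand_seq, idx in ((seq, snp_idx), (seq.translate(_COMP)[::-1],
                                             len(seq) - 1 - snp_idx)):
        lo = max(0, idx - L + 1)
        hi = min(len(strand_seq) - L, idx)
        for start in range(lo, hi + 1):
            window = strand_seq[start : start + L]
            try:
                s = sum(lom[_BASE_INDEX[b], k] for k, b in enumerate(window))
            except KeyError:
                continue  # ambiguous base
            best = max(best, s)
    return best


def scan_motif_alteration(
    seq: str,
    snp_idx: int,
    ref: str,
    alt: str,
    pwm_counts: np.ndarray,
    hit_fraction: float = 0.8,
) -> str:
    """Classify a SNP's effect on one motif: introduced / interrupted / none.

    ``seq`` carries the REF allele at ``snp_idx``; flanks must extend at
    least motif length - 1 on each side of the SNP.
    """
    lom = _log_odds(pwm_counts)
    L = lom.shape[1]
    if snp_idx < L - 1 or len(seq) - snp_idx - 1 < L - 1:
        raise ValueError("flanking sequence shorter than motif length - 1")
    if seq[snp_idx].upper() != ref.upper():
        raise ValueError("sequence does not carry the REF allele at snp_idx")
    seq = seq.upper()
    alt_seq = seq[:snp_idx] + alt.upper() + seq[snp_idx + 1 :]
    threshold = hit_fraction * float(lom.max(axis=0).sum())
    ref_hit = _best_score(seq, snp_idx, lom) >= threshold
    alt_hit = _best_score(alt_seq, snp_idx, lom) >= threshold
    if ref_hit and not alt_hit:
        return "interrupted"
    if alt_hit and not ref_hit:
        return "introduced"
    return "none"


def ld_proxies(geno, lead_snp: str, r2_min: float = 0.8,
               window_bp: int = 1_000_000) -> list:
    """All SNPs within the window in LD r^2 >= r2_min with the lead."""
    meta = geno.snp_meta
    lead = meta.loc[lead_snp]
    g_lead = geno.column(lead_snp)
    cand = meta.index[
        (meta["chrom"] == lead["chrom"])
        & ((meta["pos"] - lead["pos"]).abs() <= window_bp)
    ]
    out = []
    for snp in cand:
        g = geno.column(snp)
        if np.std(g) == 0:
            continue
        if ld_r2(g_lead, g) >= r2_min:
            out.append(snp)
    return out


def alteration_matrix(signal_ids, proxy_map: dict, snp_motif_calls: dict,
                      motifs) -> pd.DataFrame:
    """Collapse per-SNP motif calls to a binary signals x motifs matrix.

    ``proxy_map[signal_id]`` lists the lead SNP and its LD proxies;
    ``snp_motif_calls[snp][motif]`` is 'introduced'/'interrupted'/'none'.
    A signal alters a motif when any of its SNPs does.
    """
    M = pd.DataFrame(0, index=list(signal_ids), columns=list(motifs), dtype=int)
    for sig in signal_ids:
        for snp in proxy_map.get(sig, []):
            calls = snp_motif_calls.get(snp, {})
            for motif, call in calls.items():
                if call in ("introduced", "interrupted") and motif in M.columns:
                    M.loc[sig, motif] = 1
    return M


def motif_enrichment(
    alterations: pd.DataFrame,
    interaction_flags: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    fdr: float = 0.05,
):
    """One-sided Fisher enrichment of motif alteration in interaction signals.

    Returns ``(table, perm_p, null_counts)``: per-motif odds ratio, p, q and
    the permutation-expected count of motifs with q < fdr; motifs altered in
    zero signals are excluded from the BH family.
    """
    flags = interaction_flags.reindex(alterations.index).astype(bool)
    if flags.all() or (~flags).all():
        raise ValueError("both interaction classes must be non-empty")

    def _family(alt_mat, flags_arr):
        recs = []
        for motif in alt_mat.columns:
            a = alt_mat[motif].to_numpy().astype(bool)
            if a.sum() == 0:
                continue  # never altered: skipped with note
            t11 = int(np.sum(a & flags_arr))
            t10 = int(np.sum(a & ~flags_arr))
            t01 = int(np.sum(~a & flags_arr))
            t00 = int(np.sum(~a & ~flags_arr))
            orr, p = stats.fisher_exact([[t11, t10], [t01, t00]],
                                        alternative="greater")
            recs.append((motif, orr, p, t11, t10))
        if not recs:
            return pd.DataFrame(
                columns=["motif", "odds_ratio", "p", "n_alt_inter", "n_alt_other"]
            )
        tab = pd.DataFrame(
            recs, columns=["motif", "odds_ratio", "p", "n_alt_inter", "n_alt_other"]
        )
        _, q, _, _ = multipletests(tab["p"], method="fdr_bh")
        tab["q"] = q
        return tab

    obs = _family(alterations, flags.to_numpy())
    observed_count = int((obs["q"] < fdr).sum()) if len(obs) else 0
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=int)
    f = flags.to_numpy()
    for b in range(n_perm):
        fp = rng.permutation(f)
        tb = _family(alterations, fp)
        null_counts[b] = int((tb["q"] < fdr).sum()) if len(tb) else 0
    perm_p = (1.0 + np.sum(null_counts >= observed_count)) / (n_perm + 1.0)
    obs.attrs["observed_significant"] = observed_count
    obs.attrs["perm_expected"] = float(null_counts.mean())
    return obs, float(perm_p), null_counts


def load_regulons(path, evidence_levels=("A", "B", "C"),
                  min_size: int = 5) -> pd.DataFrame:
    """TSV (tf, target, mode, evidence) filtered to usable regulons."""
    reg = pd.read_csv(path, sep="\t")
    reg = reg[reg["evidence"].isin(evidence_levels)]
    sizes = reg.groupby("tf")["target"].nunique()
    keep = sizes.index[sizes >= min_size]
    return reg[reg["tf"].isin(keep)].reset_index(drop=True)


@dataclass
class ActivityMatrix:
    values: pd.DataFrame  # TFs x samples
    regulons: pd.DataFrame


def regulon_activity(expr, regulons: pd.DataFrame,
                     min_size: int = 5) -> ActivityMatrix:
    """Per-sample TF activity: t-statistic of the regulon-mode regression.

    Expression is standardised across genes within each sample; the
    activity of a TF in a sample is the t-statistic of the slope from
    regressing the sample's standardised expression on the TF's mode
    vector (+1/-1 for targets, 0 elsewhere) — a single deterministic
    linear-model estimator of regulon activity.
    """
    X = expr.values.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("a sample has constant expression; activity undefined")
    Z = (X - X.mean(axis=0)) / sd  # genes x samples, per-sample z-scores
    gene_index = {g: i for i, g in enumerate(expr.genes)}
    n = Z.shape[0]
    rows = []
    tfs = []
    for tf, sub in regulons.groupby("tf"):
        sub = sub[sub["target"].isin(gene_index)]
        if sub["target"].nunique() < min_size:
            continue
        mode = np.zeros(n)
        for _, r in sub.iterrows():
            mode[gene_index[r["target"]]] = float(r["mode"])
        mc = mode - mode.mean()
        denom = float(mc @ mc)
        slope = (mc @ Z) / denom
        # residual variance of each per-sample regression
        fitted_ss = slope**2 * denom
        total_ss = (Z**2).sum(axis=0) - n * Z.mean(axis=0) ** 2
        resid_ss = np.maximum(total_ss - fitted_ss, 1e-12)
        se = np.sqrt(resid_ss / (n - 2) / denom)
        rows.append(slope / se)
        tfs.append(tf)
    values = pd.DataFrame(rows, index=tfs, columns=expr.sample_ids)
    return ActivityMatrix(values, regulons)


def differential_activity(acts: ActivityMatrix, samples: pd.DataFrame,
                          group_col: str = "srs1", n_perm: int = 0,
                          seed: int = 0, fdr: float = 0.05):
    """Per-TF LMM activity ~ group with individual random intercept.

    Returns ``(table, expected_by_chance)``; the latter is the mean count
    of BH-significant TFs over ``n_perm`` group-label permutations (NaN
    when ``n_perm`` is 0).
    """
    grp = samples[group_col].to_numpy(dtype=float)
    if len(np.unique(grp)) < 2:
        raise ValueError("both groups must be represented")
    groups = samples["individual_id"].to_numpy()
    A = acts.values.loc[:, samples["sample_id"]].to_numpy(dtype=float)

    def _family(g):
        X_full = np.column_stack([np.ones(len(g)), g])
        recs = []
        for i, tf in enumerate(acts.values.index):
            y = A[i]
            full = RandomInterceptLM(y, X_full, groups).fit()
            null = RandomInterceptLM(y, X_full[:, :1], groups).fit()
            _, p = lrt_nested(full, null, df=1)
            recs.append((tf, float(full.params[1]), float(full.bse[1]), p))
        tab = pd.DataFrame(recs, columns=["tf", "effect", "se", "p"])
        _, q, _, _ = multipletests(tab["p"], method="fdr_bh")
        tab["q"] = q
        return tab

    obs = _family(grp)
    expected = np.nan
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        counts = []
        per_ind = samples.groupby("individual_id", sort=False)[group_col].first()
        for _ in range(n_perm):
            shuffled = pd.Series(
                rng.permutation(per_ind.to_numpy()), index=per_ind.index
            )
            counts.append(
                int((_family(
                    samples["individual_id"].map(shuffled).to_numpy(float)
                )["q"] < fdr).sum())
            )
        expected = float(np.mean(counts))
    return obs, expected


def activity_cell_correlation(acts: ActivityMatrix, samples: pd.DataFrame,
                              cell_estimates: pd.DataFrame, fdr: float = 0.05):
    """Spearman activity vs estimated cell proportions, first sample per patient.

    ``cell_estimates`` is samples x cell types, indexed by sample id.
    """
    first = samples.sort_values("time_point").groupby(
        "individual_id", sort=False
    ).first()
    ids = first["sample_id"].tolist()
    A = acts.values.loc[:, ids]
    C = cell_estimates.loc[ids]
    recs = []
    for tf in A.index:
        for cell in C.columns:
            x = A.loc[tf].to_numpy(dtype=float)
            y = C[cell].to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(x) == 0:
                recs.append((tf, cell, np.nan, np.nan))
                continue
            rho, p = stats.spearmanr(x, y)
            recs.append((tf, cell, float(rho), float(p)))
    tab = pd.DataFrame(recs, columns=["tf", "cell_type", "rho", "p"])
    ok = tab["p"].notna()
    tab["q"] = np.nan
    if ok.any():
        _, q, _, _ = multipletests(tab.loc[ok, "p"], method="fdr_bh")
        tab.loc[ok, "q"] = q
    tab["significant"] = tab["q"] < fdr
    return tab


def set_enrichment(hits, universe, annotation, method: str = "hypergeometric",
                   null_rate: float | None = None):
    """Overlap enrichment of ``hits`` within ``universe``.

    ``method`` is 'hypergeometric' or 'fisher_one_sided' for set
    annotations, or 'binomial' for interval-style annotations where
    ``annotation`` is the set of hits lying in the annotation and
    ``null_rate`` the universe's annotation rate.  Returns
    ``(enrichment, p)`` with enrichment = (hit fraction)/(universe
    fraction).
    """
    hits = set(hits)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    if method == "binomial":
        if null_rate is None:
            raise ValueError("binomial method requires null_rate")
        k = len(set(annotation) & hits)
        n = len(hits)
        p = float(stats.binom.sf(k - 1, n, null_rate))
        enr = (k / n) / null_rate if n else np.nan
        return enr, p
    ann = set(annotation) & universe
    k = len(hits & ann)
    n, K, N = len(hits), len(ann), len(universe)
    if method == "hypergeometric":
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    elif method == "fisher_one_sided":
        table = [[k, n - k], [K - k, N - K - (n - k)]]
        _, p = stats.fisher_exact(table, alternative="greater")
        p = float(p)
    else:
        raise ValueError(f"unknown method {method!r}")
    hit_frac = k / n if n else np.nan
    uni_frac = K / N
    enr = hit_frac / uni_frac if uni_frac > 0 else np.nan
    return enr, p
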