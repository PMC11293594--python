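"""Weighted co-expression modules: bicor, spqn, TOM, tree cut, eigengenes.

Pipeline: regress the top expression PCs out of the log-expression matrix
and average repeated samples per individual; compute the biweight
midcorrelation between genes; remove the mean-correlation bias by spatial
quantile normalisation (genes binned by mean expression; every bin-pair's
correlation distribution is quantile-mapped onto a reference bin pair);
raise |cor| to a soft power chosen for approximate scale-free topology;
convert adjacency to topological overlap; cluster 1 - TOM by average
linkage with a static height cut; assign small clusters to the unassigned
module 0; summarise each module by its eigengene (first principal
component of the standardised member genes) and merge modules whose
eigengenes are nearly collinear.  Modules are annotated against phenotypes
(LMM), 28-day survival (Cox, Efron ties) and marker gene sets
(hypergeometric).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import covariate_matrix
from .lmm import RandomInterceptLM, lrt_nested
from .regdrivers import set_enrichment

__all__ = [
    "preprocess_expression",
    "bicor_matrix",
    "spqn_normalize",
    "build_network",
    "detect_modules",
    "module_eigengenes",
    "module_associations",
    "ModuleSet",
]


@dataclass
class ModuleSet:
    labels: pd.Series  # gene -> module id (0 = unassigned)
    eigengenes: pd.DataFrame  # modules x columns of the clustered data
    var_explained: dict
    params: dict = field(default_factory=dict)

    @property
    def module_ids(self):
        return [m for m in sorted(self.labels.unique()) if m != 0]

    def members(self, module_id):
        return self.labels.index[self.labels == module_id].tolist()

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != 0].value_counts().sort_index()


def preprocess_expression(expr, samples: pd.DataFrame,
                          n_pcs_remove: int = 20) -> pd.DataFrame:
    """Residualise on top expression PCs, then average per individual.

    Returns a genes x individuals matrix (between-individual variation
    only).
    """
    Y = expr.values.loc[:, samples["sample_id"]].to_numpy(dtype=float)
    n_samples = Y.shape[1]
    if n_pcs_remove >= n_samples:
        raise ValueError("n_pcs_remove must be below the sample count")
    if n_pcs_remove > 0:
        Yc = Y - Y.mean(axis=1, keepdims=True)
        U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
        R = Yc - (U[:, :n_pcs_remove] * s[:n_pcs_remove]) @ Vt[:n_pcs_remove]
    else:
        R = Y
    out = pd.DataFrame(R, index=expr.genes, columns=samples["sample_id"])
    ind = samples.set_index("sample_id")["individual_id"]
    return out.T.groupby(ind, sort=False).mean().T


def _bicor_weights(x: np.ndarray):
    """Tukey biweight transform of one gene; None when MAD is zero."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w


def bicor_matrix(data: pd.DataFrame):
    """Biweight midcorrelation between genes (rows); Pearson fallback.

    Genes whose MAD is zero fall back to the Pearson transform and are
    listed in the returned ``fallback``; constant genes are dropped.
    Returns ``(corr DataFrame, fallback list, dropped list)``.
    """
    X = data.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 individuals")
    transformed = np.empty_like(X)
    fallback, dropped, keep = [], [], []
    for i, gene in enumerate(data.index):
        t = _bicor_weights(X[i])
        if t is None:
            if np.std(X[i]) == 0:
                dropped.append(gene)
                continue
            t = X[i] - X[i].mean()  # Pearson fallback, flagged
            fallback.append(gene)
        keep.append(i)
        transformed[i] = t
    T = transformed[keep]
    norms = np.linalg.norm(T, axis=1)
    T = T / norms[:, None]
    C = np.clip(T @ T.T, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    genes = [data.index[i] for i in keep]
    return pd.DataFrame(C, index=genes, columns=genes), fallback, dropped


def spqn_normalize(corr: pd.DataFrame, mean_expr: pd.Series,
                   n_blocks: int = 21, ref_block: int = 18) -> pd.DataFrame:
    """Spatial quantile normalisation of a correlation matrix.

    Genes are ranked by mean expression and split into ``n_blocks``
    contiguous equal-size groups (remainder absorbed by the last); for
    every group pair the off-diagonal correlations are quantile-mapped
    onto the empirical distribution of the (ref, ref) block.  Diagonal
    stays 1; symmetry is preserved by mirroring the upper triangle.
    ``ref_block`` is a 1-based block index.
    """
    if not 1 <= ref_block <= n_blocks:
        raise ValueError("ref_block out of range")
    genes = corr.index
    order = mean_expr.reindex(genes).sort_values(kind="mergesort").index
    C = corr.loc[order, order].to_numpy(dtype=float).copy()
    n = len(order)
    size = n // n_blocks
    if size < 2:
        raise ValueError("too few genes for the requested block count")
    bounds = [(b * size, (b + 1) * size if b < n_blocks - 1 else n)
              for b in range(n_blocks)]
    r0, r1 = bounds[ref_block - 1]
    ref_vals = C[r0:r1, r0:r1][np.triu_indices(r1 - r0, k=1)]
    ref_sorted = np.sort(ref_vals)
    for i in range(n_blocks):
        i0, i1 = bounds[i]
        for j in range(i, n_blocks):
            j0, j1 = bounds[j]
            blk = C[i0:i1, j0:j1]
            if i == j:
                iu = np.triu_indices(i1 - i0, k=1)
                vals = blk[iu]
            else:
                vals = blk.ravel()
            if vals.size == 0:
                continue
            ranks = stats.rankdata(vals, method="average")
            q = (ranks - 0.5) / len(vals)
            mapped = np.quantile(ref_sorted, q, method="linear")
            if i == j:
                blk[iu] = mapped
                blk.T[iu] = mapped
            else:
                C[i0:i1, j0:j1] = mapped.reshape(blk.shape)
                C[j0:j1, i0:i1] = C[i0:i1, j0:j1].T
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    out = pd.DataFrame(C, index=order, columns=order)
    return out.loc[genes, genes]


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log p(k) vs log k over logarithmic connectivity bins."""
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.geomspace(k.min(), k.max() + 1e-9, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    ok = counts > 0
    if ok.sum() < 3:
        return 0.0
    x = np.log10(centers[ok])
    y = np.log10(counts[ok] / counts.sum())
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def build_network(corr: pd.DataFrame, power=None, rsq_target: float = 0.8):
    """Unsigned adjacency |cor|^power and the topological overlap matrix.

    When ``power`` is None the smallest power in 1..20 whose connectivity
    distribution has a scale-free fit R^2 >= ``rsq_target`` is chosen
    (falling back to the best-fitting power with a warning flag).
    Returns ``(adjacency, tom, chosen_power, fit_r2)``.
    """
    A_abs = np.abs(corr.to_numpy(dtype=float))
    np.fill_diagonal(A_abs, 0.0)
    if power is None:
        chosen, best, best_r2 = None, 1, -1.0
        for p in range(1, 21):
            k = (A_abs**p).sum(axis=1)
            r2 = _scale_free_r2(k)
            if r2 > best_r2:
                best, best_r2 = p, r2
            if r2 >= rsq_target:
                chosen = p
                fit = r2
                break
        if chosen is None:
            chosen, fit = best, best_r2
        power = chosen
    else:
        k = (A_abs**power).sum(axis=1)
        fit = _scale_free_r2(k)
    A = A_abs**power
    k = A.sum(axis=1)
    # with a zero diagonal, (A @ A)_ij sums a_iu a_uj over u != i, j exactly
    num = A @ A + A
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    genes = corr.index
    return (
        pd.DataFrame(A, index=genes, columns=genes),
        pd.DataFrame(tom, index=genes, columns=genes),
        int(power),
        float(fit),
    )


def module_eigengenes(data: pd.DataFrame, labels: pd.Series):
    """First-PC eigengene per module from standardised member genes.

    Sign is aligned so the eigengene correlates non-negatively with the
    module's mean standardised profile.  Returns ``(eigengene DataFrame
    modules x columns, variance explained dict)``.
    """
    eig = {}
    varex = {}
    for mod in sorted(labels.unique()):
        if mod == 0:
            continue
        members = labels.index[labels == mod]
        X = data.loc[members].to_numpy(dtype=float)
        sd = X.std(axis=1, ddof=0)
        X = X[sd > 0]  # constant member genes dropped before SVD
        if len(X) < 1:
            continue
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(
            axis=1, ddof=0, keepdims=True
        )
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        e = Vt[0]
        mean_profile = Z.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        eig[mod] = e
        varex[mod] = float(s[0] ** 2 / (s**2).sum())
    E = pd.DataFrame(eig, index=data.columns).T
    E.index.name = "module"
    return E, varex


def detect_modules(
    tom: pd.DataFrame,
    data: pd.DataFrame,
    min_size: int = 10,
    cut_quantile: float = 0.99,
    merge_height: float = 0.1,
) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    The cut height is the midpoint of the widest gap in the sorted merge
    heights (capped at the ``cut_quantile`` quantile): TOM dissimilarities
    between unrelated genes saturate just below 1, so the gap between the
    last within-module merge and the noise plateau locates the natural
    static cut.  Clusters below ``min_size`` become unassigned (module 0);
    modules with eigengene dissimilarity (1 - cor) below ``merge_height``
    are merged until stable; final labels are renumbered by decreasing
    size.
    """
    genes = tom.index
    if len(genes) < min_size:
        return ModuleSet(
            pd.Series(0, index=genes), pd.DataFrame(columns=data.columns), {},
            {"note": "fewer than min_size genes"},
        )
    D = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    h = np.sort(Z[:, 2])
    gi = int(np.argmax(np.diff(h))) if len(h) > 1 else 0
    gap_mid = float((h[gi] + h[min(gi + 1, len(h) - 1)]) / 2.0)
    height = min(gap_mid, float(np.quantile(h, cut_quantile)))
    raw = fcluster(Z, t=height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    counts = labels.value_counts()
    small = counts.index[counts < min_size]
    labels[labels.isin(small)] = 0

    # iterative eigengene merge
    while True:
        mods = [m for m in sorted(labels.unique()) if m != 0]
        if len(mods) < 2:
            break
        E, _ = module_eigengenes(data, labels)
        C = np.corrcoef(E.loc[mods].to_numpy())
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if 1.0 - C[i, j] >= merge_height:
            break
        labels[labels == mods[j]] = mods[i]

    # renumber by decreasing size (ties: lower old label first)
    sizes = labels[labels != 0].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    mapping = {old: new for new, old in enumerate(order, start=1)}
    mapping[0] = 0
    labels = labels.map(mapping)
    E, varex = module_eigengenes(data, labels)
    return ModuleSet(
        labels, E, varex,
        {"min_size": min_size, "cut_height": height,
         "merge_height": merge_height},
    )


def module_associations(
    eigengenes: pd.DataFrame,
    samples: pd.DataFrame,
    marker_sets: dict | None = None,
    labels: pd.Series | None = None,
    universe=None,
    fdr: float = 0.05,
):
    """Annotate module eigengenes against phenotypes, survival and markers.

    ``eigengenes`` must be modules x samples (sample-level scores so the
    repeated-measures LMM applies).  Survival uses each patient's
    last-time-point eigengene in a Cox model with Efron tie handling.
    Returns a dict of tidy tables: ``phenotypes``, ``survival``,
    ``markers``.
    """
    groups = samples["individual_id"].to_numpy()
    phenos = [c for c in ["srs1", "diagnosis_fp", "time_point",
                          "int_neutrophils", "int_lymphocytes",
                          "int_monocytes"] if c in samples]
    recs = []
    for mod in eigengenes.index:
        y = eigengenes.loc[mod, samples["sample_id"]].to_numpy(dtype=float)
        for ph in phenos:
            x = samples[ph].to_numpy(dtype=float)
            X_full = np.column_stack([np.ones(len(x)), x])
            full = RandomInterceptLM(y, X_full, groups).fit()
            null = RandomInterceptLM(y, X_full[:, :1], groups).fit()
            _, p = lrt_nested(full, null, df=1)
            recs.append((mod, ph, float(full.params[1]), float(full.bse[1]), p))
    pheno_tab = pd.DataFrame(
        recs, columns=["module", "phenotype", "effect", "se", "p"]
    )
    if len(pheno_tab):
        _, q, _, _ = multipletests(pheno_tab["p"], method="fdr_bh")
        pheno_tab["q"] = q

    # survival: last time point per patient
    surv_tab = pd.DataFrame(columns=["module", "log_hazard", "se", "p", "q"])
    if {"surv_time", "surv_event"} <= set(samples.columns):
        last = samples.loc[
            samples.groupby("individual_id", sort=False)["time_point"].idxmax()
        ]
        if last["surv_event"].sum() > 0:
            from lifelines import CoxPHFitter

            recs = []
            for mod in eigengenes.index:
                df = pd.DataFrame(
                    {
                        "eigengene": eigengenes.loc[
                            mod, last["sample_id"]
                        ].to_numpy(dtype=float),
                        "time": last["surv_time"].to_numpy(dtype=float),
                        "event": last["surv_event"].to_numpy(dtype=int),
                    }
                )
                cph = CoxPHFitter()
                try:
                    cph.fit(df, duration_col="time", event_col="event")
                    recs.append(
                        (mod, float(cph.params_["eigengene"]),
                         float(cph.standard_errors_["eigengene"]),
                         float(cph.summary.loc["eigengene", "p"]))
                    )
                except Exception:
                    recs.append((mod, np.nan, np.nan, np.nan))
            surv_tab = pd.DataFrame(
                recs, columns=["module", "log_hazard", "se", "p"]
            )
            ok = surv_tab["p"].notna()
            surv_tab["q"] = np.nan
            if ok.any():
                _, q, _, _ = multipletests(surv_tab.loc[ok, "p"],
                                           method="fdr_bh")
                surv_tab.loc[ok, "q"] = q

    marker_tab = pd.DataFrame(columns=["module", "marker_set", "enrichment",
                                       "p", "q"])
    if marker_sets and labels is not None:
        if universe is None:
            universe = set(labels.index)
        recs = []
        for mod in eigengenes.index:
            members = set(labels.index[labels == mod])
            for name, gset in marker_sets.items():
                enr, p = set_enrichment(
                    members, universe, gset, method="hypergeometric"
                )
                recs.append((mod, name, enr, p))
        marker_tab = pd.DataFrame(
            recs, columns=["module", "marker_set", "enrichment", "p"]
        )
        _, q, _, _ = multipletests(marker_tab["p"], method="fdr_bh")
        marker_tab["q"] = q
    return {"phenotypes": pheno_tab, "survival": surv_tab,
            "markers": marker_tab}
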