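"""Empirical-Bayes sharing of eQTL effects between two conditions.

Effect estimates (b1, b2) for the same SNP-gene pair measured in two
cohorts (e.g., sepsis and a reference whole-blood cohort) are modelled as
draws from a mixture of bivariate normal priors scaled over a grid,

    b_hat_j ~ sum_{k,w} pi_{k,w} N(0, w U_k + V_j),   V_j = diag(se_j^2),

with canonical covariance patterns U_k: the null (point mass at zero),
equal effects in both conditions, an effect in condition 1 only, condition
2 only, and optionally a rank-1 data-driven pattern from the strong-set
SVD.  The weights pi are estimated by EM on a "random" subset of tests;
posterior summaries on the "strong" set give per-condition posterior means
and local false sign rates (lfsr), from which each pair significant in
condition 1 is categorised as shared / magnified / dampened / opposite by
the factor-of-2 magnitude band convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SharingModel",
    "SharingPosterior",
    "fit_sharing_model",
    "categorize_sharing",
    "canonical_covariances",
    "default_scale_grid",
]

CATEGORIES = [
    "shared",
    "sepsis_magnified",
    "sepsis_dampened",
    "opposite",
    "not_significant",
]


@dataclass
class SharingModel:
    covariance_components: list  # (name, 2x2 matrix); null first
    scale_grid: np.ndarray
    mixture_weights: np.ndarray  # flat over (component, scale) incl. null once
    component_index: list  # (name, U, omega) per weight slot
    loglik_path: list = field(default_factory=list)
    converged: bool = False

    def weight_by_component(self) -> pd.Series:
        agg: dict = {}
        for w, (name, _, _) in zip(self.mixture_weights, self.component_index):
            agg[name] = agg.get(name, 0.0) + float(w)
        return pd.Series(agg)


@dataclass
class SharingPosterior:
    pair_id: object
    post_mean: np.ndarray  # (b1~, b2~)
    lfsr: np.ndarray
    category: str


def canonical_covariances(data_driven: np.ndarray | None = None):
    comps = [
        ("null", np.zeros((2, 2))),
        ("equal", np.ones((2, 2))),
        ("cond1_only", np.array([[1.0, 0.0], [0.0, 0.0]])),
        ("cond2_only", np.array([[0.0, 0.0], [0.0, 1.0]])),
        # full-rank pattern: effects present in both conditions but free to
        # differ (incl. opposite signs); without it the mixture cannot
        # explain discordant pairs and the no-shrinkage limit fails
        ("independent", np.eye(2)),
    ]
    if data_driven is not None:
        U = np.asarray(data_driven, dtype=float)
        U = U / max(np.max(np.abs(U)), 1e-12)
        comps.append(("data_rank1", U))
    return comps


def default_scale_grid(betas, ses, n_grid: int = 10) -> np.ndarray:
    """Logarithmic grid of prior scales spanning the data's effect range."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    lo = max(float(np.min(ses)) ** 2 / 10.0, 1e-6)
    hi = max(float(np.max(betas**2)) * 2.0, lo * 10.0)
    return np.geomspace(lo, hi, n_grid)


def _component_list(comps, grid):
    idx = [("null", np.zeros((2, 2)), 0.0)]
    for name, U in comps:
        if name == "null":
            continue
        for w in grid:
            idx.append((name, U, float(w)))
    return idx


def _loglik_matrix(B, V, index):
    """log N(b_j; 0, wU + V_j) for every pair j and component slot c."""
    n = len(B)
    L = np.empty((n, len(index)))
    for c, (_, U, w) in enumerate(index):
        S = w * U  # prior covariance
        a = S[0, 0] + V[:, 0]
        d = S[1, 1] + V[:, 1]
        b = np.full(n, S[0, 1])
        det = a * d - b * b
        det = np.maximum(det, 1e-300)
        q = (d * B[:, 0] ** 2 - 2 * b * B[:, 0] * B[:, 1] + a * B[:, 1] ** 2) / det
        L[:, c] = -0.5 * (np.log(det) + q) - np.log(2 * np.pi)
    return L


def fit_sharing_model(
    random_betas,
    random_ses,
    grid: np.ndarray | None = None,
    data_driven: np.ndarray | None = None,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SharingModel:
    """EM over mixture weights on the 'random' test subset."""
    B = np.asarray(random_betas, dtype=float)
    S = np.asarray(random_ses, dtype=float)
    if B.shape != S.shape or B.ndim != 2 or B.shape[1] != 2:
        raise ValueError("betas and ses must both be n x 2")
    if len(B) < 100:
        raise ValueError("need at least 100 random tests to fit the model")
    if np.any(S <= 0):
        raise ValueError("standard errors must be positive")
    if grid is None:
        grid = default_scale_grid(B, S)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("degenerate scale grid")
    comps = canonical_covariances(data_driven)
    index = _component_list(comps, grid)
    V = S**2
    L = _loglik_matrix(B, V, index)
    K = len(index)
    pi = np.full(K, 1.0 / K)
    path = []
    converged = False
    for _ in range(max_iter):
        logw = L + np.log(np.maximum(pi, 1e-300))
        m = logw.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logw - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logw - lse[:, None])
        pi = resp.mean(axis=0)
        if path and abs(ll - path[-1]) <= tol * abs(path[-1]):
            path.append(ll)
            converged = True
            break
        path.append(ll)
    return SharingModel(
        covariance_components=comps,
        scale_grid=grid,
        mixture_weights=pi,
        component_index=index,
        loglik_path=path,
        converged=converged,
    )


def _posterior(b, v, model: SharingModel):
    """Posterior mixture for one pair: weights, means, sds, zero mass."""
    V = np.diag(v)
    logw = []
    means = []
    sds = []
    for pi_c, (_, U, w) in zip(model.mixture_weights, model.component_index):
        S = w * U
        C = S + V
        det = C[0, 0] * C[1, 1] - C[0, 1] ** 2
        det = max(det, 1e-300)
        Cinv = np.array([[C[1, 1], -C[0, 1]], [-C[0, 1], C[0, 0]]]) / det
        q = b @ Cinv @ b
        logw.append(np.log(max(pi_c, 1e-300)) - 0.5 * (np.log(det) + q)
                    - np.log(2 * np.pi))
        # posterior of true effect: N(S C^-1 b, S - S C^-1 S)
        G = S @ Cinv
        mu = G @ b
        P = S - G @ S
        means.append(mu)
        sds.append(np.sqrt(np.maximum(np.diag(P), 0.0)))
    logw = np.asarray(logw)
    logw -= logw.max()
    wts = np.exp(logw)
    wts /= wts.sum()
    return wts, np.asarray(means), np.asarray(sds)


def posterior_summaries(betas, ses, model: SharingModel, pair_ids=None):
    """Posterior means and lfsr per condition for each pair.

    lfsr is the smaller of the posterior probabilities of a non-negative /
    non-positive true effect, with point mass at zero counted in both.
    """
    B = np.asarray(betas, dtype=float)
    S = np.asarray(ses, dtype=float)
    if pair_ids is None:
        pair_ids = list(range(len(B)))
    out_mean = np.empty_like(B)
    out_lfsr = np.empty_like(B)
    for j in range(len(B)):
        wts, means, sds = _posterior(B[j], S[j] ** 2, model)
        for d in range(2):
            mu, sd = means[:, d], sds[:, d]
            point = sd <= 1e-12
            p_zero = float(wts[point & (np.abs(mu) <= 1e-12)].sum())
            cont = ~point
            p_neg = float((wts[cont] * norm.cdf(0.0, mu[cont], sd[cont])).sum())
            p_neg += float(wts[point & (mu < -1e-12)].sum())
            p_pos = 1.0 - p_neg - p_zero
            out_mean[j, d] = float((wts * mu).sum())
            out_lfsr[j, d] = min(p_neg + p_zero, p_pos + p_zero)
    return pair_ids, out_mean, out_lfsr


def categorize_sharing(
    strong_betas,
    strong_ses,
    model: SharingModel,
    pair_ids=None,
    lfsr_cut: float = 0.05,
    factor: float = 2.0,
    rule: str = "ratio",
) -> list:
    """Categorise pairs significant in condition 1 against condition 2.

    ``rule='ratio'`` (default): shared when same sign and the magnitude
    ratio lies in [1/factor, factor]; ``rule='difference'``: shared when
    |b1 - b2| <= 0.5 |b2|.  Pairs significant in both conditions with
    opposite posterior signs are 'opposite'; significant only in condition
    1, or same-sign with a larger magnitude, are 'sepsis_magnified';
    remaining significant pairs are 'sepsis_dampened'.
    """
    ids, mean, lfsr = posterior_summaries(strong_betas, strong_ses, model, pair_ids)
    out = []
    for j, pid in enumerate(ids):
        b1, b2 = mean[j]
        sig1 = lfsr[j, 0] < lfsr_cut
        sig2 = lfsr[j, 1] < lfsr_cut
        if not sig1:
            cat = "not_significant"
        elif sig2 and np.sign(b1) != np.sign(b2) and b2 != 0:
            cat = "opposite"
        elif not sig2:
            cat = "sepsis_magnified"
        else:
            if rule == "ratio":
                ratio = abs(b1) / max(abs(b2), 1e-300)
                if 1.0 / factor <= ratio <= factor:
                    cat = "shared"
                elif ratio > factor:
                    cat = "sepsis_magnified"
                else:
                    cat = "sepsis_dampened"
            elif rule == "difference":
                if abs(b1 - b2) <= 0.5 * abs(b2):
                    cat = "shared"
                elif abs(b1) > abs(b2):
                    cat = "sepsis_magnified"
                else:
                    cat = "sepsis_dampened"
            else:
                raise ValueError("rule must be 'ratio' or 'difference'")
        out.append(SharingPosterior(pid, mean[j].copy(), lfsr[j].copy(), cat))
    return out


def sharing_table(posteriors) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair": p.pair_id,
                "post_mean_1": p.post_mean[0],
                "post_mean_2": p.post_mean[1],
                "lfsr_1": p.lfsr[0],
                "lfsr_2": p.lfsr[1],
                "category": p.category,
            }
            for p in posteriors
        ]
    )
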