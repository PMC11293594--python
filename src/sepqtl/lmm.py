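"""Random-intercept linear mixed model with profiled maximum likelihood.

The repeated-measures engine shared by every association stage: a Gaussian
linear model with one random intercept per individual,

    y = X beta + Z u + e,   u_i ~ N(0, s2_u),   e ~ N(0, s2_e I),

fitted by full maximum likelihood (ML, not REML) so that likelihood-ratio
tests between nested fixed-effect specifications are valid.  The covariance
V = s2_e (I + lambda Z Z') with lambda = s2_u / s2_e is block diagonal by
individual, so the likelihood is profiled down to a one-dimensional
optimisation over lambda: for fixed lambda the GLS solution follows from
quasi-demeaning each individual's rows,

    x~ = x - (theta_g / m_g) * sum_g(x),   theta_g = 1 - (1 + lambda m_g)^{-1/2},

after which beta is least squares on the transformed data and
s2_e = RSS / n.  The boundary lambda = 0 (no individual variance) is
allowed and reduces exactly to OLS.

Implementation note: all per-lambda quantities are assembled from fixed
cross-product matrices.  Writing W = [X, y], the transformed Gram matrix is

    M(lambda) = W'W - sum_u c_u(lambda) B_u,    c_u = (2 theta_u - theta_u^2)/u,

where B_u sums s_g s_g' over groups of size u (s_g = within-group column
sums).  Group sizes take very few distinct values in a serial-sampling
cohort, so each likelihood evaluation costs O(p^2) regardless of n, and
:class:`ProfiledScan` reuses the covariate block across thousands of
candidate SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

__all__ = ["RandomInterceptLM", "ProfiledScan", "LmmFit", "fit_lmm", "lrt_nested"]

_LOG_2PI = np.log(2.0 * np.pi)


class DesignError(ValueError):
    """Raised for rank-deficient or mismatched design input."""


@dataclass
class LmmFit:
    """Result of a random-intercept ML fit.

    ``params``/``bse`` are indexed like the supplied design; columns dropped
    for collinearity carry NaN.  ``sigma2_u``/``sigma2_e`` are the ML
    variance components and ``llf`` the maximised log-likelihood.
    """

    params: np.ndarray
    bse: np.ndarray
    sigma2_u: float
    sigma2_e: float
    llf: float
    converged: bool
    n_obs: int
    n_groups: int
    xnames: list = field(default_factory=list)
    dropped: list = field(default_factory=list)
    _group_key: int = 0

    @property
    def lam(self) -> float:
        return self.sigma2_u / self.sigma2_e if self.sigma2_e > 0 else 0.0

    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    def summary(self) -> str:
        lines = [
            "Random-intercept LMM (ML)",
            f"  n_obs={self.n_obs}  n_groups={self.n_groups}  "
            f"llf={self.llf:.4f}  converged={self.converged}",
            f"  sigma2_u={self.sigma2_u:.6g}  sigma2_e={self.sigma2_e:.6g}",
            f"  {'term':<20}{'coef':>12}{'se':>12}{'z':>9}",
        ]
        for i, name in enumerate(self.xnames):
            b, s = self.params[i], self.bse[i]
            if np.isnan(b):
                lines.append(f"  {name:<20}{'dropped':>12}")
            else:
                lines.append(f"  {name:<20}{b:>12.5f}{s:>12.5f}{b / s:>9.3f}")
        return "\n".join(lines)


def _order_by_group(groups):
    _, codes = np.unique(groups, return_inverse=True)
    order = np.argsort(codes, kind="stable")
    codes = codes[order]
    sizes = np.bincount(codes)
    starts = np.concatenate(([0], np.cumsum(sizes)))[:-1]
    return order, codes, sizes, starts


def _independent_columns(X, tol=1e-9):
    """Left-to-right rank selection via unpivoted QR (leftmost kept)."""
    keep = list(range(X.shape[1]))
    while True:
        R = np.linalg.qr(X[:, keep], mode="r")
        diag = np.abs(np.diag(R))
        norms = np.linalg.norm(X[:, keep], axis=0)
        bad = np.where(diag <= tol * np.maximum(norms, 1.0))[0]
        if len(bad) == 0:
            return keep
        del keep[bad[0]]
        if not keep:
            raise DesignError("design matrix has no independent columns")


class _ProfiledCore:
    """Cross-product machinery shared by the model and the scanner."""

    def __init__(self, y, X, groups):
        y = np.asarray(y, dtype=float).ravel()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not (len(y) == len(X) == len(groups)):
            raise DesignError("y, X and groups must have matching rows")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
            raise DesignError("non-finite values in y or X")
        order, codes, sizes, starts = _order_by_group(np.asarray(groups))
        self.order = order
        self.codes = codes
        self.sizes = sizes
        self.starts = starts
        self.n_obs = len(y)
        self.n_groups = len(sizes)
        self.y = y[order]
        self.X = X[order]
        self.usizes = np.unique(sizes)
        self._group_key = hash(
            (self.n_obs, self.n_groups, sizes.tobytes(), self.y.tobytes())
        )

    def build(self, W):
        """A = W'W and per-group-size outer-product sums B_u."""
        A = W.T @ W
        S = np.add.reduceat(W, self.starts, axis=0)  # group sums, G x q
        Bs = {}
        Ss = {}
        for u in self.usizes:
            Su = S[self.sizes == u]
            Ss[u] = Su
            Bs[u] = Su.T @ Su
        return A, Bs, Ss

    def _c(self, lam):
        c = {}
        for u in self.usizes:
            theta = 1.0 - 1.0 / np.sqrt(1.0 + lam * u)
            c[u] = (2.0 * theta - theta * theta) / u
        return c

    def loglik(self, lam, A, Bs):
        """Profiled ML log-likelihood; also returns beta, s2_e, Mxx factor."""
        M = A.copy()
        for u, cu in self._c(lam).items():
            if cu != 0.0:
                M -= cu * Bs[u]
        q = M.shape[0] - 1
        Mxx = M[:q, :q]
        Mxy = M[:q, q]
        Myy = M[q, q]
        try:
            cf = linalg.cho_factor(Mxx, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        beta = linalg.cho_solve(cf, Mxy, check_finite=False)
        rss = max(float(Myy - Mxy @ beta), 1e-300)
        n = self.n_obs
        logdet = float(
            sum(np.log1p(lam * u) * np.count_nonzero(self.sizes == u)
                for u in self.usizes)
        )
        llf = -0.5 * (n * (_LOG_2PI + np.log(rss / n) + 1.0) + logdet)
        return llf, beta, rss / n, cf

    def optimize(self, A, Bs, bounds=(-8.0, 6.0), xatol=1e-5):
        """Maximise over log10(lambda), comparing with the lambda=0 boundary."""
        res0 = self.loglik(0.0, A, Bs)
        if res0 is None:
            raise DesignError("rank-deficient design in profiled fit")
        if np.all(self.sizes == 1):
            # one sample per individual: s2_u unidentifiable, pinned to 0
            return 0.0, res0, True
        def neg(t):
            out = self.loglik(10.0 ** t, A, Bs)
            return 1e300 if out is None else -out[0]  # finite: Brent-safe
        opt = optimize.minimize_scalar(
            neg, bounds=bounds, method="bounded", options={"xatol": xatol}
        )
        lam = 10.0 ** opt.x
        if not np.isfinite(opt.fun) or res0[0] >= -opt.fun or opt.x <= bounds[0] + 1e-6:
            return 0.0, res0, bool(opt.success)
        return lam, self.loglik(lam, A, Bs), bool(opt.success)


class RandomInterceptLM:
    """Model object for ``y = X beta + u[group] + e``.

    Parameters
    ----------
    y : array (n,)
        Response.
    X : array (n, p)
        Fixed-effects design (include an intercept column explicitly).
    groups : array (n,)
        Individual labels; repeated labels share a random intercept.
    xnames : optional list of column names for ``summary()``.
    """

    def __init__(self, y, X, groups, xnames=None):
        self.core = _ProfiledCore(y, X, groups)
        p = self.core.X.shape[1]
        self.xnames = list(xnames) if xnames is not None else [
            f"x{i}" for i in range(p)
        ]
        self._keep = _independent_columns(self.core.X)
        W = np.column_stack([self.core.X[:, self._keep], self.core.y])
        self._A, self._Bs, _ = self.core.build(W)

    @property
    def n_obs(self):
        return self.core.n_obs

    @property
    def n_groups(self):
        return self.core.n_groups

    def fit(self) -> LmmFit:
        lam, (llf, beta, s2e, cf), converged = self.core.optimize(self._A, self._Bs)
        cov = s2e * linalg.cho_solve(
            cf, np.eye(len(beta)), check_finite=False
        )
        p_all = self.core.X.shape[1]
        params = np.full(p_all, np.nan)
        bse = np.full(p_all, np.nan)
        params[self._keep] = beta
        bse[self._keep] = np.sqrt(np.maximum(np.diag(cov), 0.0))
        if s2e <= 1e-12:
            converged = False  # degenerate: zero residual variance, flagged
        return LmmFit(
            params=params,
            bse=bse,
            sigma2_u=lam * s2e,
            sigma2_e=s2e,
            llf=llf,
            converged=converged,
            n_obs=self.core.n_obs,
            n_groups=self.core.n_groups,
            xnames=self.xnames,
            dropped=[self.xnames[j] for j in range(p_all) if j not in self._keep],
            _group_key=self.core._group_key,
        )


class ProfiledScan:
    """Amortised 1-df LRT scan: X0 (null) versus X0 plus one extra column.

    The covariate cross products are computed once; each candidate column
    only contributes its own cross terms, so scanning thousands of SNPs for
    the same response is cheap.  ``scan`` returns beta, se and the LRT p
    for each candidate against the shared null fit.
    """

    def __init__(self, y, X0, groups):
        self.core = _ProfiledCore(y, X0, groups)
        self._keep = _independent_columns(self.core.X)
        self.X0 = self.core.X[:, self._keep]
        self.p0 = self.X0.shape[1]
        W0 = np.column_stack([self.X0, self.core.y])
        self.A0, self.B0s, self.S0s = self.core.build(W0)
        # null fit (no extra column): strip the would-be g slot
        self.null_lam, (self.null_llf, self.null_beta, self.null_s2, _), self.null_ok = (
            self.core.optimize(self.A0, self.B0s)
        )

    def _augment(self, g):
        """Insert column g between X0 and y in A and B_u."""
        g = np.asarray(g, dtype=float)[self.core.order]
        p0 = self.p0
        q = p0 + 2  # X0 cols, g, y
        gW0 = np.concatenate([self.X0.T @ g, [g @ self.core.y]])  # vs [X0, y]
        A = np.empty((q, q))
        A[:p0, :p0] = self.A0[:p0, :p0]
        A[:p0, q - 1] = self.A0[:p0, p0]
        A[q - 1, :p0] = self.A0[p0, :p0]
        A[q - 1, q - 1] = self.A0[p0, p0]
        A[p0, :p0] = gW0[:p0]
        A[:p0, p0] = gW0[:p0]
        A[p0, q - 1] = gW0[p0]
        A[q - 1, p0] = gW0[p0]
        A[p0, p0] = g @ g
        sg = np.add.reduceat(g, self.core.starts)
        Bs = {}
        for u in self.core.usizes:
            mask = self.core.sizes == u
            su = sg[mask]
            cross = su @ self.S0s[u]  # length p0+1, order [X0, y]
            B = np.empty((q, q))
            B0 = self.B0s[u]
            B[:p0, :p0] = B0[:p0, :p0]
            B[:p0, q - 1] = B0[:p0, p0]
            B[q - 1, :p0] = B0[p0, :p0]
            B[q - 1, q - 1] = B0[p0, p0]
            B[p0, :p0] = cross[:p0]
            B[:p0, p0] = cross[:p0]
            B[p0, q - 1] = cross[p0]
            B[q - 1, p0] = cross[p0]
            B[p0, p0] = su @ su
            Bs[u] = B
        return A, Bs

    def fit_extra(self, g):
        """Fit the full model with one extra column; returns (beta, se, llf)
        for that column or ``None`` when it is collinear with X0."""
        A, Bs = self._augment(g)
        try:
            lam, out, ok = self.core.optimize(A, Bs)
        except DesignError:
            return None
        llf, beta, s2e, cf = out
        cov = s2e * linalg.cho_solve(cf, np.eye(len(beta)), check_finite=False)
        var = cov[self.p0, self.p0]
        if var <= 0 or not np.isfinite(var):
            return None
        return float(beta[self.p0]), float(np.sqrt(var)), float(llf)

    def scan(self, columns, names=None):
        """LRT each column in ``columns`` (n x k) against the shared null.

        Returns a list of dicts with beta, se, p, llf (NaN/p=1 for
        collinear columns).
        """
        columns = np.asarray(columns, dtype=float)
        if columns.ndim == 1:
            columns = columns[:, None]
        out = []
        for j in range(columns.shape[1]):
            res = self.fit_extra(columns[:, j])
            name = names[j] if names is not None else j
            if res is None:
                out.append({"name": name, "beta": np.nan, "se": np.nan,
                            "p": 1.0, "llf": np.nan})
                continue
            beta, se, llf = res
            stat = max(0.0, 2.0 * (llf - self.null_llf))
            p = float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
            out.append({"name": name, "beta": beta, "se": se,
                        "p": max(p, 1e-300), "llf": llf})
        return out


def fit_lmm(y, X, groups, xnames=None) -> LmmFit:
    """Convenience wrapper: build the model and fit in one call."""
    return RandomInterceptLM(y, X, groups, xnames=xnames).fit()


def lrt_nested(full: LmmFit, null: LmmFit, df: int):
    """Likelihood-ratio test of nested ML fits on identical data.

    Returns ``(statistic, p)`` with the statistic clipped at zero and the
    p-value from the upper tail of chi-square with ``df`` degrees of
    freedom.
    """
    if full.n_obs != null.n_obs or full.n_groups != null.n_groups:
        raise DesignError("LRT requires identical observations and grouping")
    if full._group_key != null._group_key:
        raise DesignError("LRT fits were made on different responses")
    stat = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, max(p, 1e-300)
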