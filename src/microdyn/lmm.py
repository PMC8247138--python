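"""Random-intercept linear mixed models with REML estimation and
Satterthwaite degrees of freedom.

This is the inference engine behind the temporal segmentation (per-segment
slope tests), the alpha-diversity trend, and the network edge-count models:

    y = X b + Z u + e,   u ~ N(0, sigma_u^2 I),   e ~ N(0, sigma_e^2 I)

with Z the subject (group) indicator.  The variance ratio
gamma = sigma_u^2 / sigma_e^2 is profiled out, leaving a one-dimensional
REML criterion minimised by bounded search; fixed effects follow by GLS.
Satterthwaite's approximation gives generally fractional degrees of freedom
for each fixed-effect t-test via the delta method: the gradient of
Var(b_j) with respect to the variance components is taken numerically and
combined with the asymptotic covariance of the variance-component estimates
(inverse REML information, also numerical).

All computations run on per-group sufficient statistics, so a fit on a few
hundred observations costs microseconds -- the genetic-algorithm fitness
function depends on this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import ValidationError


class ConvergenceError(RuntimeError):
    """REML optimisation failed to produce finite estimates."""


@dataclass
class MixedModelFit:
    """Fixed-effect table plus variance components of a random-intercept fit.

    ``params`` has one row per fixed effect: term, b, SE, t, df, p.
    """

    params: pd.DataFrame
    sigma_u2: float
    sigma_e2: float
    reml_loglik: float
    n_obs: int
    n_groups: int
    rmse: float
    method: str = "reml"
    fitted: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.sigma_u2 < 0 or self.sigma_e2 < 0:
            raise ValidationError("variance components must be non-negative")

    def coef(self, term: str) -> pd.Series:
        return self.params.set_index("term").loc[term]

    @property
    def slope(self) -> float:
        """Convenience accessor for the 'day' (or second) coefficient."""
        terms = list(self.params["term"])
        name = "day" if "day" in terms else terms[-1]
        return float(self.coef(name)["b"])

    def to_frame(self) -> pd.DataFrame:
        return self.params.copy()


# ---------------------------------------------------------------------------
# sufficient statistics and the REML criterion
# ---------------------------------------------------------------------------

class _Suff:
    """Per-group sufficient statistics for the random-intercept model."""

    def __init__(self, y, X, groups):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if len(y) != X.shape[0]:
            raise ValidationError("y and X length mismatch")
        codes, uniques = pd.factorize(np.asarray(groups))
        self.n, self.p = X.shape
        self.k = len(uniques)
        self.group_names = list(uniques)
        if np.linalg.matrix_rank(X) < self.p:
            raise ValidationError("fixed-effect design is singular")
        self.X, self.y, self.codes = X, y, codes
        self.n_i = np.bincount(codes, minlength=self.k).astype(float)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # group sums of rows of X and of y
        self.Sx = np.zeros((self.k, self.p))
        for j in range(self.p):
            self.Sx[:, j] = np.bincount(codes, weights=X[:, j], minlength=self.k)
        self.Sy = np.bincount(codes, weights=y, minlength=self.k)

    def gls(self, gamma: float):
        """GLS pieces at variance ratio gamma (scaled so sigma_e^2 = 1)."""
        c = gamma / (1.0 + gamma * self.n_i)          # per-group shrinkage
        A = self.XtX - (self.Sx * c[:, None]).T @ self.Sx   # X' W X
        u = self.Xty - self.Sx.T @ (c * self.Sy)            # X' W y
        q = self.yty - float(c @ self.Sy**2)                # y' W y
        b = np.linalg.solve(A, u)
        rwr = q - float(b @ u)                              # r' W r
        return A, u, q, b, max(rwr, 1e-300)


def profiled_reml_criterion(suff: _Suff, gamma: float) -> float:
    """-2 x profiled REML log-likelihood (up to an additive constant) as a
    function of the variance ratio gamma = sigma_u^2 / sigma_e^2."""
    A, _, _, _, rwr = suff.gls(gamma)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    return ((suff.n - suff.p) * np.log(rwr)
            + float(np.sum(np.log1p(gamma * suff.n_i)))
            + logdetA)


def _minus2_reml(suff: _Suff, su2: float, se2: float) -> float:
    """-2 x REML log-likelihood at explicit variance components (with
    constants, for numerical information matrices)."""
    if se2 <= 0 or su2 < 0:
        return np.inf
    gamma = su2 / se2
    A, u, q, b, rwr = suff.gls(gamma)
    A = A / se2
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    logdetV = suff.n * np.log(se2) + float(np.sum(np.log1p(gamma * suff.n_i)))
    yPy = (q - float(b @ u)) / se2
    return logdetV + logdetA + yPy + (suff.n - suff.p) * np.log(2 * np.pi)


def _var_beta(suff: _Suff, su2: float, se2: float) -> np.ndarray:
    gamma = su2 / se2
    A, *_ = suff.gls(gamma)
    return np.linalg.inv(A / se2)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_lmm(y, X, groups, term_names=None) -> MixedModelFit:
    """REML fit of a Gaussian random-intercept model.

    Parameters
    ----------
    y : (n,) response values
    X : (n, p) fixed-effect design (include the intercept column yourself)
    groups : (n,) grouping labels (the random-intercept factor, e.g. subject)
    term_names : optional names for the p fixed effects
    """
    suff = _Suff(y, X, groups)
    if suff.k < 2:
        raise ValidationError("random intercept needs at least 2 groups")
    if np.all(suff.n_i <= 1):
        raise ValidationError(
            "one observation per group: random intercept is unidentifiable")
    # profile the variance ratio on a log grid, refine with Brent
    grid = np.concatenate([[0.0], np.logspace(-4, 4, 33)])
    crit = np.array([profiled_reml_criterion(suff, g) for g in grid])
    i = int(np.argmin(crit))
    if i == 0:
        gamma_hat = 0.0
        # check that zero really is a local minimum vs. a tiny positive ratio
        res = optimize.minimize_scalar(
            lambda lg: profiled_reml_criterion(suff, np.exp(lg)),
            bounds=(np.log(1e-8), np.log(grid[1])), method="bounded")
        if res.fun < crit[0]:
            gamma_hat = float(np.exp(res.x))
    else:
        lo = grid[max(i - 1, 1)] if i > 1 else 1e-8
        hi = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda lg: profiled_reml_criterion(suff, np.exp(lg)),
            bounds=(np.log(lo), np.log(hi)), method="bounded")
        gamma_hat = float(np.exp(res.x))
        if profiled_reml_criterion(suff, 0.0) < res.fun:
            gamma_hat = 0.0

    A, u, q, b, rwr = suff.gls(gamma_hat)
    se2 = rwr / (suff.n - suff.p)
    su2 = gamma_hat * se2
    if not (np.isfinite(se2) and np.isfinite(su2) and se2 > 0):
        raise ConvergenceError(f"non-finite variance estimates (se2={se2}, su2={su2})")
    vb = np.linalg.inv(A) * se2
    se = np.sqrt(np.diag(vb))
    tval = b / se
    df = _satterthwaite_df(suff, su2, se2, se)
    pval = 2 * stats.t.sf(np.abs(tval), df)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    if term_names is None:
        term_names = [f"x{j}" for j in range(suff.p)]
    params = pd.DataFrame({"term": list(term_names), "b": b, "SE": se,
                           "t": tval, "df": df, "p": pval})

    # conditional residuals (BLUP-adjusted) for the RMSE used as GA fitness
    resid = suff.y - suff.X @ b
    shrink = su2 / (se2 + su2 * suff.n_i)
    u_hat = shrink * np.bincount(suff.codes, weights=resid, minlength=suff.k)
    cond = resid - u_hat[suff.codes]
    rmse = float(np.sqrt(np.mean(cond**2)))
    loglik = -0.5 * _minus2_reml(suff, su2, se2)
    return MixedModelFit(params=params, sigma_u2=float(su2), sigma_e2=float(se2),
                         reml_loglik=float(loglik), n_obs=suff.n, n_groups=suff.k,
                         rmse=rmse, method="reml",
                         fitted=suff.X @ b + u_hat[suff.codes])


def _satterthwaite_df(suff: _Suff, su2: float, se2: float, se: np.ndarray) -> np.ndarray:
    """Satterthwaite df per fixed effect: df_j = 2 Var(b_j)^2 / (g' A g) with
    g the numerical gradient of Var(b_j) w.r.t. (sigma_u^2, sigma_e^2) and A
    the asymptotic covariance of the variance components."""
    theta = np.array([su2, se2])
    h = np.maximum(np.abs(theta) * 1e-4, 1e-8)
    fallback = np.full(suff.p, float(suff.n - suff.p))

    def vb_diag(t):
        return np.diag(_var_beta(suff, max(t[0], 0.0), t[1]))

    grads = np.empty((suff.p, 2))
    for m in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[m] += h[m]
        tm[m] -= h[m]
        if tm[0] < 0:
            tm[0] = 0.0  # one-sided at the boundary
        grads[:, m] = (vb_diag(tp) - vb_diag(tm)) / (tp[m] - tm[m])

    # numerical Hessian of -2 log L_REML
    H = np.empty((2, 2))
    hh = np.maximum(np.abs(theta) * 1e-3, 1e-6)
    shift = np.maximum(0.0, hh[0] - theta[0])  # keep su2 probes non-negative
    base = theta + np.array([shift, 0.0])
    with np.errstate(invalid="ignore"):
        for a in range(2):
            for c in range(a, 2):
                ea = np.eye(2)[a] * hh[a]
                ec = np.eye(2)[c] * hh[c]
                f = _minus2_reml
                H[a, c] = H[c, a] = (
                    f(suff, *(base + ea + ec)) - f(suff, *(base + ea - ec))
                    - f(suff, *(base - ea + ec)) + f(suff, *(base - ea - ec))
                ) / (4 * hh[a] * hh[c])
    if not np.all(np.isfinite(H)):
        return fallback
    try:
        acov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return fallback
    denom = np.einsum("jm,mn,jn->j", grads, acov, grads)
    var_b = se**2
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * var_b**2 / denom
    df = np.where(np.isfinite(df) & (df > 0), df, fallback)
    # df cannot reasonably exceed the residual df of the fixed-effect model
    return np.minimum(df, suff.n - suff.p)


def fit_ols(y, X, term_names=None) -> MixedModelFit:
    """Ordinary least squares wrapped in the same result type (used for the
    between-subjects series, which has one point per day and no grouping)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p:
        raise ValidationError("too few observations for OLS")
    if np.linalg.matrix_rank(X) < p:
        raise ValidationError("fixed-effect design is singular")
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    df = n - p
    se2 = float(resid @ resid) / df
    vb = se2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(vb))
    tval = b / se
    pval = 2 * stats.t.sf(np.abs(tval), df)
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]
    params = pd.DataFrame({"term": list(term_names), "b": b, "SE": se, "t": tval,
                           "df": float(df), "p": pval})
    return MixedModelFit(params=params, sigma_u2=0.0, sigma_e2=se2,
                         reml_loglik=np.nan, n_obs=n, n_groups=0,
                         rmse=float(np.sqrt(np.mean(resid**2))), method="ols",
                         fitted=X @ b)


def fit_alpha_trend(values, days, subjects) -> MixedModelFit:
    """Alpha-diversity trend: value ~ 1 + day with subject random intercept."""
    days = np.asarray(days, dtype=float)
    X = np.column_stack([np.ones_like(days), days])
    return fit_lmm(values, X, subjects, term_names=["intercept", "day"])
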