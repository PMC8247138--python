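"""Ordination and permutational statistics on distance matrices.

* :func:`nmds` -- Kruskal non-metric multidimensional scaling by iterative
  majorisation (SMACOF) with monotone (isotonic) regression of the fitted
  on the observed distances, best configuration over many random starts.
* :func:`permanova` -- sequential (Type I) permutational multivariate ANOVA
  on a distance matrix with several ordered factors, via projection hat
  matrices on the Gower-centred inner-product matrix.
* :func:`betadisper` -- multivariate homogeneity of group dispersions:
  principal-coordinate embedding with negative-eigenvalue correction,
  distances to group spatial medians, one-way F test.
* :func:`anova_oneway`, :func:`bh_adjust` -- classical one-way ANOVA and
  Benjamini-Hochberg step-up correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

from .io import ValidationError, stage_rng
from .diversity import DistanceMatrix


# ---------------------------------------------------------------------------
# non-metric multidimensional scaling
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: np.ndarray   # samples x k
    stress: float             # Kruskal stress-1 of the best start
    n_starts: int
    converged: bool
    stress_trace: list[float]  # per-iteration stress of the best start
    labels: list[str] | None = None


def _stress1(d_fit: np.ndarray, d_hat: np.ndarray) -> float:
    return float(np.sqrt(np.sum((d_fit - d_hat) ** 2) / np.sum(d_fit**2)))


def _smacof_single(D: np.ndarray, k: int, rng, maxit: int, tol: float):
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    dobs = D[iu]
    order = np.argsort(dobs, kind="stable")
    iso = IsotonicRegression(increasing=True)
    X = rng.normal(size=(n, k))
    trace = []
    prev = np.inf
    converged = False
    for _ in range(maxit):
        diff = X[:, None, :] - X[None, :, :]
        dx = np.sqrt((diff**2).sum(-1))
        dfit = dx[iu]
        # monotone regression of configuration distances on dissimilarity rank
        dhat = np.empty_like(dfit)
        dhat[order] = iso.fit_transform(np.arange(len(order)), dfit[order])
        s = _stress1(dfit, dhat)
        trace.append(s)
        if prev - s < tol:
            converged = True
            break
        prev = s
        # Guttman transform toward the disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.zeros_like(dx)
            full_dhat = np.zeros_like(dx)
            full_dhat[iu] = dhat
            full_dhat += full_dhat.T
            np.divide(full_dhat, dx, out=ratio, where=dx > 0)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = (B @ X) / n
        X -= X.mean(axis=0)
    return X, trace, converged


def nmds(d: DistanceMatrix, k: int = 2, n_starts: int = 300, seed: int = 0,
         maxit: int = 200, tol: float = 1e-7) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1, best of ``n_starts``
    random initialisations."""
    D = d.values
    n = D.shape[0]
    if k >= n:
        raise ValidationError("embedding dimension must be below the sample count")
    if k < 1:
        raise ValidationError("k must be >= 1")
    rng = stage_rng(seed, "nmds")
    best = None
    for _ in range(n_starts):
        X, trace, conv = _smacof_single(D, k, rng, maxit, tol)
        if best is None or trace[-1] < best[1][-1]:
            best = (X, trace, conv)
        if best[1][-1] < 1e-6:
            break
    X, trace, conv = best
    return OrdinationResult(coordinates=X, stress=trace[-1], n_starts=n_starts,
                            converged=conv, stress_trace=trace, labels=list(d.labels))


# ---------------------------------------------------------------------------
# PERMANOVA (sequential sums of squares)
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    table: pd.DataFrame        # factor, df, SS, R2, F, p
    residual_ss: float
    total_ss: float
    n_permutations: int

    def r2(self, factor: str) -> float:
        return float(self.table.set_index("factor").loc[factor, "R2"])

    def p(self, factor: str) -> float:
        return float(self.table.set_index("factor").loc[factor, "p"])


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D**2
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _design_columns(values: np.ndarray) -> np.ndarray:
    """Dummy-code a categorical factor (drop first level) or pass through a
    numeric covariate as a single centred column."""
    if np.issubdtype(np.asarray(values).dtype, np.number):
        v = np.asarray(values, dtype=float)
        return (v - v.mean())[:, None]
    codes, uniq = pd.factorize(values)
    if len(uniq) < 2:
        raise ValidationError("constant factor in PERMANOVA design")
    out = np.zeros((len(values), len(uniq) - 1))
    for j in range(1, len(uniq)):
        out[codes == j, j - 1] = 1.0
    return out


def _hat(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


def permanova(d: DistanceMatrix, factors: pd.DataFrame, n_perm: int = 1000,
              seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential (Type I) sums of
    squares in the given column order of ``factors``.

    p-values use unrestricted row permutations:
    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if len(factors) != len(d.labels):
        raise ValidationError("factor table does not align with the distance matrix")
    G = _gower_center(d.values)
    n = G.shape[0]
    total_ss = float(np.trace(G))

    names = list(factors.columns)
    X = np.ones((n, 1))
    hats = [_hat(X)]
    dfs = []
    for name in names:
        cols = _design_columns(factors[name].to_numpy())
        X = np.hstack([X, cols])
        if np.linalg.matrix_rank(X) <= np.linalg.matrix_rank(hats[-1]):
            raise ValidationError(f"factor {name} adds no rank to the design")
        hats.append(_hat(X))
        dfs.append(int(round(np.trace(hats[-1]) - np.trace(hats[-2]))))
    df_resid = n - int(round(np.trace(hats[-1])))
    if df_resid <= 0:
        raise ValidationError("saturated design: no residual degrees of freedom")

    def stats_for(Gp):
        tr = [float(np.sum(h * Gp)) for h in hats]  # tr(H G) = sum(H * G)
        ss = np.diff(tr)
        ss_res = float(np.trace(Gp)) - tr[-1]
        F = (ss / np.asarray(dfs)) / (ss_res / df_resid)
        return ss, ss_res, F

    ss_obs, ss_res_obs, F_obs = stats_for(G)
    rng = stage_rng(seed, "permanova")
    exceed = np.zeros(len(names))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, _, F_perm = stats_for(G[np.ix_(perm, perm)])
        exceed += F_perm >= F_obs - 1e-12
    pvals = (exceed + 1.0) / (n_perm + 1.0)

    table = pd.DataFrame({
        "factor": names, "df": dfs, "SS": ss_obs,
        "R2": ss_obs / total_ss, "F": F_obs, "p": pvals,
    })
    return PermanovaResult(table=table, residual_ss=ss_res_obs,
                           total_ss=total_ss, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# beta dispersion
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    group_means: pd.Series     # mean distance-to-median per group
    distances: np.ndarray      # per-sample distance to its group's median
    F: float
    p: float


def _pcoa_axes(D: np.ndarray):
    """Principal coordinates split into real (positive-eigenvalue) and
    imaginary (negative-eigenvalue) axes."""
    G = _gower_center(D)
    vals, vecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    eps = np.max(np.abs(vals)) * 1e-10
    pos = vals > eps
    neg = vals < -eps
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag


def _spatial_median(X: np.ndarray, maxit: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Geometric (L1) median by Weiszfeld iteration."""
    if X.shape[1] == 0:
        return np.zeros(0)
    m = X.mean(axis=0)
    for _ in range(maxit):
        d = np.sqrt(((X - m) ** 2).sum(axis=1))
        if np.any(d < 1e-12):
            return X[np.argmin(d)]
        w = 1.0 / d
        new = (X * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - m) < tol:
            return new
        m = new
    return m


def betadisper(d: DistanceMatrix, groups) -> DispersionResult:
    """Homogeneity of multivariate dispersions: per-sample distance to the
    group spatial median in principal-coordinate space (imaginary axes
    subtract), followed by a one-way F test with a parametric p-value."""
    groups = np.asarray(groups)
    if len(groups) != len(d.labels):
        raise ValidationError("group labels do not align with the distance matrix")
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValidationError(f"group {small!r} has fewer than 2 members")
    real, imag = _pcoa_axes(d.values)
    dist = np.empty(len(groups))
    for g in uniq:
        sel = groups == g
        mr = _spatial_median(real[sel])
        mi = _spatial_median(imag[sel])
        d2 = ((real[sel] - mr) ** 2).sum(axis=1)
        if imag.shape[1]:
            d2 = d2 - ((imag[sel] - mi) ** 2).sum(axis=1)
        dist[sel] = np.sqrt(np.clip(d2, 0.0, None))
    F, p = anova_oneway(dist, groups)
    means = pd.Series({g: float(dist[groups == g].mean()) for g in uniq})
    return DispersionResult(group_means=means, distances=dist, F=F, p=p)


def anova_oneway(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA (between/within decomposition)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValidationError("one-way ANOVA needs at least 2 groups")
    if np.ptp(values) <= 1e-12 * max(1.0, float(np.abs(values).max())):
        return 0.0, 1.0  # no spread at all: degenerate, not significant
    samples = [values[groups == g] for g in uniq]
    F, p = stats.f_oneway(*samples)
    if np.isnan(F):  # zero within-group variance and equal means
        F, p = 0.0, 1.0
    return float(F), float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
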