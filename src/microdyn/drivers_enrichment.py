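"""Per-ASV trend models selecting the "drivers of diversity" of each
subject, and hypergeometric enrichment of stable-cluster membership among
those drivers.

A driver is an ASV whose standardised absolute consecutive-timepoint
abundance differences follow the same segmented temporal pattern as the
subject's overall within-subject turnover: its segment-wise linear model is
significant (BH-adjusted across the subject's ASVs) and every segment slope
sign matches the global pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError
from .preprocess import NormalizedTable
from .segmentation import Segmentation
from .community_stats import bh_adjust

logger = logging.getLogger("microdyn")


@dataclass
class DriverResult:
    subject_id: str
    asv_id: str
    segment_slopes: list[float]
    concordant: bool
    p: float
    p_adj: float = np.nan
    driver: bool = False


@dataclass
class EnrichmentResult:
    subject_id: str
    N: int       # ASV universe size
    K: int       # stable-cluster size
    n: int       # drivers for this subject
    k: int       # stable drivers
    p: float
    p_adj: float
    fold: float

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValidationError("k cannot exceed min(n, K)")


def _segment_design(days: np.ndarray, cps: list[int]):
    """Segment indicators and segment-specific day slopes."""
    edges = [-np.inf, *cps, np.inf]
    seg_of = np.zeros(len(days), dtype=int)
    for s, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        seg_of[(days > a) & (days <= b)] = s
    nseg = len(cps) + 1
    X = np.zeros((len(days), 2 * nseg))
    for s in range(nseg):
        sel = seg_of == s
        X[sel, s] = 1.0
        X[sel, nseg + s] = days[sel] - days[sel].mean() if sel.any() else 0.0
    return X, seg_of, nseg


def asv_trend_models(table: NormalizedTable, seg: Segmentation, subject: str,
                     global_slope_signs: list[int],
                     alpha: float = 0.05) -> list[DriverResult]:
    """Fit, for every ASV the subject carries, a linear model of its
    standardised |consecutive difference| series with segment-specific
    intercepts and day slopes; flag drivers.

    ``global_slope_signs`` are the signs of the per-segment slopes of the
    subject-pooled within-subject turnover (the pattern a driver must
    reproduce).
    """
    cols = [j for j, s in enumerate(table.samples) if s.subject_id == subject]
    if not cols:
        raise ValidationError(f"subject {subject!r} has no samples")
    cols.sort(key=lambda j: table.samples[j].day)
    days_obs = np.array([table.samples[j].day for j in cols], dtype=float)
    diffs_days = days_obs[1:]
    X, seg_of, nseg = _segment_design(diffs_days, seg.changepoint_days)
    if nseg != len(global_slope_signs):
        raise ValidationError("global pattern length does not match the segmentation")

    results = []
    vals = table.values[:, cols]
    for i, asv in enumerate(table.asv_ids):
        series = vals[i]
        if np.all(series == 0):
            continue  # ASV absent from this subject entirely
        d = np.abs(np.diff(series))
        sd = d.std(ddof=0)
        if sd == 0:
            results.append(DriverResult(subject, asv, [0.0] * nseg, False, 1.0))
            continue
        z = (d - d.mean()) / sd
        b, *_ = np.linalg.lstsq(X, z, rcond=None)
        resid = z - X @ b
        ss1 = float(resid @ resid)
        ss0 = float(np.sum((z - z.mean()) ** 2))
        p_model = 2 * nseg - 1  # extra parameters over the intercept-only model
        df_resid = len(z) - 2 * nseg
        if df_resid <= 0 or ss1 <= 0:
            p = 1.0
        else:
            F = ((ss0 - ss1) / p_model) / (ss1 / df_resid)
            p = float(stats.f.sf(F, p_model, df_resid))
        slopes = [float(b[nseg + s]) for s in range(nseg)]
        concordant = all(np.sign(s) == np.sign(g) and s != 0
                         for s, g in zip(slopes, global_slope_signs))
        results.append(DriverResult(subject, asv, slopes, concordant, p))

    if results:
        adj = bh_adjust([r.p for r in results])
        for r, pa in zip(results, adj):
            r.p_adj = float(pa)
            r.driver = bool(r.p_adj < alpha and r.concordant)
    return results


def drivers_table(results: list[DriverResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": r.subject_id, "asv_id": r.asv_id,
        "slopes": ";".join(f"{s:.6g}" for s in r.segment_slopes),
        "concordant": r.concordant, "p": r.p, "p_adj": r.p_adj, "driver": r.driver,
    } for r in results])


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric P(X >= k) when n draws come from a universe
    of N holding K successes."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValidationError(f"invalid hypergeometric parameters N={N} K={K} n={n} k={k}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(drivers_by_subject: dict[str, list[DriverResult]],
                         stable_ids, universe) -> list[EnrichmentResult]:
    """Per-subject enrichment of stable-cluster ASVs among that subject's
    drivers, BH-corrected across subjects."""
    universe = list(universe)
    N = len(universe)
    stable = set(stable_ids) & set(universe)
    K = len(stable)
    rows = []
    for subject in sorted(drivers_by_subject):
        driver_ids = {r.asv_id for r in drivers_by_subject[subject] if r.driver}
        driver_ids &= set(universe)
        n = len(driver_ids)
        k = len(driver_ids & stable)
        if n == 0:
            logger.warning("subject %s has no drivers: enrichment p set to 1", subject)
            p = 1.0
            fold = 0.0
        else:
            p = hypergeom_pvalue(N, K, n, k)
            fold = (k / n) / (K / N) if K else 0.0
        rows.append((subject, n, k, p, fold))
    adj = bh_adjust([r[3] for r in rows]) if rows else []
    return [EnrichmentResult(subject_id=s, N=N, K=K, n=n, k=k, p=p,
                             p_adj=float(pa), fold=fold)
            for (s, n, k, p, fold), pa in zip(rows, adj)]


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": r.subject_id, "N": r.N, "K": r.K, "n": r.n, "k": r.k,
        "fraction_stable": (r.k / r.n if r.n else 0.0),
        "fold": r.fold, "p": r.p, "p_adj": r.p_adj,
    } for r in results])
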