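"""Three-stage temporal segmentation of diversity series.

1. **Change-point detection.**  Per-subject nonparametric PELT: the segment
   cost is the empirical-CDF multinomial cost evaluated at K quantiles of
   the full series (K = ceil(4 log n) by default), and the penalty is the
   modified BIC: 3 log n per change-point plus a sum of log(segment
   length / n) corrections folded into the segment costs.  PELT minimises
   the penalised total cost exactly, with pruning.

2. **Genetic-algorithm refinement.**  Change-points pooled over subjects
   form a candidate set; chromosomes are inclusion masks over it (the empty
   mask -- no change-points -- is admissible).  The fitness of a mask is
   1 / sum_k RMSE(lmm_k), where lmm_k is the subject-random-intercept model
   of segment k (ordinary regression for ungrouped series).  Elitist GA
   with uniform crossover and bit-flip mutation; fitness values are cached
   per mask, so the search effectively enumerates the reachable masks.

3. **Per-segment inference.**  Each segment is fitted as value ~ day with a
   subject random intercept (Satterthwaite df), and the cumulative effect
   slope x (segment day span) is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ValidationError, stage_rng
from .diversity import DiversitySeries
from .lmm import MixedModelFit, fit_lmm, fit_ols

logger = logging.getLogger("microdyn")


# ---------------------------------------------------------------------------
# nonparametric PELT with MBIC penalty
# ---------------------------------------------------------------------------

def _np_cost_terms(values: np.ndarray, n_quantiles: int):
    """Cumulative empirical-CDF counts at K tail-weighted quantiles.

    Returns (cum_lt, cum_eq, weight): cum arrays of shape (K, n+1) so the
    segment (s, t] statistics are differences of cumulative sums.
    """
    n = len(values)
    K = n_quantiles
    c = -np.log(2 * n - 1)
    k = np.arange(1, K + 1)
    probs = 1.0 / (1.0 + (2 * n - 1) * np.exp(c * (2 * k - 1) / K))
    quantiles = np.quantile(values, probs, method="linear")
    lt = values[None, :] < quantiles[:, None]
    eq = values[None, :] == quantiles[:, None]
    cum_lt = np.zeros((K, n + 1))
    cum_eq = np.zeros((K, n + 1))
    cum_lt[:, 1:] = np.cumsum(lt, axis=1)
    cum_eq[:, 1:] = np.cumsum(eq, axis=1)
    weight = (-c) / K
    return cum_lt, cum_eq, weight


def _segment_cost(cum_lt, cum_eq, weight, s: int, t: int) -> float:
    """Nonparametric cost of the segment (s, t] (0-based, half-open)."""
    m = t - s
    fhat = (cum_lt[:, t] - cum_lt[:, s] + 0.5 * (cum_eq[:, t] - cum_eq[:, s])) / m
    inner = np.zeros_like(fhat)
    ok = (fhat > 0) & (fhat < 1)
    f = fhat[ok]
    inner[ok] = f * np.log(f) + (1 - f) * np.log1p(-f)
    return float(weight * m * -np.sum(inner))


def pelt_np(times, values, penalty: str = "MBIC", n_quantiles: int | None = None,
            min_seg_len: int = 2) -> list[int]:
    """Nonparametric PELT change-point detection on an ordered series.

    Returns the detected change-points as the *times* of the last
    observation of each non-final segment (a change-point at time t means
    the distribution changes after t).  Series with fewer than 4
    observations return no change-points, with a warning.
    """
    times = np.asarray(times)
    values = np.asarray(values, dtype=float)
    if len(times) != len(values):
        raise ValidationError("times/values length mismatch")
    if np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing")
    n = len(values)
    if n < 4:
        logger.warning("pelt_np: series of length %d is too short; no change-points", n)
        return []
    if penalty != "MBIC":
        raise ValidationError(f"unsupported penalty {penalty!r}")
    if n_quantiles is None:
        n_quantiles = int(np.ceil(4.0 * np.log(n)))
    cum_lt, cum_eq, weight = _np_cost_terms(values, n_quantiles)
    # MBIC: 3 log n per change-point plus log(segment length / n)
    # corrections folded into the segment costs; on this likelihood scale
    # the constant reproduces the expected null behaviour (i.i.d. series
    # stay unsegmented)
    beta = 3.0 * np.log(n)

    def cost(s, t):
        # MBIC folds a log(segment length / n) correction into each segment
        return _segment_cost(cum_lt, cum_eq, weight, s, t) + np.log((t - s) / n)

    # PELT dynamic program over segment ends 0..n
    F = np.full(n + 1, np.inf)
    F[0] = -beta
    last = np.zeros(n + 1, dtype=int)
    candidates = [0]
    # pruning slack: the MBIC length correction is not exactly subadditive,
    # a log n margin preserves exactness
    prune_slack = np.log(n)
    for t in range(min_seg_len, n + 1):
        best, arg = np.inf, 0
        for s in candidates:
            if t - s < min_seg_len:
                continue
            v = F[s] + cost(s, t) + beta
            if v < best:
                best, arg = v, s
        F[t] = best
        last[t] = arg
        candidates = [s for s in candidates
                      if (t - s < min_seg_len)
                      or (F[s] + cost(s, t) + prune_slack <= F[t])]
        candidates.append(t - min_seg_len + 1)
        candidates = sorted(set(s for s in candidates if s <= t))

    # backtrack
    cps = []
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            cps.append(s)
        t = s
    cps.sort()
    return [int(times[c - 1]) for c in cps]


def exhaustive_np(times, values, n_quantiles: int | None = None,
                  min_seg_len: int = 2) -> tuple[list[int], float]:
    """Brute-force optimal segmentation (all subsets of boundaries) under the
    same cost and penalty as :func:`pelt_np`.  Exponential; small n only.
    Returns (change-point times, total penalised cost)."""
    from itertools import combinations

    times = np.asarray(times)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n_quantiles is None:
        n_quantiles = int(np.ceil(4.0 * np.log(n)))
    cum_lt, cum_eq, weight = _np_cost_terms(values, n_quantiles)
    beta = 3.0 * np.log(n)
    positions = range(min_seg_len, n - min_seg_len + 1)
    best_cost, best_cps = np.inf, []
    for m in range(0, n // min_seg_len):
        for cps in combinations(positions, m):
            bounds = [0, *cps, n]
            if any(b2 - b1 < min_seg_len for b1, b2 in zip(bounds[:-1], bounds[1:])):
                continue
            tot = beta * m
            for b1, b2 in zip(bounds[:-1], bounds[1:]):
                tot += (_segment_cost(cum_lt, cum_eq, weight, b1, b2)
                        + np.log((b2 - b1) / n))
            if tot < best_cost - 1e-12:
                best_cost, best_cps = tot, list(cps)
    return [int(times[c - 1]) for c in best_cps], float(best_cost)


def optimal_partition_np(times, values, n_quantiles: int | None = None,
                         min_seg_len: int = 2) -> tuple[list[int], float]:
    """Exact optimal segmentation by full dynamic programming over every
    admissible split (no pruning): the independent oracle for PELT."""
    times = np.asarray(times)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n_quantiles is None:
        n_quantiles = int(np.ceil(4.0 * np.log(n)))
    cum_lt, cum_eq, weight = _np_cost_terms(values, n_quantiles)
    beta = 3.0 * np.log(n)
    F = np.full(n + 1, np.inf)
    F[0] = -beta
    last = np.zeros(n + 1, dtype=int)
    for t in range(min_seg_len, n + 1):
        for s in range(0, t - min_seg_len + 1):
            if 0 < s < min_seg_len:
                continue
            v = (F[s] + _segment_cost(cum_lt, cum_eq, weight, s, t)
                 + np.log((t - s) / n) + beta)
            if v < F[t]:
                F[t], last[t] = v, s
    cps = []
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            cps.append(s)
        t = s
    cps.sort()
    return [int(times[c - 1]) for c in cps], float(F[n])


def pelt_total_cost(times, values, cp_times, n_quantiles: int | None = None) -> float:
    """Penalised total cost of a given segmentation (for optimality checks)."""
    times = np.asarray(times)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n_quantiles is None:
        n_quantiles = int(np.ceil(4.0 * np.log(n)))
    cum_lt, cum_eq, weight = _np_cost_terms(values, n_quantiles)
    beta = 3.0 * np.log(n)
    idx = [int(np.searchsorted(times, c, side="right")) for c in cp_times]
    bounds = [0, *idx, n]
    tot = beta * len(cp_times)
    for b1, b2 in zip(bounds[:-1], bounds[1:]):
        tot += _segment_cost(cum_lt, cum_eq, weight, b1, b2) + np.log((b2 - b1) / n)
    return float(tot)


# ---------------------------------------------------------------------------
# segmentation containers
# ---------------------------------------------------------------------------

@dataclass
class Segmentation:
    """Ordered change-point days partitioning the observation span.

    A change-point day c puts observations with day <= c in the left
    segment.  ``fitness`` is 1 / sum of per-segment model RMSEs.
    """

    changepoint_days: list[int]
    segments: list[tuple[int, int]]
    fitness: float

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.changepoint_days, self.changepoint_days[1:])):
            raise ValidationError("change-point days must be strictly increasing")
        if self.fitness <= 0:
            raise ValidationError("fitness must be positive")

    @property
    def n_segments(self) -> int:
        return len(self.changepoint_days) + 1


def _segments_from_cps(days: np.ndarray, cps: list[int]) -> list[tuple[int, int]]:
    lo, hi = int(days.min()), int(days.max())
    bounds = [lo - 1, *cps, hi]
    return [(a + 1, b) for a, b in zip(bounds[:-1], bounds[1:])]


def _segment_members(series: DiversitySeries, cps: list[int]) -> list[np.ndarray]:
    days = series.days
    edges = [-np.inf, *cps, np.inf]
    return [np.flatnonzero((days > a) & (days <= b))
            for a, b in zip(edges[:-1], edges[1:])]


def _fit_one_segment(series: DiversitySeries, idx: np.ndarray) -> MixedModelFit:
    days = series.days[idx].astype(float)
    vals = series.values[idx]
    X = np.column_stack([np.ones_like(days), days])
    if series.kind == "within_subject" and len(set(series.subjects[idx])) > 1:
        return fit_lmm(vals, X, series.subjects[idx], term_names=["intercept", "day"])
    return fit_ols(vals, X, term_names=["intercept", "day"])


def segmentation_fitness(series: DiversitySeries, cps: list[int],
                         min_segment_transitions: int = 3) -> float:
    """1 / sum of per-segment model RMSEs; 0 (infeasible) when any segment
    holds fewer than ``min_segment_transitions`` distinct transition days."""
    total = 0.0
    for idx in _segment_members(series, cps):
        if len(np.unique(series.days[idx])) < min_segment_transitions:
            return 0.0
        try:
            total += _fit_one_segment(series, idx).rmse
        except ValidationError:
            return 0.0
    if total <= 0:
        return np.inf
    return 1.0 / total


# ---------------------------------------------------------------------------
# genetic-algorithm refinement
# ---------------------------------------------------------------------------

@dataclass
class GAParams:
    population: int = 200
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    elite_fraction: float = 0.05
    patience: int = 25
    tournament: int = 3


@dataclass
class GAResult:
    segmentation: Segmentation
    trajectory: list[float] = field(default_factory=list)
    n_evaluated: int = 0


def ga_refine(candidate_days, series: DiversitySeries,
              ga_params: GAParams | None = None, seed: int = 0,
              min_segment_transitions: int = 3,
              initial_masks: list[list[int]] | None = None) -> GAResult:
    """Select the change-point subset maximising 1 / sum RMSE(lmm_k).

    Chromosomes are inclusion masks over ``candidate_days``.  The detected
    change-points (``initial_masks``, typically the per-subject PELT pool)
    seed the initial population as starting points, alongside the empty
    mask (no change-points is admissible) and random masks.  Elitist;
    fitness values are cached per mask, so the returned mask's fitness is
    >= that of every seeded mask and of the empty mask.
    """
    params = ga_params or GAParams()
    cands = sorted(set(int(c) for c in candidate_days))
    rng = stage_rng(seed, "ga_refine")
    cache: dict[tuple, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = tuple(int(b) for b in mask)
        if key not in cache:
            cps = [c for c, b in zip(cands, mask) if b]
            cache[key] = segmentation_fitness(series, cps, min_segment_transitions)
        return cache[key]

    nb = len(cands)
    if nb == 0:
        fit = segmentation_fitness(series, [], min_segment_transitions)
        seg = Segmentation([], _segments_from_cps(series.days, []), fit)
        return GAResult(seg, [fit], 1)

    def mask_of(day_list):
        return np.isin(cands, list(day_list))

    seeds = [np.ones(nb, bool), np.zeros(nb, bool)]
    seeds += [mask_of(m) for m in (initial_masks or [])]
    pop = rng.random((params.population, nb)) < 0.25
    for i, m in enumerate(seeds[:params.population]):
        pop[i] = m
    scores = np.array([fitness(m) for m in pop])
    n_elite = max(1, int(np.ceil(params.elite_fraction * params.population)))
    trajectory = [float(scores.max())]
    stall = 0
    for _ in range(params.generations):
        order = np.argsort(-scores)
        elite = pop[order[:n_elite]]
        # tournament selection
        draws = rng.integers(0, params.population,
                             size=(params.population - n_elite, params.tournament))
        winners = draws[np.arange(len(draws)), np.argmax(scores[draws], axis=1)]
        parents = pop[winners]
        # uniform crossover between consecutive parent pairs
        partners = parents[rng.permutation(len(parents))]
        do_cross = rng.random(len(parents)) < params.crossover_rate
        swap = rng.random(parents.shape) < 0.5
        children = np.where(do_cross[:, None] & swap, partners, parents)
        # bit-flip mutation
        flips = rng.random(children.shape) < params.mutation_rate
        children = children ^ flips
        pop = np.vstack([elite, children])
        scores = np.array([fitness(m) for m in pop])
        best = float(scores.max())
        if best > trajectory[-1] + 1e-12:
            stall = 0
        else:
            stall += 1
        trajectory.append(best)
        if stall >= params.patience:
            break
    best_mask = pop[int(np.argmax(scores))]
    # guarantee the optimizer contract even on degenerate landscapes
    for ref in seeds:
        if fitness(ref) > fitness(best_mask):
            best_mask = ref
    cps = [c for c, b in zip(cands, best_mask) if b]
    fit = fitness(best_mask)
    if fit <= 0:
        # all masks infeasible under the segment-length guard: fall back to
        # the unsegmented series
        cps, fit = [], segmentation_fitness(series, [], min_segment_transitions)
    seg = Segmentation(cps, _segments_from_cps(series.days, cps), fit)
    return GAResult(seg, trajectory, len(cache))


def detect_candidates(series: DiversitySeries, n_quantiles: int | None = None,
                      min_seg_len: int = 2) -> list[int]:
    """Per-subject PELT change-points pooled (union) over subjects."""
    pool: set[int] = set()
    for subject in np.unique(series.subjects):
        sel = series.subjects == subject
        days = series.days[sel]
        order = np.argsort(days)
        cps = pelt_np(days[order], series.values[sel][order],
                      n_quantiles=n_quantiles, min_seg_len=min_seg_len)
        pool.update(cps)
    last = int(series.days.max())
    return sorted(c for c in pool if c < last)


# ---------------------------------------------------------------------------
# per-segment inference
# ---------------------------------------------------------------------------

@dataclass
class SegmentFit:
    """Mixed-model (or OLS) fit of one segment: value ~ day."""

    start_day: int
    end_day: int
    fit: MixedModelFit

    @property
    def slope(self) -> float:
        return float(self.fit.coef("day")["b"])

    @property
    def cumulative_effect(self) -> float:
        """Slope x segment day span: the modelled net change over the segment."""
        return self.slope * (self.end_day - self.start_day)

    def row(self) -> dict:
        day = self.fit.coef("day")
        return {"start_day": self.start_day, "end_day": self.end_day,
                "b": day["b"], "SE": day["SE"], "t": day["t"], "df": day["df"],
                "p": day["p"], "cumulative_effect": self.cumulative_effect}


def fit_segments(series: DiversitySeries, seg: Segmentation) -> list[SegmentFit]:
    """Per-segment slope inference (random intercept for within-subject
    series; ordinary regression for the one-point-per-day between series)."""
    fits = []
    for (start, end), idx in zip(seg.segments, _segment_members(series, seg.changepoint_days)):
        if len(idx) == 0:
            raise ValidationError(f"segment {start}-{end} holds no observations")
        fits.append(SegmentFit(start, end, _fit_one_segment(series, idx)))
    return fits


def segments_table(fits: list[SegmentFit]) -> pd.DataFrame:
    return pd.DataFrame([f.row() for f in fits])


def segment_series(series: DiversitySeries, seed: int = 0,
                   ga_params: GAParams | None = None,
                   min_segment_transitions: int = 3,
                   n_quantiles: int | None = None) -> tuple[Segmentation, list[SegmentFit]]:
    """Full three-stage pipeline: detect -> refine -> fit.

    Per-subject PELT change-points are the GA's starting point; the GA then
    fine-tunes over every interior transition day, so detection inflation
    or misplacement is corrected by the model-fitness criterion.
    """
    detected = detect_candidates(series, n_quantiles=n_quantiles)
    all_days = sorted(set(int(d) for d in series.days))[:-1]
    result = ga_refine(all_days, series, ga_params=ga_params, seed=seed,
                       min_segment_transitions=min_segment_transitions,
                       initial_masks=[detected])
    return result.segmentation, fit_segments(series, result.segmentation)
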