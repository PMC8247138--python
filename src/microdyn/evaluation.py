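"""Validation experiments: recovery, calibration, and exactness studies.

Each routine regenerates its inputs from scratch under the default study
conditions (or the stated null/printed-value inputs), runs the analysis
method, and measures the outcome.  They power the acceptance checks and the
reproduction script; every routine is fully seeded.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .io import stage_seed
from .synthetic_data import SyntheticDesign, generate
from .preprocess import filter_rare, scale_counts, wisconsin_sqrt
from .diversity import (DistanceMatrix, bray_curtis, within_subject_series,
                        between_subjects_series)
from .community_stats import permanova
from .lmm import fit_lmm
from .segmentation import (pelt_np, optimal_partition_np, pelt_total_cost,
                           segment_series, fit_segments, Segmentation,
                           _segments_from_cps)
from .persistence_dynamics import (persistence_matrix, dtw_cluster,
                                   build_networks, edge_deltas, edge_models)
from .drivers_enrichment import hypergeom_pvalue

#: printed study-design counts (samples per phase per subject):
#: 7 outbound and 5 return timepoints for all six subjects; 3 follow-up
#: timepoints with two discarded samples
TABLE1 = {"outbound": 6 * 7, "return": 6 * 5, "followup": 6 * 3 - 2}

#: printed between-subjects result: cumulative decrease over the 520-day
#: isolation and the per-day effect size it implies
BETWEEN_CUMULATIVE_DECREASE = 0.02179
ISOLATION_SPAN_DAYS = 520


def sample_bookkeeping(seed: int = 0) -> dict:
    """Reconstruct the sampling design and count samples per phase."""
    table, _ = generate(SyntheticDesign(seed=seed), with_tree=False)
    meta = table.metadata_frame()
    counts = meta.groupby("phase").size().to_dict()
    counts["total"] = len(meta)
    return counts


def between_slope_implied() -> float:
    """Per-day slope implied by the printed cumulative 520-day decrease."""
    return BETWEEN_CUMULATIVE_DECREASE / ISOLATION_SPAN_DAYS


def bray_curtis_identity(n_pairs: int = 1000, seed: int = 0) -> float:
    """Largest deviation between the direct Bray-Curtis formula and its
    gains/losses decomposition over random abundance pairs."""
    rng = np.random.default_rng(stage_seed(seed, "bc_identity"))
    worst = 0.0
    for _ in range(n_pairs):
        m = int(rng.integers(5, 60))
        x = rng.random(m) * rng.integers(0, 2, m)
        y = rng.random(m) * rng.integers(0, 2, m)
        x[int(rng.integers(m))] += rng.random() + 0.01
        d, dec = bray_curtis(x, y)
        alt = (dec.B + dec.C) / (2 * dec.A + dec.B + dec.C)
        worst = max(worst, abs(d - alt))
    return worst


def _within_series(design: SyntheticDesign):
    table, _ = generate(design, with_tree=False)
    norm = wisconsin_sqrt(scale_counts(filter_rare(table)))
    return norm, within_subject_series(norm, "bray_curtis")


def changepoint_recovery(n_seeds: int = 50, seed: int = 0,
                         n_null: int = 5) -> dict:
    """Detect -> GA-refine -> fit on fresh default-design draws.

    Returns the fraction of seeds recovering both planted change-points
    within one timepoint, the fraction recovering all three slope signs
    (fitting the planted segmentation), and the fraction of between-subjects
    null-design runs left unsegmented.
    """
    d0 = SyntheticDesign()
    days = np.asarray(d0.timepoint_days)
    windows = []
    for cp in d0.planted_changepoints:
        pos = int(np.argmin(np.abs(days - cp)))
        windows.append(set(days[max(pos - 1, 0):pos + 2].tolist()))
    planted_cps = [int(days[np.searchsorted(days, cp) - 1])
                   for cp in d0.planted_changepoints]
    planted_signs = [int(np.sign(s)) for s in d0.segment_turnover_slopes]

    hits = sign_hits = 0
    for i in range(n_seeds):
        s = stage_seed(seed, f"recovery_{i}")
        design = SyntheticDesign(seed=s)
        _, ws = _within_series(design)
        seg, _ = segment_series(ws, seed=s)
        cps = seg.changepoint_days
        ok = (len(cps) == len(windows)
              and all(c in w for c, w in zip(cps, windows)))
        hits += ok
        true_seg = Segmentation(planted_cps,
                                _segments_from_cps(ws.days, planted_cps), 1.0)
        fits = fit_segments(ws, true_seg)
        sign_hits += [int(np.sign(f.slope)) for f in fits] == planted_signs

    null_zero = 0
    for i in range(n_null):
        s = stage_seed(seed, f"null_between_{i}")
        design = SyntheticDesign(
            seed=s, segment_turnover_slopes=(0.0, 0.0, 0.0),
            segment_level_offsets=(0.0, 0.0, 0.0), isolation_end_jump=0.0,
            churn_decline_per_day=0.0)
        norm, _ = _within_series(design)
        bs = between_subjects_series(norm, "bray_curtis")
        seg, _ = segment_series(bs, seed=s)
        null_zero += seg.changepoint_days == []
    return {"both_changepoints_rate": hits / n_seeds if n_seeds else np.nan,
            "slope_sign_rate": sign_hits / n_seeds if n_seeds else np.nan,
            "between_null_unsegmented_rate": (null_zero / n_null
                                              if n_null else np.nan)}


def pelt_exactness(n_cases: int = 100, seed: int = 0) -> float:
    """Fraction of random small series where PELT attains the exact optimal
    penalised cost (full dynamic program without pruning as the oracle)."""
    rng = np.random.default_rng(stage_seed(seed, "pelt_exact"))
    agree = 0
    for _ in range(n_cases):
        n = int(rng.integers(6, 21))
        y = rng.normal(0, 1, n)
        if rng.random() < 0.5:
            split = int(rng.integers(2, n - 1))
            y[split:] += rng.uniform(0.5, 5.0)
        t = np.arange(1, n + 1)
        cps = pelt_np(t, y)
        _, ref_cost = optimal_partition_np(t, y)
        agree += abs(pelt_total_cost(t, y, cps) - ref_cost) < 1e-9
    return agree / n_cases


def permanova_type1(n_reps: int = 500, n_perm: int = 199, n: int = 24,
                    alpha: float = 0.05, seed: int = 0) -> float:
    """Rejection rate of PERMANOVA under a label-independent null."""
    rng = np.random.default_rng(stage_seed(seed, "permanova_null"))
    labels = pd.DataFrame({"g": ["a"] * (n // 2) + ["b"] * (n // 2)})
    rejections = 0
    for i in range(n_reps):
        y = rng.normal(0, 1, n)
        dm = DistanceMatrix([f"s{j}" for j in range(n)],
                            np.abs(y[:, None] - y[None, :]), "bray_curtis")
        res = permanova(dm, labels, n_perm=n_perm,
                        seed=stage_seed(seed, f"perm_{i}"))
        rejections += res.p("g") <= alpha
    return rejections / n_reps


def clustering_recovery(n_seeds: int = 20, seed: int = 0) -> float:
    """Median adjusted Rand index of the DTW/PAM split against the planted
    stable/transient families."""
    aris = []
    for i in range(n_seeds):
        s = stage_seed(seed, f"cluster_{i}")
        table, _ = generate(SyntheticDesign(seed=s), with_tree=False)
        filtered = filter_rare(table)
        pm = persistence_matrix(filtered)
        truth = [1 if a.startswith("ASV_S") else 0 for a in pm.asv_ids]
        ca = dtw_cluster(pm, seed=s)
        pred = [ca.labels[a] - 1 for a in pm.asv_ids]
        aris.append(adjusted_rand_score(truth, pred))
    return float(np.median(aris))


def edge_dynamics(n_seeds: int = 50, seed: int = 0) -> dict:
    """Recovery of the planted post-isolation jump in formed edges, plus an
    exact check of the edge bookkeeping identity on every run."""
    jumps = []
    violations = 0
    for i in range(n_seeds):
        s = stage_seed(seed, f"edges_{i}")
        design = SyntheticDesign(seed=s)
        table, _ = generate(design, with_tree=False)
        filtered = filter_rare(table)
        nets = sorted(build_networks(filtered), key=lambda x: x.day)
        deltas = edge_deltas(nets)
        fits = edge_models(deltas)
        jumps.append(float(fits["formed"].coef("post_isolation")["b"]))
        per = deltas.frame.set_index(["subject_id", "day"])
        for prev, cur in zip(nets[:-1], nets[1:]):
            for subj in prev.subjects & cur.subjects:
                e_prev = sum(1 for x, _ in prev.edges if x == subj)
                e_cur = sum(1 for x, _ in cur.edges if x == subj)
                row = per.loc[(subj, cur.day)]
                if e_cur != e_prev + row["formed"] - row["destroyed"]:
                    violations += 1
    return {"jump_median": float(np.median(jumps)),
            "planted_jump": SyntheticDesign().isolation_end_jump,
            "bookkeeping_violations": violations}


def hypergeom_agreement(max_n: int = 12) -> float:
    """Largest deviation between the closed-form upper-tail probability and
    exact combinatorial enumeration over all small parameter sets."""
    worst = 0.0
    for N in range(2, max_n + 1):
        for K in range(0, N + 1):
            for n in range(0, N + 1):
                for k in range(max(0, n + K - N), min(n, K) + 1):
                    exact = sum(comb(K, j) * comb(N - K, n - j)
                                for j in range(k, min(n, K) + 1)) / comb(N, n)
                    worst = max(worst, abs(hypergeom_pvalue(N, K, n, k) - exact))
    return worst


def lmm_recovery(n_reps: int = 200, seed: int = 0, slope: float = 0.001,
                 su: float = 0.05, se: float = 0.05) -> dict:
    """Slope bias and 95 percent CI coverage of the REML engine on the
    6-subject x 15-timepoint design."""
    rng = np.random.default_rng(stage_seed(seed, "lmm_recovery"))
    days = np.tile(np.linspace(1, 720, 15), 6)
    groups = np.repeat([f"g{i}" for i in range(6)], 15)
    X = np.column_stack([np.ones_like(days), days])
    estimates, covered = [], 0
    for _ in range(n_reps):
        u = rng.normal(0, su, 6)
        y = 0.4 + slope * days + np.repeat(u, 15) + rng.normal(0, se, len(days))
        fit = fit_lmm(y, X, groups, ["intercept", "day"])
        row = fit.coef("day")
        estimates.append(float(row["b"]))
        half = stats.t.ppf(0.975, row["df"]) * row["SE"]
        covered += (row["b"] - half) <= slope <= (row["b"] + half)
    bias = (np.mean(estimates) - slope) / slope
    return {"slope_bias_fraction": float(bias),
            "ci95_coverage": covered / n_reps}
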