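"""Persistence of ASVs across subjects, stable/inconsistent clustering, and
bipartite subject-ASV network dynamics.

The *persistence* of an ASV at a timepoint is the number of subjects in
which it is detected.  Row-standardised persistence trajectories are
clustered with dynamic time warping + partitioning around medoids into two
groups: the *stable* microbiota (cluster 2, high persistence, shared by most
subjects throughout) and the *inconsistent* microbiota (cluster 1, sporadic,
low abundance).  The same detection rule defines per-timepoint bipartite
subject-ASV networks whose edge turnover (formed/destroyed edges per
transition) is modelled with random-intercept mixed models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import LongitudinalCountTable, ValidationError, stage_rng
from .preprocess import NormalizedTable
from .lmm import MixedModelFit, fit_lmm, fit_ols

logger = logging.getLogger("microdyn")


# ---------------------------------------------------------------------------
# persistence matrix
# ---------------------------------------------------------------------------

@dataclass
class PersistenceMatrix:
    """ASV x timepoint counts of carrying subjects."""

    asv_ids: list[str]
    days: list[int]
    values: np.ndarray                 # integer, 0..subjects sampled that day
    n_subjects_per_day: np.ndarray

    def scaled(self) -> np.ndarray:
        """Per-row centred/scaled variant (constant rows map to zeros)."""
        v = self.values.astype(float)
        mean = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, ddof=1, keepdims=True)
        out = np.zeros_like(v)
        np.divide(v - mean, sd, out=out, where=sd > 0)
        return out

    def mean_persistence_fraction(self) -> np.ndarray:
        """Per-ASV mean persistence as a fraction of subjects sampled."""
        return (self.values / self.n_subjects_per_day[None, :]).mean(axis=1)


def persistence_matrix(table: LongitudinalCountTable | NormalizedTable,
                       detection_threshold: int = 1) -> PersistenceMatrix:
    """entry(a, t) = number of subjects whose sample at day t holds at least
    ``detection_threshold`` counts of ASV a."""
    if detection_threshold < 1:
        raise ValidationError("detection threshold must be >= 1")
    v = table.counts if isinstance(table, LongitudinalCountTable) else table.values
    days = sorted({s.day for s in table.samples})
    day_ix = {d: i for i, d in enumerate(days)}
    out = np.zeros((len(table.asv_ids), len(days)), dtype=int)
    n_subj = np.zeros(len(days), dtype=int)
    for j, s in enumerate(table.samples):
        t = day_ix[s.day]
        n_subj[t] += 1
        out[:, t] += (np.asarray(v)[:, j] >= detection_threshold)
    return PersistenceMatrix(list(table.asv_ids), days, out, n_subj)


# ---------------------------------------------------------------------------
# dynamic time warping + partitioning around medoids
# ---------------------------------------------------------------------------

def dtw_distance(a, b) -> float:
    """Classic DTW with the symmetric step pattern and no window constraint."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    cost = np.abs(a[:, None] - b[None, :])
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = cost[i - 1, j - 1] + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return float(D[n, m])


def dtw_distance_matrix(rows: np.ndarray, chunk: int = 200_000) -> np.ndarray:
    """All-pairs DTW distances; the dynamic program is vectorised over pairs
    with rolling rows (memory O(chunk x T))."""
    rows = np.asarray(rows, dtype=float)
    r, T = rows.shape
    ii, jj = np.triu_indices(r, 1)
    out = np.zeros((r, r))
    for lo in range(0, len(ii), chunk):
        sl = slice(lo, min(lo + chunk, len(ii)))
        a = rows[ii[sl]]          # (m, T)
        b = rows[jj[sl]]
        m = a.shape[0]
        prev = np.full((m, T + 1), np.inf)
        prev[:, 0] = 0.0
        cur = np.empty((m, T + 1))
        for i in range(1, T + 1):
            cur[:, 0] = np.inf
            ai = a[:, i - 1][:, None]
            c = np.abs(ai - b)                      # (m, T)
            for j in range(1, T + 1):
                cur[:, j] = c[:, j - 1] + np.minimum(
                    np.minimum(prev[:, j], cur[:, j - 1]), prev[:, j - 1])
            prev, cur = cur, prev
        out[ii[sl], jj[sl]] = prev[:, T]
    out += out.T
    return out


def pam(dist: np.ndarray, k: int, seed: int = 0, maxit: int = 100) -> np.ndarray:
    """Partitioning around medoids (BUILD + SWAP) on a precomputed distance
    matrix; returns integer labels 0..k-1."""
    n = dist.shape[0]
    if n < k:
        raise ValidationError(f"cannot form {k} clusters from {n} rows")
    rng = stage_rng(seed, "pam")
    # BUILD: greedy medoid selection
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    # SWAP
    for _ in range(maxit):
        best_cost = dist[:, medoids].min(axis=1).sum()
        improved = False
        for mi, m in enumerate(list(medoids)):
            others = [x for x in range(n) if x not in medoids]
            rng.shuffle(others)
            for h in others:
                trial = list(medoids)
                trial[mi] = h
                cost = dist[:, trial].min(axis=1).sum()
                if cost < best_cost - 1e-12:
                    medoids = trial
                    best_cost = cost
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break
    return np.argmin(dist[:, medoids], axis=1)


@dataclass
class ClusterAssignment:
    """asv_id -> cluster label; 1 = inconsistent, 2 = stable (higher mean
    raw persistence)."""

    labels: dict[str, int]
    summary: pd.DataFrame   # cluster, size, mean_persistence, mean_abundance

    @property
    def stable_ids(self) -> list[str]:
        return [a for a, c in self.labels.items() if c == 2]

    @property
    def inconsistent_ids(self) -> list[str]:
        return [a for a, c in self.labels.items() if c == 1]


def dtw_cluster(pm: PersistenceMatrix, k: int = 2, seed: int = 0,
                abundance: np.ndarray | None = None) -> ClusterAssignment:
    """DTW distances between scaled persistence rows, PAM into k clusters;
    labels mapped so cluster 2 carries the higher mean raw persistence."""
    if pm.values.shape[0] < k:
        raise ValidationError("fewer persistence rows than clusters")
    if k != 2:
        raise ValidationError("the stable/inconsistent contrast uses k = 2")
    dist = dtw_distance_matrix(pm.scaled())
    raw_labels = pam(dist, k, seed=seed)
    mean_pers = pm.values.mean(axis=1)
    means = [mean_pers[raw_labels == c].mean() for c in range(k)]
    stable_raw = int(np.argmax(means))
    labels = {a: (2 if raw_labels[i] == stable_raw else 1)
              for i, a in enumerate(pm.asv_ids)}
    if means[stable_raw] <= means[1 - stable_raw]:
        raise ValidationError("degenerate clustering: equal mean persistences")
    rows = []
    for c in (1, 2):
        sel = np.array([labels[a] == c for a in pm.asv_ids])
        rows.append({
            "cluster": c, "size": int(sel.sum()),
            "mean_persistence": float(mean_pers[sel].mean()) if sel.any() else np.nan,
            "mean_abundance": (float(np.asarray(abundance)[sel].mean())
                               if abundance is not None and sel.any() else np.nan),
        })
    return ClusterAssignment(labels, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# persistence vs. abundance
# ---------------------------------------------------------------------------

@dataclass
class LinearFitResult:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r2: float
    t: float
    df: float
    p: float


def persistence_abundance_fit(pm: PersistenceMatrix,
                              table: NormalizedTable) -> LinearFitResult:
    """OLS of log mean normalised abundance (+1) on mean persistence
    expressed as a fraction of subjects (0..1)."""
    if pm.values.shape[0] < 3:
        raise ValidationError("need at least 3 ASVs")
    if list(pm.asv_ids) != list(table.asv_ids):
        raise ValidationError("persistence matrix and table hold different ASVs")
    x = pm.mean_persistence_fraction()
    y = np.log(table.values.mean(axis=1) + 1.0)
    if np.std(x) == 0:
        raise ValidationError("no variance in persistence: fit is degenerate")
    fit = fit_ols(y, np.column_stack([np.ones_like(x), x]),
                  term_names=["intercept", "persistence"])
    row = fit.coef("persistence")
    tcrit = stats.t.ppf(0.975, fit.n_obs - 2)
    resid_ss = fit.sigma_e2 * (fit.n_obs - 2)
    total_ss = float(np.sum((y - y.mean()) ** 2))
    return LinearFitResult(
        slope=float(row["b"]), intercept=float(fit.coef("intercept")["b"]),
        ci_low=float(row["b"] - tcrit * row["SE"]),
        ci_high=float(row["b"] + tcrit * row["SE"]),
        r2=1.0 - resid_ss / total_ss, t=float(row["t"]), df=float(row["df"]),
        p=float(row["p"]))


# ---------------------------------------------------------------------------
# bipartite networks and edge turnover
# ---------------------------------------------------------------------------

@dataclass
class NetworkSnapshot:
    """Bipartite subject-ASV presence network at one timepoint."""

    day: int
    edges: set[tuple[str, str]]     # (subject_id, asv_id)
    subjects: set[str]
    asv_ids: list[str]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, asv_id: str) -> int:
        return sum(1 for _, a in self.edges if a == asv_id)

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(self.subjects, bipartite="subject")
        g.add_nodes_from(self.asv_ids, bipartite="asv")
        g.add_edges_from(self.edges)
        return g


def build_networks(table: LongitudinalCountTable | NormalizedTable,
                   detection_threshold: int = 1) -> list[NetworkSnapshot]:
    """One bipartite snapshot per timepoint; edge (subject, ASV) present iff
    the ASV is detected in that subject's sample that day."""
    v = np.asarray(table.counts if isinstance(table, LongitudinalCountTable)
                   else table.values)
    days = sorted({s.day for s in table.samples})
    snaps = []
    for day in days:
        edges = set()
        subjects = set()
        for j, s in enumerate(table.samples):
            if s.day != day:
                continue
            subjects.add(s.subject_id)
            for i in np.nonzero(v[:, j] >= detection_threshold)[0]:
                edges.add((s.subject_id, table.asv_ids[i]))
        snaps.append(NetworkSnapshot(day, edges, subjects, list(table.asv_ids)))
    return snaps


@dataclass
class EdgeDeltaSeries:
    """Formed/destroyed subject-ASV edges per subject per transition."""

    frame: pd.DataFrame   # subject_id, day, formed, destroyed
    spearman_rho: float
    spearman_p: float


def edge_deltas(nets: list[NetworkSnapshot]) -> EdgeDeltaSeries:
    """Per subject per consecutive-timepoint transition: edges formed
    (present now, absent before) and destroyed; plus the Spearman
    correlation between the two across all transitions."""
    if len(nets) < 2:
        raise ValidationError("need at least 2 snapshots")
    nets = sorted(nets, key=lambda s: s.day)
    rows = []
    for prev, cur in zip(nets[:-1], nets[1:]):
        for subject in sorted(prev.subjects & cur.subjects):
            e_prev = {a for s, a in prev.edges if s == subject}
            e_cur = {a for s, a in cur.edges if s == subject}
            rows.append({"subject_id": subject, "day": cur.day,
                         "formed": len(e_cur - e_prev),
                         "destroyed": len(e_prev - e_cur)})
    frame = pd.DataFrame(rows)
    if frame["formed"].nunique() > 1 and frame["destroyed"].nunique() > 1:
        rho, p = stats.spearmanr(frame["formed"], frame["destroyed"])
    else:
        rho, p = np.nan, np.nan
    return EdgeDeltaSeries(frame, float(rho), float(p))


def edge_models(deltas: EdgeDeltaSeries,
                isolation_end_day: int = 520) -> dict[str, MixedModelFit]:
    """Mixed models formed ~ day + post_isolation and destroyed ~ day +
    post_isolation, subject random intercept.  The post-isolation indicator
    estimates the jump in edge turnover at the end of confinement."""
    f = deltas.frame
    if f["subject_id"].nunique() < 2:
        raise ValidationError("edge models need at least 2 subjects")
    day = f["day"].to_numpy(dtype=float)
    post = (day > isolation_end_day).astype(float)
    X = np.column_stack([np.ones_like(day), day, post])
    names = ["intercept", "day", "post_isolation"]
    return {
        "formed": fit_lmm(f["formed"].to_numpy(float), X, f["subject_id"], names),
        "destroyed": fit_lmm(f["destroyed"].to_numpy(float), X, f["subject_id"], names),
    }


def degree_centrality(nets: list[NetworkSnapshot],
                      normalized: bool = False) -> pd.DataFrame:
    """Per-ASV per-timepoint degree (number of carrying subjects), optionally
    normalised by the subjects sampled that day.  Long format:
    asv_id, day, degree."""
    rows = []
    for snap in sorted(nets, key=lambda s: s.day):
        deg = {a: 0 for a in snap.asv_ids}
        for _, a in snap.edges:
            deg[a] += 1
        denom = max(len(snap.subjects), 1) if normalized else 1
        for a, k in deg.items():
            rows.append({"asv_id": a, "day": snap.day, "degree": k / denom})
    return pd.DataFrame(rows)


def cluster_rank_tests(centrality: pd.DataFrame,
                       clusters: ClusterAssignment) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test of stable vs. inconsistent ASV
    centrality at every timepoint."""
    rows = []
    for day, sub in centrality.groupby("day"):
        lab = sub["asv_id"].map(clusters.labels)
        a = sub.loc[lab == 2, "degree"]
        b = sub.loc[lab == 1, "degree"]
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"day": day, "U": float(stat), "p": float(p),
                     "median_stable": float(a.median()),
                     "median_inconsistent": float(b.median())})
    return pd.DataFrame(rows)
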