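"""Alpha diversity, coverage, pairwise beta-diversity indexes, and the
within/between-subject temporal series consumed by the segmentation stage.

Beta diversity comes in qualitative (Sorensen, unweighted UniFrac) and
quantitative (Bray-Curtis, weighted UniFrac) flavours.  Sorensen and
Bray-Curtis are also returned with their gains/losses decomposition
(A = unscaled similarity, B = losses from the first to the second sample,
C = gains), so that the within-subject turnover series can be read as a
temporal beta-diversity index: ``(B + C) / (2A + B + C)`` equals the plain
Bray-Curtis (respectively Sorensen) value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.spatial.distance import squareform, pdist
import skbio
from skbio.diversity import beta_diversity

from .io import LongitudinalCountTable, PhylogeneticTree, ValidationError
from .preprocess import NormalizedTable

logger = logging.getLogger("microdyn")

BETA_INDEXES = ("sorensen", "bray_curtis", "unweighted_unifrac", "weighted_unifrac")


# ---------------------------------------------------------------------------
# alpha diversity and coverage
# ---------------------------------------------------------------------------

def inverse_simpson(counts) -> float:
    """Inverse Simpson index 1 / sum(p_i^2) of a non-negative abundance vector."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValidationError("negative abundances")
    total = x.sum()
    if total == 0:
        raise ValidationError("all-zero abundance vector")
    p = x / total
    return float(1.0 / np.sum(p**2))


def goods_coverage(counts) -> float:
    """Good's coverage 100 * (1 - F1/N): the percentage of reads not coming
    from singleton ASVs.  Defined on raw integer counts only."""
    x = np.asarray(counts)
    if not np.issubdtype(x.dtype, np.integer):
        if np.any(np.mod(x, 1) != 0):
            raise ValidationError("coverage is undefined on non-integer (scaled) counts")
        x = x.astype(np.int64)
    n = int(x.sum())
    if n <= 0:
        raise ValidationError("empty sample")
    f1 = int((x == 1).sum())
    return 100.0 * (1.0 - f1 / n)


def rarefaction_curve(counts, depths) -> np.ndarray:
    """Expected richness E[S_d] at each subsampling depth d (without
    replacement), via log-gamma arithmetic:

    E[S_d] = sum_i [1 - C(N - N_i, d) / C(N, d)]
    """
    x = np.asarray(counts)
    if np.any(np.mod(x, 1) != 0):
        raise ValidationError("rarefaction requires integer counts")
    x = x.astype(np.int64)
    x = x[x > 0]
    n = int(x.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if np.any(depths > n) or np.any(depths < 1):
        raise ValidationError(f"depths must be in [1, {n}]")

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(len(depths))
    for k, d in enumerate(depths):
        keep = (n - x) >= d
        miss = np.zeros(len(x))
        miss[keep] = np.exp(log_choose(n - x[keep], d) - log_choose(n, d))
        out[k] = np.sum(1.0 - miss)
    return out


# ---------------------------------------------------------------------------
# pairwise indexes with gains/losses decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseDecomposition:
    """A = unscaled similarity, B = losses (1st -> 2nd), C = gains, J = shared."""

    A: float
    B: float
    C: float
    J: int


def sorensen(x, y) -> tuple[float, PairwiseDecomposition]:
    """Qualitative Sorensen dissimilarity (A + B - 2J)/(A + B) with A, B the
    richness of each sample and J the shared ASV count."""
    px = np.asarray(x) > 0
    py = np.asarray(y) > 0
    if px.shape != py.shape:
        raise ValidationError("length mismatch")
    a, b = int(px.sum()), int(py.sum())
    if a == 0 and b == 0:
        raise ValidationError("both samples are empty")
    j = int((px & py).sum())
    dist = (a + b - 2 * j) / (a + b)
    losses = int((px & ~py).sum())
    gains = int((~px & py).sum())
    return dist, PairwiseDecomposition(A=float(j), B=float(losses), C=float(gains), J=j)


def bray_curtis(x, y) -> tuple[float, PairwiseDecomposition]:
    """Quantitative (Bray-Curtis) dissimilarity sum|x - y| / sum(x + y),
    identically (B + C)/(2A + B + C) with A = sum min, B = sum of declines,
    C = sum of increases."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("length mismatch")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("negative abundances")
    denom = float((x + y).sum())
    if denom == 0:
        raise ValidationError("both samples are empty")
    dist = float(np.abs(x - y).sum() / denom)
    a = float(np.minimum(x, y).sum())
    b = float(np.clip(x - y, 0, None).sum())
    c = float(np.clip(y - x, 0, None).sum())
    j = int(((x > 0) & (y > 0)).sum())
    return dist, PairwiseDecomposition(A=a, B=b, C=c, J=j)


def unifrac(x, y, asv_ids, tree: PhylogeneticTree, weighted: bool = False) -> float:
    """UniFrac distance between two abundance vectors over ``asv_ids``.

    Unweighted: fraction of branch length unique to either sample within the
    branch length spanned by their union.  Weighted: Lozupone-normalised
    abundance-weighted variant; both in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    leaves = set(tree.leaf_names)
    for i in np.nonzero((x > 0) | (y > 0))[0]:
        if asv_ids[i] not in leaves:
            raise ValidationError(f"ASV {asv_ids[i]} is not a leaf of the tree")
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    dm = beta_diversity(metric, np.vstack([x, y]), ids=["x", "y"], taxa=list(asv_ids),
                        tree=tree.tree, validate=True,
                        **({"normalized": True} if weighted else {}))
    return float(dm["x", "y"])


# ---------------------------------------------------------------------------
# distance matrices and temporal series
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances under one index."""

    labels: list[str]
    values: np.ndarray
    index_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        np.fill_diagonal(self.values, 0.0)

    def __getitem__(self, pair) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.values, ids=self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(table: NormalizedTable, index: str,
                    tree: PhylogeneticTree | None = None) -> DistanceMatrix:
    """All pairwise distances among samples under the chosen index.

    The caller supplies the appropriately transformed table (scaled for
    UniFrac, scaled + Wisconsin-sqrt for Bray-Curtis, anything for the
    presence-based Sorensen).
    """
    if index not in BETA_INDEXES:
        raise ValidationError(f"unknown index {index!r}")
    if len(table.samples) < 2:
        raise ValidationError("need at least 2 samples")
    v = table.values
    if index == "sorensen":
        vals = squareform(pdist((v > 0).astype(float).T, metric="braycurtis"))
    elif index == "bray_curtis":
        vals = squareform(pdist(v.T, metric="braycurtis"))
    else:
        if tree is None:
            raise ValidationError("UniFrac requires a phylogenetic tree")
        leaves = set(tree.leaf_names)
        missing = [a for a, nz in zip(table.asv_ids, (v > 0).any(axis=1)) if nz and a not in leaves]
        if missing:
            raise ValidationError(f"ASV {missing[0]} is not a leaf of the tree")
        kwargs = {"normalized": True} if index == "weighted_unifrac" else {}
        dm = beta_diversity(index, v.T, ids=table.sample_ids, taxa=list(table.asv_ids),
                            tree=tree.tree, validate=True, **kwargs)
        vals = dm.data
    return DistanceMatrix(list(table.sample_ids), vals, index)


@dataclass
class DiversitySeries:
    """Temporal series of turnover values.

    ``kind == 'within_subject'``: one point per subject per consecutive
    timepoint transition, assigned to the later day.
    ``kind == 'between_subjects'``: one point per timepoint (subject 'ALL'),
    the mean of all pairwise distances among subjects sampled that day.
    """

    kind: str
    points: list[tuple[str, int, float]]  # (subject_id or "ALL", day, value)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["subject_id", "day", "value"])

    @property
    def days(self) -> np.ndarray:
        return np.asarray([p[1] for p in self.points])

    @property
    def values(self) -> np.ndarray:
        return np.asarray([p[2] for p in self.points])

    @property
    def subjects(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.points])


def _pair_distance(table: NormalizedTable, j1: int, j2: int, index: str,
                   tree: PhylogeneticTree | None) -> float:
    x, y = table.values[:, j1], table.values[:, j2]
    if index == "sorensen":
        return sorensen(x, y)[0]
    if index == "bray_curtis":
        return bray_curtis(x, y)[0]
    return unifrac(x, y, table.asv_ids, tree, weighted=(index == "weighted_unifrac"))


def within_subject_series(table: NormalizedTable, index: str = "bray_curtis",
                          tree: PhylogeneticTree | None = None) -> DiversitySeries:
    """Within-subject turnover: distance between each subject's consecutive
    samples, assigned to the later day of the transition."""
    by_subject: dict[str, list[int]] = {}
    for j, s in enumerate(table.samples):
        by_subject.setdefault(s.subject_id, []).append(j)
    points = []
    for subject in sorted(by_subject):
        cols = sorted(by_subject[subject], key=lambda j: table.samples[j].day)
        if len(cols) < 2:
            logger.warning("within_subject_series: subject %s has a single "
                           "timepoint; excluded", subject)
            continue
        for j1, j2 in zip(cols[:-1], cols[1:]):
            d = _pair_distance(table, j1, j2, index, tree)
            points.append((subject, table.samples[j2].day, d))
    return DiversitySeries("within_subject", points)


def between_subjects_series(table: NormalizedTable, index: str = "bray_curtis",
                            tree: PhylogeneticTree | None = None) -> DiversitySeries:
    """Between-subject divergence: at each timepoint, the mean of all pairwise
    distances among the subjects sampled that day."""
    by_day: dict[int, list[int]] = {}
    for j, s in enumerate(table.samples):
        by_day.setdefault(s.day, []).append(j)
    points = []
    for day in sorted(by_day):
        cols = by_day[day]
        if len(cols) < 2:
            logger.warning("between_subjects_series: day %d has a single "
                           "subject; excluded", day)
            continue
        vals = [_pair_distance(table, j1, j2, index, tree)
                for j1, j2 in combinations(cols, 2)]
        points.append(("ALL", day, float(np.mean(vals))))
    return DiversitySeries("between_subjects", points)
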