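"""Rare-ASV filtering, depth normalisation, and variance-stabilising transforms.

Order of operations for the downstream diversity stages:

* alpha diversity uses size-factor-scaled counts of the full table;
* beta diversity (qualitative and quantitative) uses the rare-filtered table,
  size-factor scaled, with Wisconsin double standardisation + square root
  applied additionally for the abundance-based indexes (Bray-Curtis); the
  presence-based Sorensen index and UniFrac see scaled counts only.

The size factors use the median-of-ratios estimator with a positive-counts
geometric-mean reference: zero-inflated amplicon tables leave the classic
all-counts reference undefined for most ASVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import LongitudinalCountTable, SampleRecord, ValidationError

logger = logging.getLogger("microdyn")


@dataclass
class NormalizedTable:
    """Same shape as the count table it came from, real-valued entries."""

    asv_ids: list[str]
    samples: list[SampleRecord]
    values: np.ndarray
    provenance: str  # "scaled", "scaled+wisconsin_sqrt", or "filtered_presence"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValidationError("normalized table holds negative values")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]


def filter_rare(table: LongitudinalCountTable, prevalence_fraction: float = 0.05,
                min_abundance: int = 10) -> LongitudinalCountTable:
    """Drop ASVs that are BOTH low-prevalence and low-abundance.

    An ASV is removed when it occurs (count > 0) in fewer than
    ``ceil(prevalence_fraction * n_samples)`` samples AND its total count
    over all samples is below ``min_abundance``.  Both conditions must hold:
    the filter targets extremely rare taxa that distort presence/absence
    indexes, not prevalent-but-shallow ones.
    """
    if not (0 < prevalence_fraction <= 1):
        raise ValidationError("prevalence_fraction must be in (0, 1]")
    n_present = (table.counts > 0).sum(axis=1)
    total = table.counts.sum(axis=1)
    min_samples = int(np.ceil(prevalence_fraction * table.n_samples))
    remove = (n_present < min_samples) & (total < min_abundance)
    if remove.all():
        raise ValidationError("rare-ASV filter removed every ASV (degenerate input)")
    keep = [a for a, r in zip(table.asv_ids, remove) if not r]
    logger.info("filter_rare: removed %d of %d ASVs (kept %d)",
                int(remove.sum()), table.n_asvs, len(keep))
    return table.subset_asvs(keep)


def size_factors(table: LongitudinalCountTable) -> np.ndarray:
    """Median-of-ratios size factors (positive-counts reference), rescaled to
    geometric mean 1.

    The reference for each ASV is the geometric mean of its *nonzero* counts;
    a sample's factor is the median over its nonzero ASVs of count/reference.
    """
    counts = table.counts.astype(float)
    pos = counts > 0
    if (pos.sum(axis=0) == 0).any():
        j = int(np.argmax(pos.sum(axis=0) == 0))
        raise ValidationError(f"sample {table.sample_ids[j]} has no positive counts")
    logc = np.zeros_like(counts)
    np.log(counts, out=logc, where=pos)
    n_pos = pos.sum(axis=1)
    ok = n_pos > 0
    ref = np.full(table.n_asvs, np.nan)
    ref[ok] = np.exp(logc[ok].sum(axis=1) / n_pos[ok])
    factors = np.empty(table.n_samples)
    for j in range(table.n_samples):
        mask = pos[:, j] & ok
        if not mask.any():
            raise ValidationError(
                f"sample {table.sample_ids[j]} shares no nonzero ASV with the reference")
        factors[j] = np.median(counts[mask, j] / ref[mask])
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def scale_counts(table: LongitudinalCountTable) -> NormalizedTable:
    """Divide each sample column by its size factor (depth normalisation)."""
    f = size_factors(table)
    return NormalizedTable(list(table.asv_ids), list(table.samples),
                           table.counts / f[None, :], provenance="scaled")


def wisconsin_sqrt(table: NormalizedTable) -> NormalizedTable:
    """Square root of the Wisconsin double standardisation.

    Each ASV row is divided by its row maximum, then each sample column by
    its column sum, then the square root is taken elementwise.  All-zero
    rows/columns pass through as zeros.
    """
    v = table.values.copy()
    rmax = v.max(axis=1, keepdims=True)
    np.divide(v, rmax, out=v, where=rmax > 0)
    csum = v.sum(axis=0, keepdims=True)
    np.divide(v, csum, out=v, where=csum > 0)
    return NormalizedTable(list(table.asv_ids), list(table.samples), np.sqrt(v),
                           provenance="scaled+wisconsin_sqrt")


def presence(table: LongitudinalCountTable | NormalizedTable) -> NormalizedTable:
    """0/1 presence table (detection = any signal)."""
    v = table.counts if isinstance(table, LongitudinalCountTable) else table.values
    return NormalizedTable(list(table.asv_ids), list(table.samples),
                           (np.asarray(v) > 0).astype(float), provenance="filtered_presence")
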