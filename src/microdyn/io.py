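"""Data model and file I/O shared by all pipeline stages.

The central container is :class:`LongitudinalCountTable`: an ASV-by-sample
matrix of integer read counts joined to per-sample metadata (subject, study
day, diet regime, mission phase).  Counts travel as TSV with ASVs as rows
(first column ``asv_id``) and samples as columns; metadata as a TSV with one
row per sample.  Phylogenies are Newick, wrapped in a thin
:class:`PhylogeneticTree` around :class:`skbio.TreeNode`.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, asdict
from io import StringIO
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger("microdyn")

DIETS = ("FV", "TV", "NR")
PHASES = ("outbound", "return", "followup")

#: last day of the confinement period; samples at or before this day are
#: taken inside the isolation facility.
ISOLATION_END_DAY = 520


class ValidationError(ValueError):
    """Raised when an input table violates the documented contract."""


@dataclass(frozen=True, order=True)
class SampleRecord:
    """One salivary sample: who, when, and under which diet regime."""

    subject_id: str
    day: int
    sample_id: str
    diet: str
    phase: str

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValidationError(f"sample {self.sample_id}: day must be >= 1, got {self.day}")
        if self.diet not in DIETS:
            raise ValidationError(f"sample {self.sample_id}: unknown diet {self.diet!r}")
        if self.phase not in PHASES:
            raise ValidationError(f"sample {self.sample_id}: unknown phase {self.phase!r}")
        if (self.diet == "NR") != (self.phase == "followup"):
            raise ValidationError(
                f"sample {self.sample_id}: the normal (NR) diet is used exactly "
                f"during follow-up (diet={self.diet}, phase={self.phase})"
            )

    @property
    def in_isolation(self) -> bool:
        return self.day <= ISOLATION_END_DAY


@dataclass
class LongitudinalCountTable:
    """ASV x sample integer count matrix with per-sample metadata.

    ``counts[i, j]`` is the number of reads of ``asv_ids[i]`` in
    ``samples[j]``.  Samples are kept sorted by (subject, day).
    """

    asv_ids: list[str]
    samples: list[SampleRecord]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()
        order = np.argsort([(s.subject_id, s.day) for s in self.samples], axis=0)
        # argsort on tuples: use lexsort instead for correctness
        keys = [(s.subject_id, s.day) for s in self.samples]
        order = sorted(range(len(keys)), key=keys.__getitem__)
        self.samples = [self.samples[i] for i in order]
        self.counts = self.counts[:, order]

    # -- basic accessors ---------------------------------------------------
    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def subject_ids(self) -> list[str]:
        return sorted({s.subject_id for s in self.samples})

    @property
    def days(self) -> list[int]:
        return sorted({s.day for s in self.samples})

    def samples_of(self, subject_id: str) -> list[SampleRecord]:
        return [s for s in self.samples if s.subject_id == subject_id]

    def column(self, sample_id: str) -> np.ndarray:
        j = self.sample_ids.index(sample_id)
        return self.counts[:, j]

    def validate(self) -> None:
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise ValidationError("duplicate ASV ids")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids")
        pairs = [(s.subject_id, s.day) for s in self.samples]
        if len(set(pairs)) != len(pairs):
            dup = [p for p in pairs if pairs.count(p) > 1][0]
            raise ValidationError(f"duplicate (subject, day) pair {dup}")
        if self.counts.shape != (len(self.asv_ids), len(self.samples)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.asv_ids)} ASVs x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise ValidationError(
                    f"non-integer count at ASV {self.asv_ids[bad[0]]}, "
                    f"sample {self.samples[bad[1]].sample_id}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at ASV {self.asv_ids[bad[0]]}, "
                f"sample {self.samples[bad[1]].sample_id}"
            )
        colsum = self.counts.sum(axis=0)
        if (colsum == 0).any():
            j = int(np.argmax(colsum == 0))
            raise ValidationError(f"sample {self.samples[j].sample_id} has zero total count")

    # -- frames and files --------------------------------------------------
    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.asv_ids, name="asv_id"),
                            columns=self.sample_ids)

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s.sample_id, "subject_id": s.subject_id, "day": s.day,
             "diet": s.diet, "phase": s.phase, "in_isolation": s.in_isolation}
            for s in self.samples
        ]
        return pd.DataFrame(rows)

    def subset_asvs(self, keep: Sequence[str]) -> "LongitudinalCountTable":
        keep = list(keep)
        idx = {a: i for i, a in enumerate(self.asv_ids)}
        rows = [idx[a] for a in keep]
        return LongitudinalCountTable(keep, list(self.samples), self.counts[rows, :])


@dataclass
class PhylogeneticTree:
    """Rooted tree over ASV leaves with non-negative branch lengths."""

    tree: skbio.TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    @property
    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.tree.traverse() if not n.is_root())

    def to_newick(self) -> str:
        buf = StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue()


def read_count_table(counts_path, metadata_path) -> LongitudinalCountTable:
    """Read a counts TSV (rows=ASVs, first column ``asv_id``) and its
    per-sample metadata TSV into a validated :class:`LongitudinalCountTable`.

    Every column of the count table must have a metadata row; a missing row
    is a hard error naming the sample.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col="asv_id")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"subject_id": str, "sample_id": str})
    meta_ids = set(meta["sample_id"])
    for sid in counts.columns:
        if sid not in meta_ids:
            raise ValidationError(f"metadata has no row for sample {sid}")
    meta = meta.set_index("sample_id").loc[list(counts.columns)].reset_index()
    samples = [
        SampleRecord(sample_id=r.sample_id, subject_id=r.subject_id, day=int(r.day),
                     diet=r.diet, phase=r.phase)
        for r in meta.itertuples()
    ]
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        frac = values.astype(float) % 1
        if np.any(frac != 0):
            i, j = np.argwhere(frac != 0)[0]
            raise ValidationError(
                f"non-integer count at ASV {counts.index[i]}, sample {counts.columns[j]}"
            )
        values = values.astype(np.int64)
    return LongitudinalCountTable(list(counts.index), samples, values)


def write_count_table(table: LongitudinalCountTable, counts_path, metadata_path) -> None:
    table.counts_frame().to_csv(counts_path, sep="\t")
    table.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


def read_newick(path) -> PhylogeneticTree:
    """Read a rooted Newick tree.  Missing branch lengths default to 0
    (contributing nothing to UniFrac) with a logged warning."""
    tree = skbio.TreeNode.read(str(path), format="newick", convert_underscores=False)
    n_missing = 0
    for node in tree.traverse():
        if node.is_root():
            continue
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0 or not np.isfinite(node.length):
            raise ValidationError(f"invalid branch length {node.length} on node {node.name}")
    if n_missing:
        logger.warning("newick: %d missing branch lengths set to 0", n_missing)
    return PhylogeneticTree(tree)


def write_newick(tree: PhylogeneticTree, path) -> None:
    tree.tree.write(str(path), format="newick")


@dataclass
class AnalysisConfig:
    """Flat configuration driving the whole pipeline.

    Every stochastic stage derives its own substream from ``seed`` keyed by
    the stage name, so reruns are bit-reproducible stage by stage.
    """

    # rare-ASV filter (qualitative-index rationale)
    prevalence_fraction: float = 0.05
    min_abundance: int = 10
    # community statistics
    n_permutations: int = 1000
    nmds_starts: int = 300
    significance_level: float = 0.05
    # genetic algorithm
    ga_population: int = 200
    ga_generations: int = 100
    ga_crossover_rate: float = 0.8
    ga_mutation_rate: float = 0.1
    ga_elite_fraction: float = 0.05
    min_segment_transitions: int = 3
    # persistence / networks
    cluster_count: int = 2
    detection_threshold: int = 1
    isolation_end_day: int = ISOLATION_END_DAY
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prevalence_fraction <= 1):
            raise ValidationError("prevalence_fraction must be in (0, 1]")
        for name in ("min_abundance", "n_permutations", "nmds_starts", "ga_population",
                     "ga_generations", "cluster_count", "detection_threshold",
                     "min_segment_transitions"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("ga_crossover_rate", "ga_mutation_rate", "ga_elite_fraction",
                     "significance_level"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31), keyed by stage name."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))
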