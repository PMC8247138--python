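"""End-to-end orchestration of the analysis stages.

``run_all`` executes: (optional) synthetic generation -> preprocessing ->
diversity series -> community statistics -> temporal segmentation ->
persistence/network dynamics -> drivers & enrichment, writing every stage
product as TSV plus a JSON run manifest (config echo, seed, output hashes).
Stage order mirrors the analysis: change-point detection, GA optimisation,
then per-segment modelling.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (AnalysisConfig, LongitudinalCountTable, PhylogeneticTree,
                 ValidationError, read_count_table, read_newick,
                 write_count_table, write_newick, stage_seed)
from .synthetic_data import SyntheticDesign, generate
from . import preprocess as prep
from . import diversity as div
from . import community_stats as cstats
from .lmm import fit_alpha_trend
from . import segmentation as seg
from . import persistence_dynamics as pdyn
from . import drivers_enrichment as drv

logger = logging.getLogger("microdyn")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, Path]) -> None:
        hashes = {}
        for name, path in outputs.items():
            h = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
            hashes[name] = {"path": str(path), "sha256_16": h}
        self.stages.append({"stage": stage, "outputs": hashes})

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "seed": self.seed, "stages": self.stages},
            indent=2))


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return path


def run_all(config: AnalysisConfig, outdir,
            counts_path=None, metadata_path=None, tree_path=None,
            design: SyntheticDesign | None = None,
            index: str = "bray_curtis") -> RunManifest:
    """Run every stage on real input files or on a synthetic draw.

    Provide either (counts_path, metadata_path[, tree_path]) or a
    :class:`SyntheticDesign` (``design``); with neither, the default
    synthetic design seeded from the config is used.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), seed=config.seed)
    tree: PhylogeneticTree | None = None

    # --- input / generation -------------------------------------------------
    stage = "generate"
    try:
        if counts_path is not None:
            if metadata_path is None:
                raise ValidationError("counts file given without metadata")
            table = read_count_table(counts_path, metadata_path)
            if tree_path is not None:
                tree = read_newick(tree_path)
        else:
            d = design or SyntheticDesign(seed=stage_seed(config.seed, "synthetic"))
            table, tree = generate(d)
            write_count_table(table, out / "counts.tsv", out / "metadata.tsv")
            write_newick(tree, out / "tree.nwk")
            (out / "design.json").write_text(json.dumps(d.to_dict(), indent=2))
            manifest.record(stage, {"counts": out / "counts.tsv",
                                    "metadata": out / "metadata.tsv",
                                    "tree": out / "tree.nwk",
                                    "design": out / "design.json"})
    except Exception as e:                       # noqa: BLE001
        raise StageError(stage, e) from e

    # --- preprocessing ------------------------------------------------------
    stage = "preprocess"
    try:
        filtered = prep.filter_rare(table, config.prevalence_fraction,
                                    config.min_abundance)
        removed = sorted(set(table.asv_ids) - set(filtered.asv_ids))
        scaled_all = prep.scale_counts(table)        # alpha diversity input
        scaled = prep.scale_counts(filtered)         # beta diversity input
        transformed = prep.wisconsin_sqrt(scaled)
        rep = pd.DataFrame({"removed_asv": removed})
        outputs = {"filter_report": _write(rep, out / "filter_report.tsv")}
        norm_df = pd.DataFrame(transformed.values,
                               index=pd.Index(transformed.asv_ids, name="asv_id"),
                               columns=transformed.sample_ids)
        norm_df.to_csv(out / "normalized.tsv", sep="\t")
        outputs["normalized"] = out / "normalized.tsv"
        manifest.record(stage, outputs)
    except Exception as e:                       # noqa: BLE001
        raise StageError(stage, e) from e

    # --- diversity ----------------------------------------------------------
    stage = "diversity"
    try:
        alpha = pd.DataFrame({
            "sample_id": scaled_all.sample_ids,
            "subject_id": [s.subject_id for s in scaled_all.samples],
            "day": [s.day for s in scaled_all.samples],
            "inverse_simpson": [div.inverse_simpson(scaled_all.values[:, j])
                                for j in range(len(scaled_all.samples))],
        })
        alpha_fit = fit_alpha_trend(alpha["inverse_simpson"], alpha["day"],
                                    alpha["subject_id"])
        beta_input = transformed if index in ("bray_curtis", "sorensen") else scaled
        dmat = div.distance_matrix(beta_input, index,
                                   tree if index.endswith("unifrac") else None)
        within = div.within_subject_series(beta_input, index,
                                           tree if index.endswith("unifrac") else None)
        between = div.between_subjects_series(beta_input, index,
                                              tree if index.endswith("unifrac") else None)
        dmat.to_frame().to_csv(out / f"distance_{index}.tsv", sep="\t")
        outputs = {
            "alpha": _write(alpha, out / "alpha.tsv"),
            "alpha_trend": _write(alpha_fit.to_frame(), out / "alpha_trend.tsv"),
            "distance": out / f"distance_{index}.tsv",
            "within": _write(within.to_frame(), out / "within_series.tsv"),
            "between": _write(between.to_frame(), out / "between_series.tsv"),
        }
        manifest.record(stage, outputs)
    except Exception as e:                       # noqa: BLE001
        raise StageError(stage, e) from e

    # --- community statistics -----------------------------------------------
    stage = "community_stats"
    try:
        factors = pd.DataFrame({
            "subject": [s.subject_id for s in beta_input.samples],
            "diet": [s.diet for s in beta_input.samples],
            "day": [s.day for s in beta_input.samples],
        })
        perma = cstats.permanova(dmat, factors, n_perm=config.n_permutations,
                                 seed=stage_seed(config.seed, "permanova"))
        disp_rows = []
        for factor in ("subject", "diet"):
            d_res = cstats.betadisper(dmat, factors[factor])
            disp_rows.append({"factor": factor, "F": d_res.F, "p": d_res.p})
        disp = pd.DataFrame(disp_rows)
        disp["p_adj"] = cstats.bh_adjust(disp["p"])
        ord_res = cstats.nmds(dmat, k=2, n_starts=config.nmds_starts,
                              seed=stage_seed(config.seed, "nmds"))
        coords = pd.DataFrame(ord_res.coordinates, columns=["nmds1", "nmds2"])
        coords.insert(0, "sample_id", ord_res.labels)
        outputs = {
            "permanova": _write(perma.table, out / "permanova.tsv"),
            "dispersion": _write(disp, out / "dispersion.tsv"),
            "nmds": _write(coords, out / "nmds.tsv"),
        }
        manifest.record(stage, outputs)
    except Exception as e:                       # noqa: BLE001
        raise StageError(stage, e) from e

    # --- segmentation -------------------------------------------------------
    stage = "segmentation"
    try:
        ga = seg.GAParams(population=config.ga_population,
                          generations=config.ga_generations,
                          crossover_rate=config.ga_crossover_rate,
                          mutation_rate=config.ga_mutation_rate,
                          elite_fraction=config.ga_elite_fraction)
        results = {}
        for kind, series in (("within", within), ("between", between)):
            detected = seg.detect_candidates(series)
            all_days = sorted(set(int(x) for x in series.days))[:-1]
            ga_res = seg.ga_refine(all_days, series, ga_params=ga,
                                   seed=stage_seed(config.seed, f"ga_{kind}"),
                                   min_segment_transitions=config.min_segment_transitions,
                                   initial_masks=[detected])
            fits = seg.fit_segments(series, ga_res.segmentation)
            tab = seg.segments_table(fits)
            tab.insert(0, "series", kind)
            results[kind] = (ga_res, fits, tab)
        combined = pd.concat([results["within"][2], results["between"][2]])
        (out / "ga_trajectory.json").write_text(json.dumps({
            kind: res[0].trajectory for kind, res in results.items()}))
        outputs = {
            "segments": _write(combined, out / "segments.tsv"),
            "ga_trajectory": out / "ga_trajectory.json",
        }
        manifest.record(stage, outputs)
        within_seg = results["within"][0].segmentation
    except Exception as e:                       # noqa: BLE001
        raise StageError(stage, e) from e

    # --- persistence & networks ---------------------------------------------
    stage = "persistence_dynamics"
    try:
        pm = pdyn.persistence_matrix(filtered, config.detection_threshold)
        clusters = pdyn.dtw_cluster(pm, k=config.cluster_count,
                                    seed=stage_seed(config.seed, "dtw"),
                                    abundance=scaled.values.mean(axis=1))
        pa_fit = pdyn.persistence_abundance_fit(pm, scaled)
        nets = pdyn.build_networks(filtered, config.detection_threshold)
        deltas = pdyn.edge_deltas(nets)
        models = pdyn.edge_models(deltas, config.isolation_end_day)
        centrality = pdyn.degree_centrality(nets)
        rank = pdyn.cluster_rank_tests(centrality, clusters)
        edge_list = pd.DataFrame(
            [(n.day, s, a) for n in nets for (s, a) in sorted(n.edges)],
            columns=["day", "subject_id", "asv_id"])
        cl = pd.DataFrame({"asv_id": list(clusters.labels),
                           "cluster": list(clusters.labels.values())})
        em = pd.concat([models["formed"].to_frame().assign(response="formed"),
                        models["destroyed"].to_frame().assign(response="destroyed")])
        pa = pd.DataFrame([vars(pa_fit)])
        outputs = {
            "clusters": _write(cl, out / "clusters.tsv"),
            "cluster_summary": _write(clusters.summary, out / "cluster_summary.tsv"),
            "persistence_abundance": _write(pa, out / "persistence_abundance.tsv"),
            "edges": _write(edge_list, out / "edges.tsv"),
            "edge_deltas": _write(deltas.frame, out / "edge_deltas.tsv"),
            "edge_models": _write(em, out / "edge_models.tsv"),
            "centrality_tests": _write(rank, out / "centrality_tests.tsv"),
        }
        manifest.record(stage, outputs)
    except Exception as e:                       # noqa: BLE001
        raise StageError(stage, e) from e

    # --- drivers & enrichment -----------------------------------------------
    stage = "drivers_enrichment"
    try:
        within_fits = results["within"][1]
        signs = [int(np.sign(f.slope)) for f in within_fits]
        drivers = {}
        for subject in sorted({s.subject_id for s in scaled.samples}):
            drivers[subject] = drv.asv_trend_models(
                scaled, within_seg, subject, signs,
                alpha=config.significance_level)
        enr = drv.hypergeom_enrichment(drivers, clusters.stable_ids,
                                       scaled.asv_ids)
        dtab = pd.concat([drv.drivers_table(r) for r in drivers.values()])
        outputs = {
            "drivers": _write(dtab, out / "drivers.tsv"),
            "enrichment": _write(drv.enrichment_table(enr), out / "enrichment.tsv"),
        }
        manifest.record(stage, outputs)
    except Exception as e:                       # noqa: BLE001
        raise StageError(stage, e) from e

    manifest.write(out / "manifest.json")
    return manifest
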