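"""End-to-end orchestration: simulate -> DE -> overlaps -> networks -> enrichment.

``run_all`` executes the full analysis from a single :class:`PipelineConfig`,
writing every intermediate and final table under an output directory and
returning a manifest (path -> SHA-256 checksum) so that identical
config + seed reruns are verifiable byte-for-byte.  Stage failures abort
with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sexmir import io_formats
from sexmir.differential_expression import (
    AnalysisThresholds,
    DEResult,
    run_differential_expression,
)
from sexmir.enrichment import overrepresentation_test
from sexmir.io_formats import GeneSetCollection, write_table
from sexmir.mir_target_network import (
    annotate_mir_log2fc,
    background_frequencies,
    chi_squared_target_enrichment,
    classify_associations,
    intersect_target_sources,
    negative_subnetwork,
    select_surviving,
    summarize_network,
)
from sexmir.overlap_analysis import pairwise_overlaps
from sexmir.synthetic_data import SimulationConfig, simulate_experiment

logger = logging.getLogger(__name__)

CONTRAST_BY_SEX = {"male": "stress_in_males", "female": "stress_in_females"}


@dataclass
class PipelineConfig:
    """Everything one full run needs: simulation settings (or input paths),
    analysis thresholds, required prediction sources, and the seed."""

    outdir: Path
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    simulation: SimulationConfig | None = None
    counts_mir: Path | None = None
    counts_mrna: Path | None = None
    design: Path | None = None
    targets: Path | None = None
    gene_sets: Path | None = None
    required_sources: list[str] | None = None
    min_targets: int = 5
    seed: int = 0


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the artifact manifest (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds
    artifacts: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts.append(path)
        return path

    # -- stage: inputs -----------------------------------------------------
    stage = "inputs"
    try:
        if config.simulation is not None:
            sim = config.simulation
            mir_counts, mrna_counts, design, predictions, _truth = simulate_experiment(
                sim, seed=config.seed
            )
            emit("mir_counts.tsv", lambda p: io_formats.write_count_matrix(mir_counts, p))
            emit("mrna_counts.tsv", lambda p: io_formats.write_count_matrix(mrna_counts, p))
            emit("design.csv", lambda p: io_formats.write_design(design, p))
            emit("targets.tsv", lambda p: io_formats.write_target_predictions(predictions, p))
        else:
            mir_counts = io_formats.read_count_matrix(config.counts_mir, "miR")
            mrna_counts = io_formats.read_count_matrix(config.counts_mrna, "mRNA")
            design = io_formats.read_design(config.design)
            predictions = io_formats.read_target_predictions(config.targets)
        gene_sets = (
            io_formats.read_gene_sets(config.gene_sets) if config.gene_sets else None
        )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -- stage: de ---------------------------------------------------------
    stage = "de"
    try:
        de_mrna = run_differential_expression(mrna_counts, design, thresholds)
        de_mir = run_differential_expression(mir_counts, design, thresholds)
        emit("de_mrna.tsv", lambda p: write_table(de_mrna.table, p))
        emit("de_mir.tsv", lambda p: write_table(de_mir.table, p))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -- stage: overlap ----------------------------------------------------
    stage = "overlap"
    try:
        overlap_rows = []
        for assay, de, background in (
            ("mrna", de_mrna, len(de_mrna.table)),
            ("mir", de_mir, len(de_mir.table)),
        ):
            lists = {}
            for sex, contrast in CONTRAST_BY_SEX.items():
                for direction in ("up", "down"):
                    lists[f"{assay}_{sex}_{direction}"] = de.directional_list(
                        contrast, direction
                    )
            for r in pairwise_overlaps(lists, background):
                overlap_rows.append(r.as_row())
        emit("overlaps.tsv", lambda p: write_table(overlap_rows, p))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -- stage: network ----------------------------------------------------
    stage = "network"
    networks = {}
    try:
        sources = config.required_sources or predictions.sources
        universe = set(de_mrna.feature_ids)
        target_map = intersect_target_sources(predictions, sources, universe=universe)
        for sex, contrast in CONTRAST_BY_SEX.items():
            mir_dirs = de_mir.directions(contrast)
            de_mir_dirs = mir_dirs[mir_dirs != "neutral"]
            background = background_frequencies(de_mrna, contrast)
            enrich = chi_squared_target_enrichment(
                target_map, de_mrna, contrast, de_mir_dirs,
                background=background, min_targets=config.min_targets,
            )
            surviving = select_surviving(enrich, thresholds.network_bh_alpha)
            net = classify_associations(surviving, target_map, de_mrna, contrast)
            annotate_mir_log2fc(net, de_mir, contrast)
            net.validate()
            summary = summarize_network(
                net, de_mrna, contrast, surviving, n_de_mirs=len(de_mir_dirs)
            )
            networks[sex] = (net, summary)
            emit(f"chisq_{sex}.tsv", lambda p, e=enrich: write_table([x.as_row() for x in e], p))
            emit(f"network_{sex}.tsv", lambda p, n=net: io_formats.write_network(n, p, "edge-TSV"))
            emit(
                f"network_{sex}_negative.sif",
                lambda p, n=net: io_formats.write_network(negative_subnetwork(n), p, "SIF"),
            )
            emit(f"network_{sex}.graphml", lambda p, n=net: io_formats.write_network(n, p, "GraphML"))
            emit(f"network_summary_{sex}.tsv", lambda p, s=summary: write_table([s.as_row()], p))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -- stage: enrich -----------------------------------------------------
    stage = "enrich"
    try:
        if gene_sets is not None:
            for sex, contrast in CONTRAST_BY_SEX.items():
                query = de_mrna.directional_list(contrast, "up") + de_mrna.directional_list(
                    contrast, "down"
                )
                res = overrepresentation_test(query, gene_sets, de_mrna.feature_ids)
                emit(
                    f"enrichment_{sex}.tsv",
                    lambda p, r=res: write_table([x.as_row() for x in r], p),
                )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -- manifest ----------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "thresholds": vars(thresholds),
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return manifest
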