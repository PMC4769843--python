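"""End-to-end gene-model reconstruction: assign, cluster, build, report.

Glue that runs the full contig-to-gene-model pipeline with one
:class:`~genecapture.config.RunConfig` and, optionally, writes every report
to an output directory.  All outputs are deterministic for a given config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ioutils
from .capture_align import AlignmentResult, Contig, SeedTranscript, assign_contigs, cluster_by_gene
from .config import RunConfig
from .model_builder import GeneModel, best_model_for_cluster
from .promoter import PromoterCandidate, extract_upstream_candidates, upstream_length_distribution

logger = logging.getLogger(__name__)

#: Default upstream-length histogram bins (nt); the last bin is open-ended
#: in practice because capture fragments rarely reach past ~2 kb of flank.
DEFAULT_BIN_EDGES = [100, 500, 1000, 1500, 2000, 10_000_000]


@dataclass
class PipelineResult:
    alignment: AlignmentResult
    clusters: dict[str, list[str]]
    models: dict[str, GeneModel] = field(default_factory=dict)
    promoter_candidates: list[PromoterCandidate] = field(default_factory=list)
    histogram: pd.DataFrame | None = None


def run_pipeline(
    seeds: list[SeedTranscript],
    contigs: list[Contig],
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
    bin_edges: list[int] | None = None,
) -> PipelineResult:
    """Reconstruct one gene model per seed from capture contigs."""
    config = config or RunConfig()
    bin_edges = bin_edges or DEFAULT_BIN_EDGES
    logger.info("pipeline start: %d seeds, %d contigs, config %s", len(seeds), len(contigs), config.config_hash)
    contig_map = {c.id: c for c in contigs}
    seed_map = {s.id: s for s in seeds}

    alignment = assign_contigs(
        contigs,
        seeds,
        min_identity=config.min_identity,
        min_hsp_len=config.min_hsp_len,
        ambiguity_ratio=config.ambiguity_ratio,
        word_size=config.word_size,
    )
    clusters = cluster_by_gene(alignment.assignments)
    result = PipelineResult(alignment=alignment, clusters=clusters)

    for seed_id, contig_ids in clusters.items():
        seed = seed_map[seed_id]
        cluster_hsps = alignment.cluster_hsps(seed_id, contig_ids)
        model = best_model_for_cluster(
            seed,
            cluster_hsps,
            contig_map,
            overlap_tolerance_nt=config.overlap_tolerance_nt,
            min_intron=config.min_intron,
            max_states=config.max_states,
        )
        if model is not None:
            result.models[seed_id] = model

    all_hsps = [h for hsps in alignment.hsps.values() for h in hsps]
    result.promoter_candidates = extract_upstream_candidates(
        list(result.models.values()),
        contig_map,
        all_hsps,
        seed_map,
        min_upstream=config.min_upstream,
        max_codon=config.max_codon,
    )
    result.histogram = upstream_length_distribution(result.promoter_candidates, bin_edges)

    if outdir is not None:
        write_outputs(result, config, Path(outdir))
    return result


def write_outputs(result: PipelineResult, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_file(outdir / "run_config.txt")
    ioutils.write_assignments_tsv(result.alignment, outdir / "assignments.tsv")
    models = sorted(result.models.values(), key=lambda m: m.seed_id)
    if models:
        ioutils.write_gff3(models, outdir / "models.gff3")
        ioutils.write_fasta(
            ((f"{m.seed_id}_model", m.model_sequence) for m in models),
            outdir / "models.fasta",
        )
        ioutils.write_scores_tsv(models, outdir / "scores.tsv")
    ioutils.write_promoters_tsv(result.promoter_candidates, outdir / "promoters.tsv")
    if result.histogram is not None:
        ioutils.write_histogram_tsv(result.histogram, outdir / "upstream_histogram.tsv")
    logger.info("outputs written to %s", outdir)
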