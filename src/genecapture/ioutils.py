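"""FASTA / GFF3 / TSV readers and writers for pipeline inputs and reports.

Seed transcripts may carry their CDS coordinates in the FASTA description as
a ``cds=START..END`` token (1-based inclusive, as humans write them); the
reader converts to the 0-based half-open coordinates used internally, and
the writer emits them back the same way.  GFF3 output is version 3, 1-based
inclusive, with a gene -> mRNA -> exon hierarchy per model plus one
``match_part`` feature per contributing contig segment carrying a ``Target``
attribute (contig id, start, end, strand in the contig's own coordinates).

All writers order records deterministically so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .capture_align import AlignmentResult, Contig, SeedTranscript
from .model_builder import GeneModel
from .probe_design import Probe
from .promoter import PromoterCandidate
from .structure_compare import GeneStructure, IntronStats, StructureTable

_CDS_RE = re.compile(r"\bcds=(\d+)\.\.(\d+)\b")

GFF_SOURCE = "genecapture"


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a multi-FASTA file into ``(id, description, sequence)`` tuples.

    Ids keep everything up to the first whitespace; empty records are
    rejected.  CRLF line endings are accepted.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, rec.description, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path: str | Path, width: int = 60) -> None:
    """Write ``(id, sequence)`` or ``(id, description, sequence)`` records."""
    seq_records = []
    for rec in records:
        if len(rec) == 2:
            rid, seq = rec
            desc = ""
        else:
            rid, desc, seq = rec
        if not seq:
            raise ValueError(f"refusing to write empty record {rid!r}")
        seq_records.append(SeqRecord(Seq(seq), id=rid, description=desc))
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(seq_records)


def read_contigs(path: str | Path) -> list[Contig]:
    return [Contig(id=rid, sequence=seq) for rid, _, seq in read_fasta(path)]


def read_seeds(path: str | Path) -> list[SeedTranscript]:
    seeds = []
    for rid, desc, seq in read_fasta(path):
        m = _CDS_RE.search(desc)
        if m:
            start1, end1 = int(m.group(1)), int(m.group(2))
            seeds.append(SeedTranscript(id=rid, sequence=seq, cds_start=start1 - 1, cds_end=end1))
        else:
            seeds.append(SeedTranscript(id=rid, sequence=seq))
    return seeds


def write_seeds(seeds: list[SeedTranscript], path: str | Path) -> None:
    records = []
    for seed in sorted(seeds, key=lambda s: s.id):
        desc = f"cds={seed.cds_start + 1}..{seed.cds_end}" if seed.cds_start is not None else ""
        records.append((seed.id, desc, seed.sequence))
    write_fasta(records, path)


def _gff_attrs(**kwargs: str) -> str:
    return ";".join(f"{k}={v}" for k, v in kwargs.items() if v)


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    """Write finalized gene models as GFF3 on their model-sequence coordinates."""
    lines = ["##gff-version 3"]
    for model in sorted(models, key=lambda m: m.seed_id):
        if not model.model_sequence:
            raise ValueError(f"model for {model.seed_id!r} must be finalized before GFF3 export")
        seqid = f"{model.seed_id}_model"
        length = len(model.model_sequence)
        lines.append(f"##sequence-region {seqid} 1 {length}")
        gene_id = f"gene:{model.seed_id}"
        mrna_id = f"mRNA:{model.seed_id}"
        attrs = _gff_attrs(ID=gene_id, Name=model.seed_id)
        if model.suspect_repeat:
            attrs += ";suspect_repeat=true"
        lines.append(f"{seqid}\t{GFF_SOURCE}\tgene\t1\t{length}\t.\t+\t.\t{attrs}")
        lines.append(f"{seqid}\t{GFF_SOURCE}\tmRNA\t1\t{length}\t.\t+\t.\t{_gff_attrs(ID=mrna_id, Parent=gene_id)}")
        for i, seg in enumerate(model.segments, start=1):
            if seg.model_span is None:
                raise ValueError(f"model for {model.seed_id!r} has unplaced segments")
            start, end = seg.model_span[0] + 1, seg.model_span[1]
            if start < 1:
                raise RuntimeError("GFF3 coordinate below 1 after conversion")
            lines.append(
                f"{seqid}\t{GFF_SOURCE}\texon\t{start}\t{end}\t.\t+\t.\t"
                f"{_gff_attrs(ID=f'exon:{model.seed_id}.{i}', Parent=mrna_id)}"
            )
        for i, seg in enumerate(model.segments, start=1):
            start, end = seg.model_span[0] + 1, seg.model_span[1]
            c0, c1 = seg.hsp.contig_span_original
            target = f"{seg.contig_id} {c0 + 1} {c1} {seg.hsp.strand}"
            lines.append(
                f"{seqid}\t{GFF_SOURCE}\tmatch_part\t{start}\t{end}\t{seg.hsp.score:.0f}\t+\t.\t"
                f"{_gff_attrs(ID=f'match:{model.seed_id}.{i}', Parent=mrna_id)};Target={target}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_structure_gff3(structures: list[GeneStructure], path: str | Path) -> None:
    """Write annotated gene structures (genomic coordinates) as GFF3."""
    lines = ["##gff-version 3"]
    for s in sorted(structures, key=lambda s: s.gene_id):
        if not s.exon_spans:
            raise ValueError(f"structure {s.gene_id!r} has no genomic exon spans")
        start = s.exon_spans[0][0] + 1
        end = s.exon_spans[-1][1]
        gene_id = f"gene:{s.gene_id}"
        mrna_id = f"mRNA:{s.gene_id}"
        lines.append(f"{s.gene_id}\t{GFF_SOURCE}\tgene\t{start}\t{end}\t.\t+\t.\t{_gff_attrs(ID=gene_id)}")
        lines.append(f"{s.gene_id}\t{GFF_SOURCE}\tmRNA\t{start}\t{end}\t.\t+\t.\t{_gff_attrs(ID=mrna_id, Parent=gene_id)}")
        for i, (es, ee) in enumerate(s.exon_spans, start=1):
            lines.append(
                f"{s.gene_id}\t{GFF_SOURCE}\texon\t{es + 1}\t{ee}\t.\t+\t.\t"
                f"{_gff_attrs(ID=f'exon:{s.gene_id}.{i}', Parent=mrna_id)}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_assignments_tsv(result: AlignmentResult, path: str | Path) -> None:
    """The contig index: which seed each contig supports, and how strongly."""
    rows = [
        {
            "contig_id": a.contig_id,
            "seed_id": a.assigned_seed_id,
            "total_score": a.total_score,
            "n_hsps": a.n_hsps,
            "single_interval": a.single_interval,
            "ambiguous_ids": ",".join(a.ambiguous_seed_ids) or "-",
        }
        for a in sorted(result.assignments, key=lambda a: a.contig_id)
    ]
    rows += [
        {
            "contig_id": cid,
            "seed_id": "-",
            "total_score": 0.0,
            "n_hsps": 0,
            "single_interval": False,
            "ambiguous_ids": "-",
        }
        for cid in sorted(result.unassigned)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.1f")


def write_scores_tsv(models: list[GeneModel], path: str | Path) -> None:
    rows = []
    for m in sorted(models, key=lambda m: m.seed_id):
        if m.score is None:
            raise ValueError(f"model for {m.seed_id!r} is unscored")
        rows.append(
            {
                "seed_id": m.seed_id,
                "recovery_pct": round(m.score.recovery_pct, 2),
                "union_recovery_pct": round(m.score.union_recovery_pct, 2),
                "exon_overlap_pct": round(m.score.exon_overlap_pct, 2),
                "fragmentation_index": m.score.fragmentation_index,
                "suspect_repeat": m.suspect_repeat,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_probes(probes: list[Probe], fasta_path: str | Path, tsv_path: str | Path) -> None:
    ordered = sorted(probes, key=lambda p: (p.seed_id, p.start))
    write_fasta(((f"{p.seed_id}_probe_{p.start}", p.sequence) for p in ordered), fasta_path)
    pd.DataFrame(
        [{"seed_id": p.seed_id, "start": p.start, "zone": p.zone} for p in ordered]
    ).to_csv(tsv_path, sep="\t", index=False)


def write_promoters_tsv(candidates: list[PromoterCandidate], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "seed_id": c.seed_id,
                "contig_id": c.contig_id,
                "upstream_length": c.upstream_length,
                "covers_codon": c.covers_codon,
            }
            for c in sorted(candidates, key=lambda c: (c.seed_id, c.contig_id))
        ],
        columns=["seed_id", "contig_id", "upstream_length", "covers_codon"],
    ).to_csv(path, sep="\t", index=False)


def write_histogram_tsv(histogram: pd.DataFrame, path: str | Path) -> None:
    histogram.to_csv(path, sep="\t", index=False)


def write_structure_tables(table: StructureTable, exon_path: str | Path, intron_path: str | Path) -> None:
    """Render structure matrices; incomplete introns are starred."""
    exon = table.exon_matrix.copy()
    exon["equal"] = table.exon_equal
    exon.to_csv(exon_path, sep="\t", index_label="exon", float_format="%.0f")

    intron = table.intron_matrix.copy()
    rendered = intron.copy().astype(object)
    for col in intron.columns:
        for idx in intron.index:
            v = intron.loc[idx, col]
            if pd.isna(v):
                rendered.loc[idx, col] = ""
            else:
                star = "*" if table.intron_incomplete.loc[idx, col] else ""
                rendered.loc[idx, col] = f"{int(v)}{star}"
    rendered["equal"] = table.intron_equal
    rendered.to_csv(intron_path, sep="\t", index_label="intron")


def write_intron_stats_tsv(stats: IntronStats, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_set_id": stats.gene_set_id,
                "n": stats.n,
                "mean": round(stats.mean, 2),
                "median": stats.median,
                "q1": stats.q1,
                "q3": stats.q3,
                "outliers": ",".join(str(v) for v in stats.outliers) or "-",
            }
        ]
    ).to_csv(path, sep="\t", index=False)
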