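"""Ground-truth synthetic genes and simulated capture contigs.

Every pipeline stage is testable offline against genes generated here: a
synthetic gene carries a known exon/intron/UTR structure, canonical GT..AG
introns, an ATG..stop open reading frame free of internal stops, and flanking
intergenic sequence, all emitted deterministically from an integer seed.
Background base composition is ~38 % GC, matching conifer genomic DNA.

The contig simulator emulates what a capture-and-assemble experiment
produces from such a gene: genomic fragments centred on exons (capture
probes pull exonic sequence, so fragments cluster there), fragments spanning
exon/intron junctions, optional diverged intronless copies that mimic
processed pseudogenes, optional fragments with a tandemly duplicated exon
(the repeat failure mode), and optional fragments reaching into the 5'
flank (promoter capture).  A truth table records each contig's source
interval and scenario so tests can recount anything directly.

The asparagine synthetase 1 (AS1) fixture packages the exon and intron
lengths of the maritime pine AS1 gene as determined from BAC sequencing,
giving a realistic 14-exon structure (2,507 nt of exons, 1,916 nt of
introns, 1,782 nt CDS, 593 aa protein) for desk-scale testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .capture_align import Contig, SeedTranscript

#: Background base probabilities for A, C, G, T (~38 % GC).
_BASE_P = (0.31, 0.19, 0.19, 0.31)
_BASES = "ACGT"

_STOPS = ("TAA", "TAG", "TGA")

#: Exon lengths (nt) of the maritime pine asparagine synthetase 1 (AS1)
#: gene, from BAC-derived annotation.
AS1_EXON_LENGTHS = (808, 139, 96, 142, 96, 98, 162, 81, 222, 135, 81, 87, 108, 252)

#: Intron lengths (nt) of the same gene.
AS1_INTRON_LENGTHS = (225, 101, 426, 119, 88, 132, 219, 104, 87, 92, 139, 89, 95)


@dataclass(frozen=True)
class SyntheticGene:
    """A generated genomic sequence with known structure."""

    gene_id: str
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    utr5: int
    utr3: int
    flank5: int
    flank3: int
    genomic_seq: str
    transcript_seq: str
    protein_seq: str
    rng_seed: int

    @property
    def cds_len(self) -> int:
        return sum(self.exon_lengths) - self.utr5 - self.utr3

    @property
    def body_start(self) -> int:
        """Genomic coordinate of the first exon start."""
        return self.flank5

    @property
    def body_end(self) -> int:
        return len(self.genomic_seq) - self.flank3

    @property
    def exon_genomic_spans(self) -> tuple[tuple[int, int], ...]:
        spans = []
        pos = self.flank5
        for i, ex in enumerate(self.exon_lengths):
            spans.append((pos, pos + ex))
            pos += ex
            if i < len(self.intron_lengths):
                pos += self.intron_lengths[i]
        return tuple(spans)

    def seed_transcript(self) -> SeedTranscript:
        return SeedTranscript(
            id=self.gene_id,
            sequence=self.transcript_seq,
            cds_start=self.utr5,
            cds_end=self.utr5 + self.cds_len,
        )


@dataclass(frozen=True)
class ContigSimConfig:
    """Scenario switches and fragment-size model for contig simulation.

    Fragment lengths follow a normal distribution (capture libraries are
    sheared to ~1.5 kb) clipped to ``[fragment_min, fragment_max]``;
    ``coverage`` is the number of exon-centred fragments emitted per gene.
    """

    fragment_mean: float = 1500.0
    fragment_sd: float = 300.0
    fragment_min: int = 500
    fragment_max: int = 2500
    coverage: int = 20
    exon_fragments: bool = True
    junction_spanning: bool = True
    intronless_pseudogene: bool = False
    pseudogene_divergence: float = 0.05
    repeat_duplication: bool = False
    upstream_flank_capture: bool = False
    upstream_flank_max: int = 1500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pseudogene_divergence <= 1.0):
            raise ValueError("pseudogene_divergence must be in [0, 1]")
        if self.coverage < 0:
            raise ValueError("coverage must be non-negative")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    if length <= 0:
        return ""
    return "".join(rng.choice(list(_BASES), size=length, p=_BASE_P))


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + internal sense codons + stop codon; no in-frame internal stop."""
    if length % 3:
        raise ValueError("CDS length must be divisible by 3")
    if length < 6:
        raise ValueError("CDS must hold at least a start and a stop codon")
    codons = ["ATG"]
    for _ in range(length // 3 - 2):
        while True:
            codon = _random_seq(rng, 3)
            if codon not in _STOPS:
                codons.append(codon)
                break
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def _random_intron(rng: np.random.Generator, length: int) -> str:
    if length < 4:
        raise ValueError("intron length must be >= 4 to carry GT..AG ends")
    return "GT" + _random_seq(rng, length - 4) + "AG"


def make_gene(
    gene_id: str,
    exon_lengths: list[int] | tuple[int, ...],
    intron_lengths: list[int] | tuple[int, ...],
    utr5: int = 50,
    utr3: int = 50,
    flank5: int = 1500,
    flank3: int = 1500,
    rng_seed: int = 0,
) -> SyntheticGene:
    """Generate a synthetic gene with the requested structure.

    The transcript is the exact splice of the genomic sequence, the CDS
    starts with ATG and ends with a stop codon, and all introns are
    GT..AG.  Identical arguments always yield identical sequences.
    """
    exon_lengths = tuple(int(x) for x in exon_lengths)
    intron_lengths = tuple(int(x) for x in intron_lengths)
    if len(intron_lengths) != len(exon_lengths) - 1:
        raise ValueError("need exactly one fewer intron than exons")
    if utr5 >= exon_lengths[0]:
        raise ValueError("5'UTR must be shorter than the first exon")
    if utr3 >= exon_lengths[-1]:
        raise ValueError("3'UTR must be shorter than the last exon")
    cds_len = sum(exon_lengths) - utr5 - utr3
    rng = np.random.default_rng(rng_seed)

    transcript = _random_seq(rng, utr5) + _random_cds(rng, cds_len) + _random_seq(rng, utr3)
    pieces = []
    pos = 0
    for i, ex in enumerate(exon_lengths):
        pieces.append(transcript[pos : pos + ex])
        pos += ex
        if i < len(intron_lengths):
            pieces.append(_random_intron(rng, intron_lengths[i]))
    genomic = _random_seq(rng, flank5) + "".join(pieces) + _random_seq(rng, flank3)
    protein = str(Seq(transcript[utr5 : utr5 + cds_len - 3]).translate())
    return SyntheticGene(
        gene_id=gene_id,
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
        utr5=utr5,
        utr3=utr3,
        flank5=flank5,
        flank3=flank3,
        genomic_seq=genomic,
        transcript_seq=transcript,
        protein_seq=protein,
        rng_seed=rng_seed,
    )


def validate_gene(gene: SyntheticGene) -> None:
    """Check all structural invariants of a synthetic gene; raise on breach."""
    spliced = "".join(gene.genomic_seq[s:e] for s, e in gene.exon_genomic_spans)
    if spliced != gene.transcript_seq:
        raise AssertionError("transcript is not the splice of the genomic sequence")
    if gene.cds_len != sum(gene.exon_lengths) - gene.utr5 - gene.utr3:
        raise AssertionError("CDS arithmetic broken")
    pos = gene.flank5
    for i, ex in enumerate(gene.exon_lengths):
        pos += ex
        if i < len(gene.intron_lengths):
            intron = gene.genomic_seq[pos : pos + gene.intron_lengths[i]]
            if not (intron.startswith("GT") and intron.endswith("AG")):
                raise AssertionError(f"intron {i + 1} lacks GT..AG ends")
            pos += gene.intron_lengths[i]
    cds = gene.transcript_seq[gene.utr5 : gene.utr5 + gene.cds_len]
    if not cds.startswith("ATG") or cds[-3:] not in _STOPS:
        raise AssertionError("CDS must start ATG and end with a stop codon")
    for i in range(3, gene.cds_len - 3, 3):
        if cds[i : i + 3] in _STOPS:
            raise AssertionError("internal in-frame stop codon")


def as1_fixture() -> SyntheticGene:
    """The 14-exon asparagine synthetase 1 (AS1) fixture gene.

    Exon and intron lengths follow the BAC-derived maritime pine AS1
    annotation; the UTR split (500 nt 5'UTR, 225 nt 3'UTR) is a packaging
    convention chosen so the CDS is 1,782 nt and the protein 593 aa.
    """
    return make_gene(
        gene_id="AS1",
        exon_lengths=AS1_EXON_LENGTHS,
        intron_lengths=AS1_INTRON_LENGTHS,
        utr5=500,
        utr3=225,
        flank5=1000,
        flank3=1000,
        rng_seed=1782,
    )


def demo_genes(rng_seed: int = 101) -> list[SyntheticGene]:
    """Five small multi-exon genes used by the packaged demo simulation.

    Structures span one to five exons with plant-typical exon (90-300 nt)
    and intron (80-140 nt) sizes, small enough that a single ~1.5 kb capture
    fragment can span a whole gene body.
    """
    specs = [
        ("g1", (300,), (), 45, 45),
        ("g2", (220, 180), (110,), 50, 50),
        ("g3", (180, 140, 200), (120, 90), 50, 50),
        ("g4", (150, 120, 90, 160), (100, 140, 80), 50, 50),
        ("g5", (200, 130, 110, 140, 170), (90, 110, 100, 120), 45, 45),
    ]
    return [
        make_gene(gid, exons, introns, utr5, utr3, flank5=1500, flank3=1500, rng_seed=rng_seed + i)
        for i, (gid, exons, introns, utr5, utr3) in enumerate(specs)
    ]


@dataclass
class SimulatedCapture:
    contigs: list[Contig] = field(default_factory=list)
    truth: pd.DataFrame | None = None


def simulate_capture_contigs(gene: SyntheticGene, config: ContigSimConfig) -> SimulatedCapture:
    """Emit capture contigs for one gene according to the enabled scenarios.

    Each contig's orientation is randomised (assemblers emit either strand).
    The truth table has one row per contig: scenario, genomic source
    interval (template coordinates for pseudogene/repeat contigs), strand
    and any scenario-specific quantity (upstream flank length, divergence).
    """
    rng = np.random.default_rng(config.rng_seed)
    g = gene.genomic_seq
    records: list[dict] = []
    contigs: list[Contig] = []

    def emit(name: str, seq: str, scenario: str, start, end, extra: float = np.nan) -> None:
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        contigs.append(Contig(id=name, sequence=seq, source_tag="sim"))
        records.append(
            {
                "contig_id": name,
                "gene_id": gene.gene_id,
                "scenario": scenario,
                "genomic_start": start,
                "genomic_end": end,
                "strand": strand,
                "extra": extra,
            }
        )

    def fragment_around(center: int) -> tuple[int, int]:
        length = int(np.clip(rng.normal(config.fragment_mean, config.fragment_sd), config.fragment_min, config.fragment_max))
        start = max(0, center - length // 2)
        end = min(len(g), start + length)
        return start, end

    exon_spans = gene.exon_genomic_spans
    if config.exon_fragments and config.coverage > 0:
        weights = np.array([e - s for s, e in exon_spans], dtype=float)
        weights /= weights.sum()
        for i in range(config.coverage):
            idx = rng.choice(len(exon_spans), p=weights)
            s, e = exon_spans[idx]
            center = int(rng.integers(s, e))
            fs, fe = fragment_around(center)
            emit(f"{gene.gene_id}_frag{i:03d}", g[fs:fe], "exon_fragment", fs, fe)

    if config.junction_spanning:
        for j in range(len(gene.intron_lengths)):
            fs = exon_spans[j][0]
            fe = exon_spans[j + 1][1]
            emit(f"{gene.gene_id}_junc{j:02d}", g[fs:fe], "junction_spanning", fs, fe)

    if config.intronless_pseudogene:
        seq = _mutate(rng, gene.transcript_seq, config.pseudogene_divergence)
        emit(f"{gene.gene_id}_psg", seq, "intronless_pseudogene", np.nan, np.nan, config.pseudogene_divergence)

    if config.repeat_duplication:
        # Tandem-duplicate a middle exon in the gene body and emit the
        # duplicated body as one contig, as a repeat-bearing locus would.
        k = len(exon_spans) // 2 if len(exon_spans) > 1 else 0
        s, e = exon_spans[k]
        body = g[gene.body_start : s] + g[s:e] + g[s:e] + g[e : gene.body_end]
        emit(f"{gene.gene_id}_rep", body, "repeat_duplication", gene.body_start, gene.body_end, float(k))

    if config.upstream_flank_capture:
        upstream = int(rng.integers(0, config.upstream_flank_max + 1))
        fs = gene.body_start - upstream
        if fs < 0:
            upstream += fs
            fs = 0
        fe = exon_spans[0][1]
        emit(f"{gene.gene_id}_ups", g[fs:fe], "upstream_flank", fs, fe, float(upstream))

    truth = pd.DataFrame.from_records(
        records,
        columns=["contig_id", "gene_id", "scenario", "genomic_start", "genomic_end", "strand", "extra"],
    )
    return SimulatedCapture(contigs=contigs, truth=truth)


def simulate_capture(genes: list[SyntheticGene], config: ContigSimConfig) -> SimulatedCapture:
    """Simulate capture over several genes with per-gene derived seeds."""
    all_contigs: list[Contig] = []
    frames = []
    for i, gene in enumerate(genes):
        sub = replace(config, rng_seed=(config.rng_seed * 1_000 + i) % (2**31))
        sim = simulate_capture_contigs(gene, sub)
        all_contigs.extend(sim.contigs)
        frames.append(sim.truth)
    truth = pd.concat(frames, ignore_index=True) if frames else None
    return SimulatedCapture(contigs=all_contigs, truth=truth)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = _BASES[(_BASES.index(out[i]) + int(rng.integers(1, 4))) % 4] if out[i] in _BASES else out[i]
    return "".join(out)
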