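"""Contig-to-seed alignment, gene assignment and per-gene clustering.

Targeted gene capture enriches genomic DNA for fragments that hybridise to
probes designed from full-length transcripts ("seeds").  After assembly the
resulting contigs are a mixture of exon fragments, intron-containing
fragments, upstream flanks and pseudogene-like intronless copies.  The first
stage of gene-model reconstruction aligns every contig against every seed
transcript, keeps high-identity local alignment segments (HSPs), assigns each
contig to the single seed it matches best, and groups contigs into per-gene
clusters.

The aligner here is a word-anchored, ungapped seed-and-extend scheme: exact
k-mers shared between contig and seed are grouped by alignment diagonal,
merged into runs, and extended with an X-drop criterion.  Because contigs and
seeds come from the same species, high-identity ungapped segments are the
expected signal; indel-containing alignments simply split into multiple HSPs
on adjacent diagonals.  An HSP's score is the number of identical bases it
contains, so that per-seed total scores are directly comparable across seeds
of different divergence.

All HSP coordinates are 0-based half-open and reported with the contig
flipped into seed orientation; the flip is recorded in ``Hsp.strand``.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

#: X-drop extension parameters: match reward, mismatch penalty and drop-off.
_MATCH = 1
_MISMATCH = -2
_XDROP = 20

#: Anchors on the same diagonal closer than this are merged into one run.
_MAX_ANCHOR_GAP = 50


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class SeedTranscript:
    """A full-length transcript used as the template a gene model must cover.

    ``cds_start``/``cds_end`` are 0-based half-open coordinates of the coding
    region within the transcript, when known.
    """

    id: str
    sequence: str
    cds_start: int | None = None
    cds_end: int | None = None
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("seed transcript requires a non-empty id")
        if not self.sequence:
            raise ValueError(f"seed {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        if set(seq) - _VALID_BASES:
            bad = sorted(set(seq) - _VALID_BASES)
            raise ValueError(f"seed {self.id!r}: invalid characters {bad}")
        object.__setattr__(self, "sequence", seq)
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"seed {self.id!r}: cds_start and cds_end must be given together")
        if self.cds_start is not None:
            if not (0 <= self.cds_start < self.cds_end <= len(seq)):
                raise ValueError(f"seed {self.id!r}: CDS [{self.cds_start}, {self.cds_end}) out of bounds")
            if (self.cds_end - self.cds_start) % 3:
                raise ValueError(f"seed {self.id!r}: CDS length not divisible by 3")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds_len(self) -> int | None:
        if self.cds_start is None:
            return None
        return self.cds_end - self.cds_start


@dataclass(frozen=True)
class Contig:
    """An assembled capture fragment."""

    id: str
    sequence: str
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig requires a non-empty id")
        if not self.sequence:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Hsp:
    """A high-scoring (ungapped) alignment segment between a contig and a seed.

    Contig coordinates are given on the contig *after* flipping it into seed
    orientation; ``strand`` records whether a flip happened.  ``score`` is the
    number of identical bases in the segment.  ``contig_length`` is carried
    along so that seed-orientation coordinates can be mapped back to the
    original contig without a lookup.
    """

    contig_id: str
    seed_id: str
    contig_start: int
    contig_end: int
    seed_start: int
    seed_end: int
    strand: str
    identity_fraction: float
    score: float
    contig_length: int

    def __post_init__(self) -> None:
        if self.contig_end <= self.contig_start or self.seed_end <= self.seed_start:
            raise ValueError("HSP spans must be non-empty half-open intervals")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def seed_span(self) -> tuple[int, int]:
        return (self.seed_start, self.seed_end)

    @property
    def contig_span_original(self) -> tuple[int, int]:
        """Span on the contig in its original (input) orientation."""
        if self.strand == "+":
            return (self.contig_start, self.contig_end)
        return (self.contig_length - self.contig_end, self.contig_length - self.contig_start)


@dataclass(frozen=True)
class GeneAssignment:
    """The seed a contig was assigned to, with near-best alternatives."""

    contig_id: str
    assigned_seed_id: str
    ambiguous_seed_ids: tuple[str, ...]
    total_score: float
    n_hsps: int
    single_interval: bool


@dataclass
class AlignmentResult:
    """Assignments plus the retained HSPs backing them.

    ``hsps`` maps ``(contig_id, seed_id)`` to the retained HSP list for every
    contig/seed pair with at least one hit (not only the assigned pair), so
    downstream stages can re-examine ambiguous matches.
    """

    assignments: list[GeneAssignment] = field(default_factory=list)
    unassigned: list[str] = field(default_factory=list)
    hsps: dict[tuple[str, str], list[Hsp]] = field(default_factory=dict)

    def cluster_hsps(self, seed_id: str, contig_ids: list[str]) -> list[Hsp]:
        """All retained HSPs between a seed and the given contigs."""
        out: list[Hsp] = []
        for cid in contig_ids:
            out.extend(self.hsps.get((cid, seed_id), ()))
        return sorted(out, key=lambda h: (h.seed_start, h.seed_end, h.contig_id, h.contig_start))


def _kmer_index(sequence: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(sequence) - k + 1):
        word = sequence[i : i + k]
        if "N" not in word:
            index[word].append(i)
    return index


def _extend_right(cseq: str, sseq: str, ci: int, si: int) -> int:
    """Best X-drop extension length to the right starting at (ci, si)."""
    best_off = 0
    best_score = 0
    score = 0
    off = 0
    limit = min(len(cseq) - ci, len(sseq) - si)
    while off < limit:
        score += _MATCH if cseq[ci + off] == sseq[si + off] else _MISMATCH
        off += 1
        if score > best_score:
            best_score = score
            best_off = off
        elif best_score - score > _XDROP:
            break
    return best_off


def _extend_left(cseq: str, sseq: str, ci: int, si: int) -> int:
    """Best X-drop extension length to the left ending just before (ci, si)."""
    best_off = 0
    best_score = 0
    score = 0
    off = 0
    limit = min(ci, si)
    while off < limit:
        score += _MATCH if cseq[ci - 1 - off] == sseq[si - 1 - off] else _MISMATCH
        off += 1
        if score > best_score:
            best_score = score
            best_off = off
        elif best_score - score > _XDROP:
            break
    return best_off


def _scan_one_strand(
    cseq: str,
    seed_index: dict[str, list[int]],
    sseq: str,
    k: int,
    min_identity: float,
    min_hsp_len: int,
) -> list[tuple[int, int, int, int, int]]:
    """Ungapped HSP spans for one contig orientation.

    Returns tuples ``(contig_start, contig_end, seed_start, seed_end, matches)``.
    """
    diagonals: dict[int, list[int]] = defaultdict(list)
    for ci in range(len(cseq) - k + 1):
        word = cseq[ci : ci + k]
        if "N" in word:
            continue
        for si in seed_index.get(word, ()):
            diagonals[ci - si].append(ci)

    spans: set[tuple[int, int, int, int]] = set()
    for diag in sorted(diagonals):
        anchors = sorted(diagonals[diag])
        runs: list[tuple[int, int]] = []
        run_start = anchors[0]
        prev = anchors[0]
        for ci in anchors[1:]:
            if ci - prev > _MAX_ANCHOR_GAP:
                runs.append((run_start, prev + k))
                run_start = ci
            prev = ci
        runs.append((run_start, prev + k))

        for c0, c1 in runs:
            s0 = c0 - diag
            left = _extend_left(cseq, sseq, c0, s0)
            right = _extend_right(cseq, sseq, c1, c1 - diag)
            spans.add((c0 - left, c1 + right, s0 - left, (c1 - diag) + right))

    out = []
    for c0, c1, s0, s1 in spans:
        length = c1 - c0
        if length < min_hsp_len:
            continue
        matches = sum(1 for i in range(length) if cseq[c0 + i] == sseq[s0 + i])
        if matches / length >= min_identity:
            out.append((c0, c1, s0, s1, matches))
    return out


def find_hsps(
    contig: Contig,
    seed: SeedTranscript,
    min_identity: float = 0.90,
    min_hsp_len: int = 30,
    word_size: int = 11,
) -> list[Hsp]:
    """Find maximal-scoring ungapped local alignment segments on either strand.

    Segments shorter than ``min_hsp_len`` or below ``min_identity`` are
    dropped, as are segments contained (on both contig and seed) within a
    higher-scoring segment on the same strand.  Results are sorted by
    ``seed_start``.
    """
    if min_hsp_len < 1:
        raise ValueError("min_hsp_len must be >= 1")
    if not (0.0 < min_identity <= 1.0):
        raise ValueError("min_identity must be in (0, 1]")
    if not contig.sequence or not seed.sequence:
        raise ValueError("empty sequence")
    k = min(word_size, min_hsp_len)

    seed_index = _kmer_index(seed.sequence, k)
    raw: list[tuple[str, tuple[int, int, int, int, int]]] = []
    for strand, cseq in (("+", contig.sequence), ("-", reverse_complement(contig.sequence))):
        for span in _scan_one_strand(cseq, seed_index, seed.sequence, k, min_identity, min_hsp_len):
            raw.append((strand, span))

    # Drop segments contained within a higher-scoring one on the same strand.
    raw.sort(key=lambda item: (-item[1][4], item[1][2], item[1][0], item[0]))
    kept: list[tuple[str, tuple[int, int, int, int, int]]] = []
    for strand, (c0, c1, s0, s1, matches) in raw:
        contained = False
        for kstrand, (kc0, kc1, ks0, ks1, _) in kept:
            if kstrand == strand and kc0 <= c0 and c1 <= kc1 and ks0 <= s0 and s1 <= ks1:
                contained = True
                break
        if not contained:
            kept.append((strand, (c0, c1, s0, s1, matches)))

    hsps = [
        Hsp(
            contig_id=contig.id,
            seed_id=seed.id,
            contig_start=c0,
            contig_end=c1,
            seed_start=s0,
            seed_end=s1,
            strand=strand,
            identity_fraction=matches / (c1 - c0),
            score=float(matches),
            contig_length=len(contig),
        )
        for strand, (c0, c1, s0, s1, matches) in kept
    ]
    hsps.sort(key=lambda h: (h.seed_start, h.seed_end, h.contig_start, h.strand))
    return hsps


def _merged_interval_count(intervals: list[tuple[int, int]]) -> int:
    """Number of disjoint intervals after merging overlapping/abutting ones."""
    count = 0
    end = -1
    for s, e in sorted(intervals):
        if s > end:
            count += 1
            end = e
        else:
            end = max(end, e)
    return count


def assign_contigs(
    contigs: list[Contig],
    seeds: list[SeedTranscript],
    min_identity: float = 0.90,
    min_hsp_len: int = 30,
    ambiguity_ratio: float = 0.90,
    word_size: int = 11,
) -> AlignmentResult:
    """Assign every contig to the seed with the highest total HSP score.

    Seeds whose total score is at least ``ambiguity_ratio`` times the best are
    recorded as ambiguous alternatives.  Contigs without any retained HSP end
    up in ``AlignmentResult.unassigned`` (the discard class).  Score ties are
    broken by lexicographic seed id for determinism.
    """
    if not seeds:
        raise ValueError("at least one seed transcript is required")
    seen: set[str] = set()
    for contig in contigs:
        if contig.id in seen:
            raise ValueError(f"duplicate contig id {contig.id!r}")
        seen.add(contig.id)

    result = AlignmentResult()
    seeds_sorted = sorted(seeds, key=lambda s: s.id)
    for contig in sorted(contigs, key=lambda c: c.id):
        totals: dict[str, float] = {}
        counts: dict[str, int] = {}
        for seed in seeds_sorted:
            hsps = find_hsps(contig, seed, min_identity, min_hsp_len, word_size)
            if hsps:
                result.hsps[(contig.id, seed.id)] = hsps
                totals[seed.id] = sum(h.score for h in hsps)
                counts[seed.id] = len(hsps)
        if not totals:
            result.unassigned.append(contig.id)
            continue
        best_seed = max(totals, key=lambda sid: (totals[sid], sid))
        # Lexicographic tie-break: among equal scores prefer the smallest id.
        best_score = totals[best_seed]
        tied = sorted(sid for sid, sc in totals.items() if sc == best_score)
        best_seed = tied[0]
        ambiguous = tuple(
            sid for sid in sorted(totals) if sid != best_seed and totals[sid] >= ambiguity_ratio * best_score
        )
        best_hsps = result.hsps[(contig.id, best_seed)]
        single = _merged_interval_count([h.seed_span for h in best_hsps]) == 1
        result.assignments.append(
            GeneAssignment(
                contig_id=contig.id,
                assigned_seed_id=best_seed,
                ambiguous_seed_ids=ambiguous,
                total_score=best_score,
                n_hsps=counts[best_seed],
                single_interval=single,
            )
        )
    if result.unassigned:
        logger.info("%d contigs had no retained HSP and were discarded", len(result.unassigned))
    return result


def cluster_by_gene(assignments: list[GeneAssignment]) -> dict[str, list[str]]:
    """Group assigned contigs by their assigned seed.

    Clusters partition the assigned contigs: every contig appears in exactly
    one cluster and empty clusters are omitted.
    """
    seen: set[str] = set()
    clusters: dict[str, list[str]] = defaultdict(list)
    for a in assignments:
        if a.contig_id in seen:
            raise ValueError(f"duplicate contig id {a.contig_id!r} in assignments")
        seen.add(a.contig_id)
        clusters[a.assigned_seed_id].append(a.contig_id)
    return {sid: sorted(cids) for sid, cids in sorted(clusters.items())}
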