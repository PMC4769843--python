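"""Build, score and select gene models from per-gene contig clusters.

A gene model is an ordered tiling of contig alignment segments along a seed
transcript.  Candidate models are subsets of a cluster's contigs in which any
two segments from *different* contigs overlap on the seed by at most a small
tolerance (contigs assembled from the same locus should tile, not stack);
multiple segments of the *same* contig are always kept together, because a
genomic repeat legitimately places one contig region onto the same seed
interval twice and the model must expose that for flagging.

Candidates are scored with four quantities:

* ``recovery_pct`` — percent of the seed covered counting every segment with
  multiplicity; repeats push this above 100 %.
* ``union_recovery_pct`` — percent of seed positions covered at least once.
* ``exon_overlap_pct`` — redundantly covered bases as a percent of the
  covered union; measures how much selected contigs stack on each other.
* ``fragmentation_index`` — number of distinct contigs used; fewer is better.

The best model maximises union recovery, then minimises exon overlap, then
minimises fragmentation; remaining ties are broken on the sorted contig-id
list so that selection is deterministic.  Models whose multiplicity recovery
exceeds 100 % are flagged as repeat-suspect rather than silently truncated.

Intron lengths are only reported where a single contig spans the junction
(both flanking exon segments come from the same contig, separated by a
genomic gap); junctions joined across different contigs are recorded with an
unknown length and the model sequence is joined with an N spacer there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .capture_align import Contig, Hsp, SeedTranscript, reverse_complement

logger = logging.getLogger(__name__)

#: Spacer inserted between segments whose junction is not spanned by one contig.
SPACER_LEN = 50


@dataclass
class ExonSegment:
    """One contig alignment segment used as exon evidence in a model."""

    contig_id: str
    hsp: Hsp
    seed_span: tuple[int, int]
    genomic_span: tuple[int, int]
    model_span: tuple[int, int] | None = None

    @property
    def seed_len(self) -> int:
        return self.seed_span[1] - self.seed_span[0]


@dataclass(frozen=True)
class ModelScore:
    recovery_pct: float
    union_recovery_pct: float
    exon_overlap_pct: float
    fragmentation_index: int


@dataclass(frozen=True)
class OrthologStructure:
    """Exon/intron lengths of an ortholog from a model species.

    ``exon_lengths`` cover the ortholog transcript from the annotated
    transcription start; ``cds_offset`` is the number of leading non-coding
    nucleotides (5'UTR) inside the first exon, so that junction positions can
    be expressed relative to the coding sequence.
    """

    species: str
    gene_id: str
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    cds_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("ortholog must have one fewer intron than exons")


@dataclass
class GeneModel:
    """An ordered tiling of contig segments over one seed transcript."""

    seed_id: str
    segments: list[ExonSegment]
    inferred_introns: list[tuple[int, int | None]] = field(default_factory=list)
    model_sequence: str = ""
    score: ModelScore | None = None
    suspect_repeat: bool = False
    junction_support: list[tuple[int, int, str]] | None = None

    @property
    def contig_ids(self) -> tuple[str, ...]:
        return tuple(sorted({seg.contig_id for seg in self.segments}))


def segments_from_hsps(hsps: list[Hsp]) -> list[ExonSegment]:
    return [
        ExonSegment(
            contig_id=h.contig_id,
            hsp=h,
            seed_span=(h.seed_start, h.seed_end),
            genomic_span=(h.contig_start, h.contig_end),
        )
        for h in hsps
    ]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def refine_junctions(
    cluster_hsps: list[Hsp],
    contigs: dict[str, Contig],
    min_intron: int = 20,
    max_trim: int = 30,
) -> list[Hsp]:
    """Reconcile small seed overlaps between same-contig HSPs at junctions.

    Ungapped extension routinely overruns a splice junction by a few bases
    when intron sequence happens to match the next exon (and vice versa), so
    two HSPs of one contig flanking an intron overlap slightly on the seed.
    Left uncorrected, that overlap double-counts seed positions — inflating
    recovery above 100 % without any genuine repeat — and misplaces the
    intron boundaries.  For each consecutive same-contig, same-strand HSP
    pair separated by an intron-sized genomic gap and overlapping on the
    seed by at most ``max_trim`` nt, the overlap is split at the position
    that makes the intervening contig sequence start GT and end AG (the
    intron length itself does not depend on the split); without a canonical
    split the overlap is divided at its midpoint.
    """
    by_group: dict[tuple[str, str, str], list[Hsp]] = {}
    for h in cluster_hsps:
        by_group.setdefault((h.contig_id, h.seed_id, h.strand), []).append(h)

    refined: list[Hsp] = []
    for (cid, _, strand), hsps in sorted(by_group.items()):
        hsps = sorted(hsps, key=lambda h: (h.seed_start, h.contig_start))
        contig = contigs.get(cid)
        oriented = None
        if contig is not None:
            oriented = contig.sequence if strand == "+" else reverse_complement(contig.sequence)
        for i in range(1, len(hsps)):
            prev, cur = hsps[i - 1], hsps[i]
            v = prev.seed_end - cur.seed_start
            if oriented is None or v <= 0 or v > max_trim:
                continue
            if cur.contig_start - prev.contig_end + v < min_intron:
                continue
            if v >= (prev.seed_end - prev.seed_start) or v >= (cur.seed_end - cur.seed_start):
                continue
            split = None
            for s in range(v + 1):
                istart = prev.contig_end - (v - s)
                iend = cur.contig_start + s
                if oriented[istart : istart + 2] == "GT" and oriented[iend - 2 : iend] == "AG":
                    split = s
                    break
            if split is None:
                split = v // 2
            trim_prev = v - split
            hsps[i - 1] = prev = _trimmed(prev, end_trim=trim_prev)
            hsps[i] = cur = _trimmed(cur, start_trim=split)
        refined.extend(hsps)
    return sorted(refined, key=lambda h: (h.seed_start, h.seed_end, h.contig_id, h.contig_start))


def _trimmed(h: Hsp, start_trim: int = 0, end_trim: int = 0) -> Hsp:
    if start_trim == 0 and end_trim == 0:
        return h
    length = h.contig_end - h.contig_start - start_trim - end_trim
    matches = max(0.0, h.score - start_trim - end_trim)  # conservative: trimmed bases counted as matches
    return Hsp(
        contig_id=h.contig_id,
        seed_id=h.seed_id,
        contig_start=h.contig_start + start_trim,
        contig_end=h.contig_end - end_trim,
        seed_start=h.seed_start + start_trim,
        seed_end=h.seed_end - end_trim,
        strand=h.strand,
        identity_fraction=min(1.0, matches / length),
        score=matches,
        contig_length=h.contig_length,
    )


def _segments_sorted(segments: list[ExonSegment]) -> list[ExonSegment]:
    return sorted(segments, key=lambda s: (s.seed_span, s.contig_id, s.genomic_span))


def build_candidate_models(
    seed: SeedTranscript,
    cluster_hsps: list[Hsp],
    overlap_tolerance_nt: int = 15,
    max_states: int = 200_000,
) -> list[GeneModel]:
    """Enumerate candidate tilings of the seed by cluster contigs.

    A candidate is a set of contigs whose cross-contig segments overlap on
    the seed by at most ``overlap_tolerance_nt``, that cannot be extended by
    a compatible contig adding new seed coverage, and that contains no contig
    whose removal would leave the covered union unchanged (no redundant
    members).  The enumeration is exhaustive up to ``max_states`` visited
    search states; beyond that the list is completed with a deterministic
    greedy candidate and a warning is logged.
    """
    for h in cluster_hsps:
        if h.seed_id != seed.id:
            raise ValueError(f"HSP for seed {h.seed_id!r} passed to cluster of {seed.id!r}")
    if not cluster_hsps:
        return []
    L = len(seed)

    by_contig: dict[str, list[ExonSegment]] = {}
    for seg in segments_from_hsps(cluster_hsps):
        by_contig.setdefault(seg.contig_id, []).append(seg)
    contig_ids = sorted(by_contig)
    n = len(contig_ids)

    cov = np.zeros((n, L), dtype=np.int32)
    for i, cid in enumerate(contig_ids):
        for seg in by_contig[cid]:
            cov[i, seg.seed_span[0] : seg.seed_span[1]] += 1

    conflict = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            for a in by_contig[contig_ids[i]]:
                if any(_overlap(a.seed_span, b.seed_span) > overlap_tolerance_nt for b in by_contig[contig_ids[j]]):
                    conflict[i, j] = conflict[j, i] = True
                    break

    chosen_sets: list[tuple[int, ...]] = []
    states = 0
    truncated = False

    def consider(chosen: list[int], total_cov: np.ndarray) -> None:
        if not chosen:
            return
        covered = total_cov > 0
        chosen_set = set(chosen)
        # Non-augmentable: no compatible contig adds new seed coverage.
        for j in range(n):
            if j in chosen_set:
                continue
            if any(conflict[j, i] for i in chosen):
                continue
            if np.any(cov[j][~covered] > 0):
                return
        # Irredundant: removing any member would shrink the union.
        for i in chosen:
            mine = cov[i] > 0
            if not np.any((total_cov[mine] - cov[i][mine]) == 0):
                return
        chosen_sets.append(tuple(sorted(chosen)))

    def recurse(idx: int, chosen: list[int], total_cov: np.ndarray) -> None:
        nonlocal states, truncated
        states += 1
        if states > max_states:
            truncated = True
            return
        if idx == n:
            consider(chosen, total_cov)
            return
        if not any(conflict[idx, i] for i in chosen):
            chosen.append(idx)
            recurse(idx + 1, chosen, total_cov + cov[idx])
            chosen.pop()
        recurse(idx + 1, chosen, total_cov)

    recurse(0, [], np.zeros(L, dtype=np.int32))

    if truncated:
        logger.warning(
            "seed %s: candidate enumeration truncated at %d states (%d contigs); adding greedy candidate",
            seed.id,
            max_states,
            n,
        )
        chosen_sets.append(_greedy_candidate(cov, conflict))

    models = []
    for chosen in sorted(set(chosen_sets)):
        segs: list[ExonSegment] = []
        for i in chosen:
            segs.extend(by_contig[contig_ids[i]])
        models.append(GeneModel(seed_id=seed.id, segments=_segments_sorted(segs)))
    return models


def _greedy_candidate(cov: np.ndarray, conflict: np.ndarray) -> tuple[int, ...]:
    """Greedy max-new-coverage tiling, then pruned of redundant members."""
    n = cov.shape[0]
    chosen: list[int] = []
    covered = np.zeros(cov.shape[1], dtype=bool)
    while True:
        best, best_gain = None, 0
        for j in range(n):
            if j in chosen or any(conflict[j, i] for i in chosen):
                continue
            gain = int(np.count_nonzero(cov[j][~covered]))
            if gain > best_gain:
                best, best_gain = j, gain
        if best is None:
            break
        chosen.append(best)
        covered |= cov[best] > 0
    total = cov[chosen].sum(axis=0) if chosen else np.zeros(cov.shape[1], dtype=np.int32)
    for i in list(chosen):
        mine = cov[i] > 0
        if not np.any((total[mine] - cov[i][mine]) == 0):
            chosen.remove(i)
            total = total - cov[i]
    return tuple(sorted(chosen))


def score_model(model: GeneModel, seed: SeedTranscript) -> ModelScore:
    """Compute recovery, union recovery, exon overlap and fragmentation."""
    if not model.segments:
        raise ValueError("cannot score an empty model")
    if len(seed) == 0:
        raise ValueError("zero-length seed")
    L = len(seed)
    total = sum(seg.seed_len for seg in model.segments)
    union = 0
    end = -1
    for s, e in sorted(seg.seed_span for seg in model.segments):
        if s > end:
            union += e - s
            end = e
        elif e > end:
            union += e - end
            end = e
    score = ModelScore(
        recovery_pct=100.0 * total / L,
        union_recovery_pct=100.0 * union / L,
        exon_overlap_pct=100.0 * (total - union) / union,
        fragmentation_index=len({seg.contig_id for seg in model.segments}),
    )
    model.score = score
    return score


def select_best_model(candidates: list[GeneModel]) -> GeneModel | None:
    """Pick the best scored candidate.

    Lexicographic criteria: maximal union recovery, then minimal exon
    overlap, then minimal fragmentation index; remaining ties broken on the
    sorted contig-id list.  Returns ``None`` for an empty candidate list.
    """
    if not candidates:
        return None
    for m in candidates:
        if m.score is None:
            raise ValueError("candidates must be scored before selection")
    return min(
        candidates,
        key=lambda m: (
            -m.score.union_recovery_pct,
            m.score.exon_overlap_pct,
            m.score.fragmentation_index,
            m.contig_ids,
        ),
    )


def flag_suspect(model: GeneModel) -> GeneModel:
    """Flag a scored model whose multiplicity recovery exceeds 100 %.

    Recovery above 100 % means some seed interval is represented more than
    once by the selected segments — the signature of an unhandled sequence
    repeat — so the model is marked rather than trusted.
    """
    if model.score is None:
        raise ValueError("model must be scored before flagging")
    model.suspect_repeat = model.score.recovery_pct > 100.0
    return model


def _oriented_sequence(contig: Contig, strand: str) -> str:
    return contig.sequence if strand == "+" else reverse_complement(contig.sequence)


def finalize_model(
    model: GeneModel,
    seed: SeedTranscript,
    contigs: dict[str, Contig],
    min_intron: int = 20,
    spacer_len: int = SPACER_LEN,
) -> GeneModel:
    """Assemble the model sequence and infer intron lengths.

    Segments are concatenated in seed order.  Where two consecutive segments
    come from the same contig (same orientation) with a genomic gap of at
    least ``min_intron``, the intervening contig sequence is retained as an
    intron of known length.  Junctions between different contigs are joined
    with a ``spacer_len`` N spacer and recorded with unknown intron length.
    Same-contig genomic gaps shorter than ``min_intron`` are kept inline as
    exonic sequence (they are alignment hiccups, not introns).
    """
    segments = _segments_sorted(model.segments)
    model.segments = segments
    model.inferred_introns = []
    pieces: list[str] = []
    pos = 0
    for i, seg in enumerate(segments):
        contig = contigs[seg.contig_id]
        oriented = _oriented_sequence(contig, seg.hsp.strand)
        if i > 0:
            prev = segments[i - 1]
            seed_gap = seg.seed_span[0] - prev.seed_span[1]
            same_contig = (
                prev.contig_id == seg.contig_id
                and prev.hsp.strand == seg.hsp.strand
                and seg.genomic_span[0] >= prev.genomic_span[1]
            )
            if same_contig:
                gap = seg.genomic_span[0] - prev.genomic_span[1]
                if gap >= min_intron:
                    model.inferred_introns.append((i - 1, gap))
                    pieces.append(oriented[prev.genomic_span[1] : seg.genomic_span[0]])
                    pos += gap
                elif gap > 0:
                    pieces.append(oriented[prev.genomic_span[1] : seg.genomic_span[0]])
                    pos += gap
            elif seed_gap >= 0:
                model.inferred_introns.append((i - 1, None))
                pieces.append("N" * spacer_len)
                pos += spacer_len
        seg_seq = oriented[seg.genomic_span[0] : seg.genomic_span[1]]
        seg.model_span = (pos, pos + len(seg_seq))
        pieces.append(seg_seq)
        pos += len(seg_seq)
    model.model_sequence = "".join(pieces)
    return model


def apply_ortholog_guidance(
    model: GeneModel,
    ortholog: OrthologStructure,
    seed: SeedTranscript,
    window: int = 10,
) -> GeneModel:
    """Annotate expected exon/exon junctions from an ortholog structure.

    Cumulative ortholog exon lengths (relative to the ortholog CDS start) are
    scaled to the seed CDS length and projected onto seed coordinates.  Each
    projected junction is classified as:

    * ``supported`` — a single contig spans it (an inferred intron lies
      within ``window`` nt of the projected position);
    * ``unsupported`` — the seed is covered through the position but no
      single contig spans the junction;
    * ``missing`` — the model has no coverage at the position.

    Guidance never alters segment selection; it is annotation only.
    """
    if not ortholog.exon_lengths:
        raise ValueError("ortholog must have at least one exon")
    if seed.cds_start is None:
        raise ValueError(f"seed {seed.id!r} has no CDS annotation for guidance")
    support: list[tuple[int, int, str]] = []
    ortho_coding = sum(ortholog.exon_lengths) - ortholog.cds_offset
    cum = 0
    intron_positions = []
    for idx, length in model.inferred_introns:
        if length is not None:
            intron_positions.append(model.segments[idx].seed_span[1])
    covered: list[tuple[int, int]] = sorted(seg.seed_span for seg in model.segments)
    merged: list[tuple[int, int]] = []
    for s, e in covered:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))

    for j, length in enumerate(ortholog.exon_lengths[:-1]):
        cum += length
        rel = cum - ortholog.cds_offset
        pos = seed.cds_start + round(rel * seed.cds_len / ortho_coding)
        if any(abs(pos - q) <= window for q in intron_positions):
            status = "supported"
        elif any(s < pos < e or (s <= pos - 1 and pos + 1 <= e) for s, e in merged):
            status = "unsupported"
        else:
            status = "missing"
        support.append((j, pos, status))
    model.junction_support = support
    return model


def best_model_for_cluster(
    seed: SeedTranscript,
    cluster_hsps: list[Hsp],
    contigs: dict[str, Contig],
    overlap_tolerance_nt: int = 15,
    min_intron: int = 20,
    max_states: int = 200_000,
) -> GeneModel | None:
    """Convenience: refine, enumerate, score, select, finalize and flag."""
    cluster_hsps = refine_junctions(cluster_hsps, contigs, min_intron=min_intron)
    candidates = build_candidate_models(seed, cluster_hsps, overlap_tolerance_nt, max_states)
    for m in candidates:
        score_model(m, seed)
    best = select_best_model(candidates)
    if best is None:
        return None
    finalize_model(best, seed, contigs, min_intron=min_intron)
    return flag_suspect(best)
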