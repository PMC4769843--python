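"""Identify contigs carrying the promoter-proximal 5' upstream region.

A capture contig whose alignment reaches the very start of a gene's coding
sequence and that extends well past the alignment into unaligned sequence is
carrying genomic DNA 5' of the first exon — promoter-proximal sequence that
can seed genome walking or direct functional studies.

A contig qualifies for a gene when one of its HSPs against the gene's seed
covers a coding position at or before codon ``max_codon`` (default 10) and
the contig, in seed orientation, extends at least ``min_upstream`` nt
(default 100) 5' of that HSP's start on the contig.  Both thresholds are
strict boundaries: 100 nt upstream qualifies, 99 does not; codon 10
qualifies, codon 11 does not.  Codon ``k`` covers transcript positions
``[cds_start + 3(k-1), cds_start + 3k)``.

The upstream-length frequency distribution counts gene models, not contigs:
one candidate per gene (the one with the longest upstream stretch) feeds the
histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .capture_align import Contig, Hsp, SeedTranscript
from .model_builder import GeneModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PromoterCandidate:
    """A contig carrying upstream sequence for one gene.

    ``upstream_length`` is the number of contig nucleotides (in seed
    orientation) 5' of the first-exon alignment start; ``covers_codon`` is
    the 1-based index of the earliest seed codon the alignment covers.
    """

    seed_id: str
    contig_id: str
    upstream_length: int
    covers_codon: int


def extract_upstream_candidates(
    models: list[GeneModel],
    contigs: dict[str, Contig],
    hsps: list[Hsp],
    seeds: dict[str, SeedTranscript],
    min_upstream: int = 100,
    max_codon: int = 10,
) -> list[PromoterCandidate]:
    """Find promoter-bearing contigs for every gene with a model.

    All retained HSPs for a gene's cluster are examined (not only those in
    the selected model): a contig that lost the tiling competition can still
    carry the upstream flank.  Genes whose seed lacks a CDS annotation are
    skipped with a warning.
    """
    by_pair: dict[tuple[str, str], list[Hsp]] = {}
    for h in hsps:
        by_pair.setdefault((h.seed_id, h.contig_id), []).append(h)

    candidates: list[PromoterCandidate] = []
    for model in sorted(models, key=lambda m: m.seed_id):
        seed = seeds[model.seed_id]
        if seed.cds_start is None:
            logger.warning("seed %s has no CDS annotation; promoter extraction skipped", seed.id)
            continue
        codon_limit = seed.cds_start + 3 * max_codon
        contig_ids = sorted({h.contig_id for (sid, _), hs in by_pair.items() if sid == seed.id for h in hs})
        for cid in contig_ids:
            if cid not in contigs:
                continue
            qualifying = [
                h
                for h in by_pair.get((seed.id, cid), ())
                if h.seed_start < codon_limit and h.seed_end > seed.cds_start
            ]
            if not qualifying:
                continue
            first = min(qualifying, key=lambda h: (h.seed_start, h.contig_start))
            covers_codon = max(0, first.seed_start - seed.cds_start) // 3 + 1
            upstream = first.contig_start
            if upstream >= min_upstream:
                candidates.append(
                    PromoterCandidate(
                        seed_id=seed.id,
                        contig_id=cid,
                        upstream_length=upstream,
                        covers_codon=covers_codon,
                    )
                )
    return candidates


def best_candidate_per_gene(candidates: list[PromoterCandidate]) -> dict[str, PromoterCandidate]:
    """One candidate per gene: longest upstream, ties by smallest contig id."""
    best: dict[str, PromoterCandidate] = {}
    for cand in sorted(candidates, key=lambda c: (c.seed_id, -c.upstream_length, c.contig_id)):
        best.setdefault(cand.seed_id, cand)
    return best


def upstream_length_distribution(
    candidates: list[PromoterCandidate],
    bin_edges: list[int],
) -> pd.DataFrame:
    """Histogram of per-gene best upstream lengths over half-open bins.

    ``bin_edges`` of length ``n + 1`` define ``n`` bins ``[lo, hi)``.  When
    the edges cover every candidate value, the counts sum to the number of
    genes with at least one qualifying candidate.
    """
    if len(bin_edges) < 2:
        raise ValueError("at least two bin edges are required")
    if any(lo >= hi for lo, hi in zip(bin_edges, bin_edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    best = best_candidate_per_gene(candidates)
    counts = [0] * (len(bin_edges) - 1)
    for cand in best.values():
        for i, (lo, hi) in enumerate(zip(bin_edges, bin_edges[1:])):
            if lo <= cand.upstream_length < hi:
                counts[i] += 1
                break
    return pd.DataFrame(
        {
            "bin_lo": bin_edges[:-1],
            "bin_hi": bin_edges[1:],
            "count": counts,
        }
    )


def upstream_sequences(
    candidates: list[PromoterCandidate],
    contigs: dict[str, Contig],
    hsps: list[Hsp],
) -> list[tuple[str, str]]:
    """Extract the upstream contig sequence for each candidate (seed orientation).

    Returns ``(name, sequence)`` pairs suitable for FASTA output, where the
    sequence is everything 5' of the first-exon alignment start.
    """
    from .capture_align import reverse_complement

    by_pair: dict[tuple[str, str], list[Hsp]] = {}
    for h in hsps:
        by_pair.setdefault((h.seed_id, h.contig_id), []).append(h)
    out = []
    for cand in candidates:
        hs = by_pair.get((cand.seed_id, cand.contig_id), [])
        if not hs:
            continue
        first = min(hs, key=lambda h: (h.seed_start, h.contig_start))
        contig = contigs[cand.contig_id]
        oriented = contig.sequence if first.strand == "+" else reverse_complement(contig.sequence)
        out.append((f"{cand.seed_id}|{cand.contig_id}|upstream", oriented[: first.contig_start]))
    return out
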