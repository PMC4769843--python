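"""Exon/intron structure annotation and cross-gene structure comparison.

Given a genomic sequence and the transcript it splices into, the annotator
finds an ordered chain of transcript segments in the genomic sequence whose
gaps are introns.  Chains are searched left to right with backtracking:
exons are grown by exact extension (single substitutions are tolerated when
the downstream context re-anchors at the same offset), and at each mismatch
the next exon start is located by an anchor search.  Candidate continuations
are tried in preference order — substitution, then introns whose sequence
starts ``GT`` and ends ``AG`` (leftmost first), then short-gap merges, then
non-canonical introns — so the reported chain maximises exonic sequence and
prefers canonical splice sites.  Genomic gaps shorter than ``min_intron``
are never opened as introns; the flanking exons merge across them instead.

Comparison utilities align structures index-by-index (exon 1 with exon 1,
intron 1 with intron 1, ...) across genes or species, flag rows that agree,
and summarise pooled intron lengths with order statistics and Tukey
outliers.  Introns marked *incomplete* (not fully recovered) are excluded
from statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .capture_align import SeedTranscript

logger = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}


class AnnotationError(RuntimeError):
    """Raised when no chain covering the transcript can be found."""


@dataclass(frozen=True)
class GeneStructure:
    """Ordered exon and intron lengths of one gene, with CDS arithmetic.

    ``incomplete_introns`` holds 0-based indices of introns whose sequence
    was not fully recovered; their lengths are lower bounds and they are
    excluded from length statistics.  ``exon_spans`` are genomic coordinates
    (0-based half-open) when the structure came from annotation.
    """

    gene_id: str
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    cds_len: int | None = None
    protein_len: int | None = None
    incomplete_introns: frozenset[int] = frozenset()
    exon_spans: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError(
                f"{self.gene_id}: {len(self.exon_lengths)} exons require "
                f"{len(self.exon_lengths) - 1} introns, got {len(self.intron_lengths)}"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)

    @property
    def n_introns(self) -> int:
        return len(self.intron_lengths)

    @property
    def span(self) -> int:
        """First exon start to last exon end: total exon + intron length."""
        return sum(self.exon_lengths) + sum(self.intron_lengths)


@dataclass(frozen=True)
class IntronStats:
    gene_set_id: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    outliers: tuple[int, ...]


@dataclass
class StructureTable:
    """Index-aligned exon and intron length matrices across genes."""

    exon_matrix: pd.DataFrame
    intron_matrix: pd.DataFrame
    intron_incomplete: pd.DataFrame
    exon_equal: pd.Series
    intron_equal: pd.Series


def _match_len(g: str, t: str, gi: int, ti: int) -> int:
    n = 0
    while gi + n < len(g) and ti + n < len(t) and g[gi + n] == t[ti + n]:
        n += 1
    return n


def _find_all(haystack: str, needle: str, start: int) -> list[int]:
    out = []
    i = haystack.find(needle, start)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def annotate_gene_structure(
    genomic: str,
    transcript: SeedTranscript,
    min_intron: int = 20,
    anchor_len: int = 20,
    max_states: int = 20_000,
) -> GeneStructure:
    """Annotate exon/intron structure by spliced chaining of the transcript.

    The transcript must be the spliced product of the genomic sequence up to
    scattered substitutions.  Raises :class:`AnnotationError` with the best
    covered fraction when no complete chain exists within the search budget.
    """
    g = genomic.upper()
    t = transcript.sequence
    if not g or not t:
        raise ValueError("empty sequence")

    states = 0
    best_progress = 0

    def search(ti: int, gi: int, exon_start: int, exons: list[tuple[int, int]]) -> list[tuple[int, int]] | None:
        nonlocal states, best_progress
        states += 1
        if states > max_states:
            return None
        m = _match_len(g, t, gi, ti)
        ti2, gi2 = ti + m, gi + m
        best_progress = max(best_progress, ti2)
        if ti2 == len(t):
            return exons + [(exon_start, gi2)]

        remaining = len(t) - ti2
        # Substitution: context re-anchors at the same offset one base on.
        k_sub = min(anchor_len, remaining - 1)
        if k_sub > 0 and g[gi2 + 1 : gi2 + 1 + k_sub] == t[ti2 + 1 : ti2 + 1 + k_sub]:
            result = search(ti2 + 1, gi2 + 1, exon_start, exons)
            if result is not None:
                return result

        k = min(anchor_len, remaining)
        anchor = t[ti2 : ti2 + k]
        # Exact extension can overrun a splice junction when the intron
        # starts with the same bases as the next exon; enumerate small
        # junction shifts and prefer the GT..AG-consistent placement
        # (leftmost intron when several shifts are canonical).
        introns_gtag: list[tuple[int, int]] = []  # (p, shift)
        introns_other: list[int] = []
        merges: list[int] = []
        for p in _find_all(g, anchor, gi2 + 1):
            gap = p - gi2
            if gap < min_intron:
                merges.append(p)
                continue
            max_shift = min(30, ti2, gi2 - exon_start - 1)
            gtag_shifts = [
                s
                for s in range(max_shift + 1)
                if t[ti2 - s : ti2] == g[p - s : p]
                and g[gi2 - s : gi2 - s + 2] == "GT"
                and g[p - s - 2 : p - s] == "AG"
            ]
            if gtag_shifts:
                introns_gtag.append((p, max(gtag_shifts)))
            else:
                introns_other.append(p)

        for p, s in introns_gtag:
            result = search(ti2 - s, p - s, p - s, exons + [(exon_start, gi2 - s)])
            if result is not None:
                return result
        for p in merges:
            result = search(ti2, p, exon_start, exons)
            if result is not None:
                return result
        for p in introns_other:
            result = search(ti2, p, p, exons + [(exon_start, gi2)])
            if result is not None:
                return result
        return None

    k0 = min(anchor_len, len(t))
    exons = None
    for start in _find_all(g, t[:k0], 0):
        exons = search(0, start, start, [])
        if exons is not None:
            break
    if exons is None:
        raise AnnotationError(
            f"{transcript.id}: no spliced chain found "
            f"(best coverage {best_progress}/{len(t)} transcript nt, {states} states)"
        )

    exon_lengths = tuple(e - s for s, e in exons)
    intron_lengths = tuple(b[0] - a[1] for a, b in zip(exons, exons[1:]))
    cds_len = transcript.cds_len
    protein_len = None
    if cds_len is not None:
        last_codon = t[transcript.cds_end - 3 : transcript.cds_end]
        protein_len = cds_len // 3 - 1 if last_codon in _STOPS else cds_len // 3
    return GeneStructure(
        gene_id=transcript.id,
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
        cds_len=cds_len,
        protein_len=protein_len,
        exon_spans=tuple(exons),
    )


def compare_structures(structures: list[GeneStructure]) -> StructureTable:
    """Index-aligned comparison of exon/intron lengths across genes.

    Rows are exon (or intron) ordinals, columns are genes.  A row is flagged
    equal when every gene has that feature and all complete entries agree;
    incomplete introns are marked separately and ignored for equality.
    """
    if len(structures) < 2:
        raise ValueError("need at least two structures to compare")
    ids = [s.gene_id for s in structures]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in comparison")
    n_ex = max(s.n_exons for s in structures)
    n_in = max(s.n_introns for s in structures)

    exon = pd.DataFrame(
        {s.gene_id: [s.exon_lengths[i] if i < s.n_exons else np.nan for i in range(n_ex)] for s in structures},
        index=[f"E{i + 1}" for i in range(n_ex)],
    )
    intron = pd.DataFrame(
        {s.gene_id: [s.intron_lengths[i] if i < s.n_introns else np.nan for i in range(n_in)] for s in structures},
        index=[f"I{i + 1}" for i in range(n_in)],
    )
    incomplete = pd.DataFrame(
        {s.gene_id: [i in s.incomplete_introns for i in range(n_in)] for s in structures},
        index=intron.index,
    )

    def row_equal(row: pd.Series, skip: pd.Series | None = None) -> bool:
        values = row if skip is None else row[~skip]
        if row.isna().any():
            return False
        values = values.dropna()
        return len(values) > 0 and values.nunique() == 1

    exon_equal = exon.apply(row_equal, axis=1)
    intron_equal = pd.Series(
        [row_equal(intron.loc[idx], incomplete.loc[idx]) for idx in intron.index],
        index=intron.index,
    )
    return StructureTable(
        exon_matrix=exon,
        intron_matrix=intron,
        intron_incomplete=incomplete,
        exon_equal=exon_equal,
        intron_equal=intron_equal,
    )


def intron_length_summary(
    structures: list[GeneStructure],
    max_len: int = 2600,
    gene_set_id: str = "all",
) -> IntronStats:
    """Pooled statistics of complete introns no longer than ``max_len``.

    Quartiles use linear interpolation; outliers are Tukey fences at
    1.5 x IQR beyond the quartiles.
    """
    pooled = [
        length
        for s in structures
        for i, length in enumerate(s.intron_lengths)
        if i not in s.incomplete_introns and length <= max_len
    ]
    if not pooled:
        return IntronStats(gene_set_id, 0, float("nan"), float("nan"), float("nan"), float("nan"), ())
    arr = np.asarray(pooled, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    outliers = tuple(int(v) for v in sorted(arr[(arr < q1 - 1.5 * iqr) | (arr > q3 + 1.5 * iqr)]))
    return IntronStats(
        gene_set_id=gene_set_id,
        n=len(pooled),
        mean=float(arr.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        outliers=outliers,
    )
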