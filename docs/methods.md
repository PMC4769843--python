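# Methods

## Scope and model

`genecapture` reconstructs per-gene genomic models from capture-enriched,
assembled contigs using full-length seed transcripts as templates. It
assumes same-species data: contigs align to their own gene's transcript at
high identity (default ≥ 90 %), so exon evidence appears as near-exact,
effectively ungapped local alignment segments. It does not perform ab
initio gene prediction, splice-site scoring, read cleaning or assembly, or
polyploid allele separation.

## HSP finding

`find_hsps` is a word-anchored seed-and-extend aligner: exact k-mers
(k = 11, N-free) shared between contig and seed are grouped by alignment
diagonal; anchor runs separated by ≤ 50 nt on a diagonal are merged and
extended in both directions with an X-drop rule (match +1, mismatch −2,
drop-off 20). Segments below `min_hsp_len` (30 nt) or `min_identity`
(0.90) are discarded, as are segments contained within a higher-scoring
segment on the same strand. Both strands are scanned; coordinates are
always reported with the contig flipped into seed orientation, the flip
recorded on the HSP. Indels between contig and seed are not modelled within
a segment — at same-species identity an indel simply splits the signal into
two HSPs on adjacent diagonals, which the tiling stage handles like any
other pair of segments.

An HSP's score is its count of identical bases. This makes per-seed score
totals directly comparable across seeds of different divergence: a contig
matching a paralog at 95 % identity scores ≈ 0.95 of its perfect-match
score, so the default ambiguity ratio of 0.90 records paralogs at ≥ 90 %
aggregate similarity as ambiguous alternatives. Assignment ties are broken
by lexicographic seed id.

A contig is classified *single-interval* ("single-hsp") when its retained
HSPs against its assigned seed merge into one seed interval; such contigs
are the ones that may be intronless pseudogene copies or plain exon
fragments.

## Junction refinement

Ungapped extension overruns a splice junction whenever the first intron
bases happen to match the next exon (one chance in four per base, and
GT-starting introns systematically collide with GT-starting exons). The two
HSPs of a contig flanking an intron then overlap by a few nucleotides on the
seed. Uncorrected, this double-counts seed positions — pushing recovery
above 100 % on perfectly clean data, which would poison the repeat flag —
and misplaces the intron. `refine_junctions` therefore splits any small
(≤ 30 nt) seed overlap between consecutive same-contig, same-strand HSPs
whose genomic gap is intron-sized: the split point is chosen so the
intervening contig sequence starts GT and ends AG (the inferred intron
length is invariant to the split point), falling back to the overlap
midpoint when no canonical split exists.

## Candidate tilings and selection

The unit of model building is the contig: all HSPs of one contig enter or
leave a candidate together, so a genomic repeat that places one contig
region onto the same seed interval twice is preserved and later flagged. A
candidate is a set of cluster contigs such that

1. any two segments from different contigs overlap on the seed by at most
   `overlap_tolerance_nt` (15 nt) — contigs from one locus should tile, not
   stack;
2. no compatible contig outside the set would add new seed coverage
   (coverage-maximality); and
3. no member is redundant — removing it would leave the covered union
   unchanged (irredundancy).

Conditions 2–3 define *tight* tilings. Under the lexicographic objective
(union recovery max, then exon overlap min, then fragmentation min, then
sorted contig ids for determinism) the global optimum over **all** subsets
satisfying condition 1 is provably tight: adding a coverage-increasing
contig would improve union recovery, and removing a redundant member lowers
overlap and fragmentation without touching the union. Enumerating tight
sets is therefore exact, and the test suite verifies selection against
brute-force enumeration of every subset on small clusters. Enumeration is
depth-first over contigs in id order with a cap of 200,000 search states;
past the cap (never reached in the packaged simulations) a deterministic
greedy tiling (max new coverage, redundancy-pruned) is appended and a
warning logged.

Recovery is reported twice on purpose: `recovery_pct` counts segment spans
with multiplicity and can exceed 100 % — exactly how repeat-corrupted
models betray themselves, hence `suspect_repeat = recovery_pct > 100` —
while `union_recovery_pct` counts each seed position once and drives
selection. Exon overlap is defined as redundantly covered bases over the
covered union.

## Model sequence and introns

Segments are concatenated in seed order. A genomic gap ≥ `min_intron`
(20 nt) between consecutive same-contig segments is retained as an intron
of known length; sub-threshold gaps are kept inline as exonic sequence
(alignment hiccups, not introns). Junctions between different contigs are
joined with a 50-N spacer and recorded with unknown intron length — the
analogue of an incompletely recovered intron. A consequence worth knowing:
two fragments that split a *single* exon mid-way are also joined with a
spacer, because without spanning evidence the pipeline cannot distinguish
an exon split from an unspanned junction.

Ortholog guidance is annotation-only and never changes segment selection.
Cumulative ortholog exon lengths, taken relative to the ortholog CDS start
(`cds_offset` absorbs its 5′UTR), are rescaled to the seed CDS length and
projected onto seed coordinates; each projected junction is labelled
`supported` (an inferred intron lies within 10 nt), `unsupported` (covered
but not spanned by one contig) or `missing` (no coverage).

## Promoter extraction

A contig qualifies for a gene when one HSP against the gene's seed covers a
coding position at or before codon 10 (codon k spans CDS positions
[3(k−1), 3k)) **and** the contig extends ≥ 100 nt 5′ of that HSP's start in
seed orientation. Both thresholds are strict: 100 nt passes, 99 fails;
codon 10 passes, 11 fails. The upstream-length histogram counts gene
models, not contigs: per gene, the candidate with the longest upstream
stretch is kept (ties to the lexicographically smallest contig id) before
binning into half-open bins. Genes whose seed lacks a CDS annotation are
skipped with a warning.

## Probe design

Probes are `probe_len` = 120 nt substrings of the seed. Starts advance by
19 nt while the next start lies below ⌈L/3⌉ (the denser 5′ zone, including
the 5′UTR), then by 29 nt from the last dense-zone start without a phase
reset; a terminal probe at L − 120 is appended when the last regular probe
does not reach the 3′ end, so every base of a designable seed is covered.
Seeds shorter than one probe are skipped with a warning; probes with ≥ 10 %
N are dropped for array manufacturability. The interior modal per-base
depth equals ⌊120/19⌋ = 6 in the dense zone and ⌊120/29⌋ = 4 beyond it;
`probe_coverage_profile` measures this over zone interiors, excluding a
probe-length ramp at each zone edge.

## Structure annotation and comparison

`annotate_gene_structure` chains transcript segments through the genomic
sequence left to right with backtracking. Exons grow by exact extension;
isolated substitutions are absorbed when a 20-nt context re-anchors at the
same offset. At each mismatch, occurrences of the next 20-nt transcript
anchor in the genomic sequence propose continuations, tried in preference
order: substitution, GT..AG introns (with junction micro-shifts of up to
30 nt to restore canonical sites, preferring the leftmost canonical
placement), sub-`min_intron` merges (the flanking exons absorb the gap),
then non-canonical introns. Gaps below `min_intron` (20 nt — plant introns
down to ~21 nt exist) are never opened as introns. The search is capped at
20,000 states and raises an annotation failure with the best covered
fraction when no complete chain exists.

CDS arithmetic: `protein_len = cds_len/3 − 1` when the CDS ends in a stop
codon, so a 1,782-nt CDS yields a 593-aa protein. The gene span is always
reported as Σ exons + Σ introns computed from the annotated structure;
externally published spans for the same gene can differ when they rest on
different UTR/boundary conventions, and no attempt is made to reproduce
such figures.

Comparison tables align exons and introns by ordinal across genes; a row is
flagged equal when every gene has the feature and all complete entries
agree. Introns marked incomplete are starred in output and excluded from
both equality and statistics. Intron summaries pool complete introns up to
`max_len` (2,600 nt) and report n, mean, median, linear-interpolation
quartiles and Tukey 1.5 × IQR outliers.

## Synthetic data

`make_gene` emits a gene with exact requested structure: background
composition ~38 % GC (conifer-like), CDS built from sense codons between
ATG and a stop with no internal in-frame stop, GT..AG introns, and the
transcript equal to the splice of the genomic sequence by construction.
All randomness flows from one integer seed; identical arguments give
identical bytes.

The packaged 14-exon fixture uses the BAC-derived exon lengths
(808, 139, 96, 142, 96, 98, 162, 81, 222, 135, 81, 87, 108, 252) and intron
lengths (225, 101, 426, 119, 88, 132, 219, 104, 87, 92, 139, 89, 95) of the
maritime pine asparagine synthetase 1 gene. The UTR split — 500 nt 5′UTR,
225 nt 3′UTR — is a packaging convention chosen once so that the CDS is
1,782 nt and the protein 593 aa; the underlying annotation does not state
the UTR lengths. Its sequence content is synthetic; only the structure is
real.

The contig simulator emulates: exon-centred genomic fragments (capture
bias), with lengths N(1500, 300) clipped to [500, 2500] nt, matching ~1.5-kb
library shearing; junction-spanning fragments covering both full flanking
exons; intronless transcript copies at 5 % divergence (processed
pseudogenes); fragments from a locus with a tandemly duplicated exon (the
repeat failure mode); and fragments reaching a uniform 0–1,500 nt into the
5′ flank (promoter capture). The demo set is five genes of one to five
exons with plant-typical exon (90–300 nt) and intron (80–140 nt) sizes —
small enough that a single sheared fragment can span a gene body, which is
what makes complete single-contig recovery attainable and keeps the
end-to-end checks sharp.

What the simulator does **not** model: sequencing error and assembly
artifacts (contigs are exact genomic substrings apart from pseudogene
divergence), chimeric contigs, heterozygosity (real capture used haploid
tissue), alternative splicing, and gene families with many cross-hybridising
members beyond the single-paralog ambiguity scenario. Passing the packaged
benchmarks therefore demonstrates correctness of the algorithms under clean
evidence, not robustness to assembler pathology.

## Problem sizes

The packaged checks run at desk scale by design: five demo genes
(~110 contigs), a 14-exon fixture (~6.4-kb genomic sequence), a 12–50-gene
promoter simulation, and a 3,000-nt probe-design target. The whole suite
and the acceptance script each complete in well under a minute on one core.

## Known limitations

- Ungapped HSPs: a genuine indel inside an exon splits evidence into two
  segments; the model still tiles but reports an extra unknown junction.
- Candidate enumeration is exponential in the worst case; the state cap
  with greedy fallback trades exactness for boundedness on pathological
  clusters (and logs when it does).
- Promoter extraction trusts the seed's CDS annotation; a wrong CDS start
  shifts the codon-10 window.
- The intron-length table equality flag compares ordinals, not homology:
  structures with shifted junctions compare position-by-position.
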