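"""Candidate tiling, scoring, selection, repeat flagging, ortholog guidance."""

from __future__ import annotations

import itertools

import pytest

from genecapture import (
    GeneModel,
    ModelScore,
    OrthologStructure,
    apply_ortholog_guidance,
    best_model_for_cluster,
    build_candidate_models,
    finalize_model,
    flag_suspect,
    score_model,
    select_best_model,
)
from genecapture.capture_align import assign_contigs, cluster_by_gene
from genecapture.model_builder import segments_from_hsps
from genecapture import simdata

from conftest import mk_hsp, plain_seed


def model_from_spans(seed_id: str, spans: dict[str, list[tuple[int, int]]]) -> GeneModel:
    """A gene model with one perfect segment per (contig, seed span)."""
    hsps = []
    for cid, intervals in spans.items():
        offset = 0
        for s, e in intervals:
            hsps.append(mk_hsp(cid, seed_id, s, e, contig_start=offset))
            offset += e - s
    return GeneModel(seed_id=seed_id, segments=segments_from_hsps(hsps))


class TestScoring:
    def test_overlapping_spans_scored_by_hand(self):
        """Spans [0,50) + [40,100) on a 100-nt seed: recovery 110 %, union
        100 %, overlap 10 %, fragmentation 2 — the hand-computed oracle."""
        seed = plain_seed("s", 100)
        model = model_from_spans("s", {"a": [(0, 50)], "b": [(40, 100)]})
        sc = score_model(model, seed)
        assert sc.recovery_pct == pytest.approx(110.0)
        assert sc.union_recovery_pct == pytest.approx(100.0)
        assert sc.exon_overlap_pct == pytest.approx(10.0)
        assert sc.fragmentation_index == 2
        # Brute-force position counting agrees.
        counts = [0] * 100
        for s, e in [(0, 50), (40, 100)]:
            for i in range(s, e):
                counts[i] += 1
        assert sum(counts) == 110
        assert sum(1 for c in counts if c) == 100

    def test_full_cover_single_contig(self):
        seed = plain_seed("s", 100)
        sc = score_model(model_from_spans("s", {"a": [(0, 100)]}), seed)
        assert (sc.recovery_pct, sc.union_recovery_pct, sc.exon_overlap_pct) == (100.0, 100.0, 0.0)
        assert sc.fragmentation_index == 1

    def test_partial_cover(self):
        seed = plain_seed("s", 100)
        sc = score_model(model_from_spans("s", {"a": [(0, 30)]}), seed)
        assert sc.recovery_pct == pytest.approx(30.0)
        assert sc.exon_overlap_pct == 0.0

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            score_model(GeneModel(seed_id="s", segments=[]), plain_seed("s", 100))


class TestSelection:
    @staticmethod
    def scored(seed_id, union, overlap, frag, cids):
        m = model_from_spans(seed_id, {c: [(0, 10)] for c in cids})
        m.score = ModelScore(
            recovery_pct=union,
            union_recovery_pct=union,
            exon_overlap_pct=overlap,
            fragmentation_index=frag,
        )
        return m

    def test_union_recovery_dominates(self):
        a = self.scored("s", 80.0, 0.0, 1, ["a"])
        b = self.scored("s", 95.0, 20.0, 5, ["b", "c", "d", "e", "f"])
        assert select_best_model([a, b]) is b

    def test_lower_overlap_breaks_union_tie(self):
        a = self.scored("s", 90.0, 10.0, 2, ["a", "b"])
        b = self.scored("s", 90.0, 0.0, 2, ["c", "d"])
        assert select_best_model([a, b]) is b

    def test_lower_fragmentation_breaks_remaining_tie(self):
        a = self.scored("s", 90.0, 5.0, 3, ["a", "b", "c"])
        b = self.scored("s", 90.0, 5.0, 2, ["d", "e"])
        assert select_best_model([a, b]) is b

    def test_empty_candidates_signal_no_model(self):
        assert select_best_model([]) is None


class TestSuspectFlag:
    def test_recovery_above_100_is_suspect(self):
        seed = plain_seed("s", 100)
        model = model_from_spans("s", {"a": [(0, 50)], "b": [(40, 100)]})
        score_model(model, seed)
        assert flag_suspect(model).suspect_repeat is True

    def test_recovery_exactly_100_is_clean(self):
        seed = plain_seed("s", 100)
        model = model_from_spans("s", {"a": [(0, 100)]})
        score_model(model, seed)
        assert flag_suspect(model).suspect_repeat is False


class TestCandidates:
    def test_single_full_contig_single_candidate(self):
        seed = plain_seed("s", 100)
        candidates = build_candidate_models(seed, [mk_hsp("a", "s", 0, 100)])
        assert len(candidates) == 1
        assert candidates[0].contig_ids == ("a",)

    def test_tolerated_overlap_tiles_both_contigs(self):
        """[0,50) and [40,100) overlap by 10 <= 15, so the only tight tiling
        uses both contigs (each alone could still be extended)."""
        seed = plain_seed("s", 100)
        hsps = [mk_hsp("a", "s", 0, 50), mk_hsp("b", "s", 40, 100)]
        candidates = build_candidate_models(seed, hsps, overlap_tolerance_nt=15)
        assert [m.contig_ids for m in candidates] == [("a", "b")]

    def test_conflicting_contigs_yield_alternatives(self):
        seed = plain_seed("s", 100)
        hsps = [mk_hsp("a", "s", 0, 60), mk_hsp("b", "s", 30, 100)]
        candidates = build_candidate_models(seed, hsps, overlap_tolerance_nt=15)
        assert sorted(m.contig_ids for m in candidates) == [("a",), ("b",)]

    def test_same_contig_repeat_segments_retained_together(self):
        seed = plain_seed("s", 100)
        hsps = [
            mk_hsp("a", "s", 0, 100, contig_start=0),
            mk_hsp("a", "s", 30, 60, contig_start=120),  # duplicated exon placement
        ]
        candidates = build_candidate_models(seed, hsps)
        assert len(candidates) == 1
        model = candidates[0]
        assert len(model.segments) == 2
        sc = score_model(model, seed)
        assert sc.recovery_pct == pytest.approx(130.0)
        assert flag_suspect(model).suspect_repeat

    def test_empty_cluster_gives_no_candidates(self):
        assert build_candidate_models(plain_seed("s", 100), []) == []


def brute_force_best(spans_by_contig: dict[str, list[tuple[int, int]]], seed_len: int, tol: int):
    """Oracle: exhaustive enumeration of every contig subset.

    Scores each subset satisfying the pairwise cross-contig overlap
    constraint with the same lexicographic key and returns the best
    (union desc, overlap asc, fragmentation asc, contig ids asc).
    """
    cids = sorted(spans_by_contig)

    def compatible(sub):
        for x, y in itertools.combinations(sub, 2):
            for a in spans_by_contig[x]:
                for b in spans_by_contig[y]:
                    if min(a[1], b[1]) - max(a[0], b[0]) > tol:
                        return False
        return True

    best_key, best_sub = None, None
    for r in range(1, len(cids) + 1):
        for sub in itertools.combinations(cids, r):
            if not compatible(sub):
                continue
            spans = [iv for c in sub for iv in spans_by_contig[c]]
            total = sum(e - s for s, e in spans)
            covered = set()
            for s, e in spans:
                covered.update(range(s, e))
            union = len(covered)
            key = (-100.0 * union / seed_len, 100.0 * (total - union) / union, len(sub), sub)
            if best_key is None or key < best_key:
                best_key, best_sub = key, sub
    return best_key, best_sub


class TestSelectionOracle:
    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_subset_enumeration(self, trial):
        """Pipeline selection equals brute-force search over all subsets for
        random clusters of up to 6 contigs."""
        import numpy as np

        rng = np.random.default_rng(1000 + trial)
        seed_len = 120
        n = int(rng.integers(2, 7))
        spans_by_contig: dict[str, list[tuple[int, int]]] = {}
        for i in range(n):
            n_spans = int(rng.integers(1, 3))
            spans = []
            for _ in range(n_spans):
                s = int(rng.integers(0, seed_len - 20))
                e = int(rng.integers(s + 10, min(seed_len, s + 60)))
                spans.append((s, e))
            spans_by_contig[f"c{i}"] = spans

        seed = plain_seed("s", seed_len)
        hsps = []
        for cid, spans in spans_by_contig.items():
            offset = 0
            for s, e in spans:
                hsps.append(mk_hsp(cid, "s", s, e, contig_start=offset))
                offset += e - s
        candidates = build_candidate_models(seed, hsps, overlap_tolerance_nt=15)
        for m in candidates:
            score_model(m, seed)
        best = select_best_model(candidates)

        oracle_key, oracle_sub = brute_force_best(spans_by_contig, seed_len, tol=15)
        assert best is not None
        got_key = (
            -best.score.union_recovery_pct,
            best.score.exon_overlap_pct,
            best.score.fragmentation_index,
            best.contig_ids,
        )
        assert got_key[:3] == pytest.approx(oracle_key[:3])
        assert best.contig_ids == oracle_sub


def test_adding_a_contig_never_decreases_best_union():
    seed = plain_seed("s", 200)
    base_hsps = [mk_hsp("a", "s", 0, 80), mk_hsp("b", "s", 90, 140)]
    extra = mk_hsp("c", "s", 140, 200)

    def best_union(hsps):
        candidates = build_candidate_models(seed, hsps)
        for m in candidates:
            score_model(m, seed)
        return select_best_model(candidates).score.union_recovery_pct

    assert best_union(base_hsps + [extra]) >= best_union(base_hsps)


class TestFinalize:
    def test_intron_reported_only_when_one_contig_spans_junction(self, as1, as1_seed):
        """Junction-spanning contigs yield known intron lengths; junctions
        joined across contigs are reported unknown with an N spacer."""
        sim = simdata.simulate_capture_contigs(
            as1,
            simdata.ContigSimConfig(rng_seed=2, exon_fragments=False, junction_spanning=True),
        )
        contig_map = {c.id: c for c in sim.contigs}
        result = assign_contigs(sim.contigs, [as1_seed])
        clusters = cluster_by_gene(result.assignments)
        model = best_model_for_cluster(
            as1_seed, result.cluster_hsps("AS1", clusters["AS1"]), contig_map
        )
        assert model.score.union_recovery_pct == pytest.approx(100.0)
        assert len(model.segments) == 14
        known = {model.segments[i].seed_span[1]: length for i, length in model.inferred_introns if length is not None}
        # Every known intron matches the generating length at its junction.
        junctions = {}
        pos = 0
        for ex, intron in zip(as1.exon_lengths[:-1], as1.intron_lengths):
            pos += ex
            junctions[pos] = intron
        for seed_pos, length in known.items():
            assert junctions[seed_pos] == length
        assert known  # at least some junctions are single-contig spanned
        unknown = [i for i, length in model.inferred_introns if length is None]
        assert unknown  # alternating junctions are joined across contigs
        assert "N" * 50 in model.model_sequence

    def test_single_contig_model_sequence_is_contig_subsequence(self, demo):
        gene = demo[1]  # two exons, one intron
        seed = gene.seed_transcript()
        body = gene.genomic_seq[gene.body_start : gene.body_end]
        from genecapture import Contig

        contig = Contig("full", body)
        result = assign_contigs([contig], [seed])
        model = best_model_for_cluster(seed, result.cluster_hsps(seed.id, ["full"]), {"full": contig})
        assert model.model_sequence == body
        assert [length for _, length in model.inferred_introns] == list(gene.intron_lengths)


class TestOrthologGuidance:
    @staticmethod
    def ortholog_like(gene: simdata.SyntheticGene, species="model_sp") -> OrthologStructure:
        exons = list(gene.exon_lengths)
        exons[-1] -= gene.utr3  # ortholog tables cover 5'UTR + CDS
        return OrthologStructure(
            species=species,
            gene_id=f"{gene.gene_id}_ortholog",
            exon_lengths=tuple(exons),
            intron_lengths=gene.intron_lengths,
            cds_offset=gene.utr5,
        )

    def build_model(self, gene, drop=None):
        sim = simdata.simulate_capture_contigs(
            gene, simdata.ContigSimConfig(rng_seed=4, exon_fragments=False, junction_spanning=True)
        )
        contigs = [c for c in sim.contigs if c.id != drop]
        contig_map = {c.id: c for c in contigs}
        seed = gene.seed_transcript()
        result = assign_contigs(contigs, [seed])
        clusters = cluster_by_gene(result.assignments)
        return seed, best_model_for_cluster(seed, result.cluster_hsps(gene.gene_id, clusters[gene.gene_id]), contig_map)

    def test_identical_structure_supports_all_junctions(self, as1):
        # A model whose contig spans the whole gene body has every junction
        # spanned, so an identically structured ortholog confirms all 13.
        seed, model = self.build_model_single(as1)
        model = apply_ortholog_guidance(model, self.ortholog_like(as1), seed)
        statuses = [status for _, _, status in model.junction_support]
        assert len(statuses) == 13
        assert set(statuses) == {"supported"}

    def test_junction_joined_across_contigs_is_unsupported(self, as1):
        # Alternating junction contigs span odd junctions only; the even
        # junctions are covered but not spanned by any single contig.
        seed, model = self.build_model(as1)
        model = apply_ortholog_guidance(model, self.ortholog_like(as1), seed)
        statuses = [status for _, _, status in model.junction_support]
        assert statuses.count("supported") == 7
        assert statuses.count("unsupported") == 6

    def test_dropped_junction_contig_reported_missing(self, as1):
        # Removing the only contig covering exons 11/12 leaves junction 11
        # without coverage at all.
        seed, model = self.build_model(as1, drop="AS1_junc10")
        model = apply_ortholog_guidance(model, self.ortholog_like(as1), seed)
        statuses = {j: status for j, _, status in model.junction_support}
        assert "missing" in statuses.values()

    def test_single_exon_ortholog_trivially_complete(self, demo):
        gene = demo[0]
        seed, model = self.build_model_single(gene)
        ortholog = OrthologStructure("sp", "o1", (gene.exon_lengths[0] - gene.utr3,), (), cds_offset=gene.utr5)
        model = apply_ortholog_guidance(model, ortholog, seed)
        assert model.junction_support == []

    def build_model_single(self, gene):
        from genecapture import Contig

        body = gene.genomic_seq[gene.body_start : gene.body_end]
        contig = Contig("full", body)
        seed = gene.seed_transcript()
        result = assign_contigs([contig], [seed])
        clusters = cluster_by_gene(result.assignments)
        return seed, best_model_for_cluster(seed, result.cluster_hsps(gene.gene_id, clusters[gene.gene_id]), {"full": contig})
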