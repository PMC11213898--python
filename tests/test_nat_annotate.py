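"""Tests for ORF reconstruction, motif scanning, triad verification, and
classification/nomenclature."""

import numpy as np
import pytest

from natminer.benchmark import group_hits, mutate_outside_motifs
from natminer.homology_search import translated_genome_search
from natminer.formats_io import Record, SeqRecordSet
from natminer.nat_annotate import (DEFAULT_MOTIFS, classify_and_name,
                                   reconstruct_orf, scan_motifs, verify_triad)
from natminer.synthetic_data import implant_locus, random_protein
from oracles import best_window_score

CANONICAL = "XXX" + "VPFENL" + "XXX" + "RGGYC" + "XXX" + "THRL" + \
    "XXX" + "VDV" + "XXX"


def edit_distance(a: str, b: str) -> int:
    dp = np.arange(len(b) + 1)
    for i, ca in enumerate(a, 1):
        prev = dp.copy()
        dp[0] = i
        for j, cb in enumerate(b, 1):
            dp[j] = min(dp[j - 1] + 1, prev[j] + 1, prev[j - 1] + (ca != cb))
    return int(dp[-1])


class TestReconstructOrf:
    def test_intact_implant_reproduces_protein(self, genome_with_intact_locus,
                                               nat_protein):
        genome, entry = genome_with_intact_locus
        hits = translated_genome_search(nat_protein, genome)
        locus = reconstruct_orf(hits, genome, locus_id="L1")
        assert locus.protein == nat_protein
        assert locus.segments == entry.segments
        assert not locus.partial_5p and not locus.partial_3p

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("lesion", ["frameshift_del1", "frameshift_ins1"])
    def test_frameshift_joined_within_edit_distance_2(self, small_genome,
                                                      nat_protein, lesion,
                                                      strand):
        genome, entry = implant_locus(small_genome, nat_protein,
                                      position=5000, strand=strand,
                                      lesion=lesion, seed=3)
        hits = translated_genome_search(nat_protein, genome)
        locus = reconstruct_orf(hits, genome, locus_id="L1")
        assert len(locus.segments) == 2
        frames = [abs(f) for _, _, f in locus.segments]
        assert frames[0] != frames[1]
        assert edit_distance(locus.protein, nat_protein) <= 2

    def test_segment_frames_differ_between_neighbours(self, small_genome,
                                                      nat_protein):
        genome, _ = implant_locus(small_genome, nat_protein, position=5000,
                                  lesion="frameshift_del1", seed=5)
        locus = reconstruct_orf(translated_genome_search(nat_protein, genome),
                                genome)
        for (s1, e1, f1), (s2, e2, f2) in zip(locus.segments,
                                              locus.segments[1:]):
            assert f1 != f2
            assert e1 <= s2  # non-overlapping, ordered 5'->3'

    def test_contig_edge_truncation_sets_partial(self, small_genome,
                                                 nat_protein):
        from natminer.formats_io import Record, SeqRecordSet
        from natminer.synthetic_data import GenomeRecord

        genome, entry = implant_locus(small_genome, nat_protein,
                                      position=18_000, seed=7)
        rec = genome.contigs.records[0]
        cut = entry.segments[0][0] + 3 * (len(nat_protein) // 2)
        clipped = GenomeRecord(
            genome.replicon_id,
            SeqRecordSet([Record(rec.id, "", rec.sequence[:cut])],
                         alphabet="dna"),
            genome.taxon)
        hits = translated_genome_search(nat_protein, clipped)
        locus = reconstruct_orf(hits, clipped)
        assert locus.partial_3p

    def test_mixed_strand_hits_rejected(self, small_genome, nat_protein):
        g, _ = implant_locus(small_genome, nat_protein, position=2000,
                             strand="+", seed=1)
        g, _ = implant_locus(g, nat_protein, position=12_000, strand="-",
                             seed=2)
        hits = translated_genome_search(nat_protein, g)
        with pytest.raises(ValueError, match="strand"):
            reconstruct_orf(hits, g)

    def test_zero_hits_rejected(self, small_genome):
        with pytest.raises(ValueError):
            reconstruct_orf([], small_genome)


class TestScanMotifs:
    def test_constructed_exact_match_positions(self):
        hits = scan_motifs(CANONICAL)
        assert hits["M1"].position == 3
        assert hits["M2"].position == 12
        assert hits["M3"].position == 20
        assert hits["M4"].position == 27
        assert all(h.score_fraction == 1.0 for h in hits.values())
        # catalytic residues: C at 16, H at 21, D at 28
        assert CANONICAL[16] == "C" and CANONICAL[21] == "H" \
            and CANONICAL[28] == "D"

    def test_scrambled_order_fewer_hits(self):
        scrambled = "XXX" + "VDV" + "XXX" + "RGGYC" + "XXX" + "THRL" + \
            "XXX" + "VPFENL" + "XXX"
        hits = scan_motifs(scrambled)
        assert sum(h is not None for h in hits.values()) < 4

    def test_substituted_motif_matches_window_oracle(self):
        seq = CANONICAL.replace("VPFENL", "VPYENL")
        hits = scan_motifs(seq)
        assert hits["M1"] is not None
        pos, frac = best_window_score(seq[:12], "VPFENL")
        assert hits["M1"].position == pos
        assert hits["M1"].score_fraction == pytest.approx(frac)

    def test_positions_strictly_increasing(self, nat_protein):
        hits = scan_motifs(nat_protein)
        positions = [h.position for h in hits.values() if h is not None]
        assert positions == sorted(positions)
        assert len(set(positions)) == len(positions)

    def test_short_protein_no_hits(self):
        assert all(h is None for h in scan_motifs("VPFENLRGGYC").values())

    def test_random_proteins_rarely_carry_all_motifs(self):
        found = 0
        for rep in range(50):
            prot = random_protein(280, seed=600 + rep)
            hits = scan_motifs(prot)
            if sum(h is not None for h in hits.values()) >= 3:
                found += 1
        assert found <= 2  # the motif rule rejects random windows


class TestVerifyTriad:
    def test_canonical(self):
        assert verify_triad(scan_motifs(CANONICAL)) == "canonical_CHD"

    def test_glu_variant_flagged(self):
        assert verify_triad(scan_motifs(CANONICAL.replace("VDV", "VEV"))) \
            == "variant_CHE"

    def test_missing_m2_incomplete(self):
        assert verify_triad(scan_motifs(CANONICAL.replace("RGGYC", "RGGYA"))) \
            == "incomplete"

    def test_no_motifs_absent(self):
        assert verify_triad({m.motif_id: None for m in DEFAULT_MOTIFS}) \
            == "absent"


class TestClassifyAndName:
    def test_identical_locus_intact_nat1(self, genome_with_intact_locus,
                                         nat_protein, reference_set):
        genome, _ = genome_with_intact_locus
        hits = translated_genome_search(nat_protein, genome)
        locus = reconstruct_orf(hits, genome, locus_id="L1")
        results = classify_and_name([locus], reference_set)
        assert results[0].classification == "intact"
        assert results[0].best_identity == 100.0
        assert results[0].assigned_symbol == "NAT1"

    def test_frameshift_still_named(self, small_genome, nat_protein,
                                    reference_set):
        genome, _ = implant_locus(small_genome, nat_protein, position=5000,
                                  lesion="frameshift_del1", seed=3)
        hits = translated_genome_search(nat_protein, genome)
        locus = reconstruct_orf(hits, genome, locus_id="fs1")
        results = classify_and_name([locus], reference_set)
        assert results[0].classification == "frameshifted_pseudogene"
        assert results[0].assigned_symbol != ""

    def test_symbols_by_descending_identity(self, small_genome, nat_protein,
                                            reference_set):
        near = mutate_outside_motifs(nat_protein, 0.05,
                                     np.random.default_rng(1))
        far = mutate_outside_motifs(nat_protein, 0.35,
                                    np.random.default_rng(2))
        g, _ = implant_locus(small_genome, far, position=2000, seed=1)
        g, _ = implant_locus(g, near, position=12_000, seed=2)
        hits = translated_genome_search(nat_protein, g, min_identity=30)
        loci = [reconstruct_orf(grp, g, locus_id=f"L{i}")
                for i, grp in enumerate(group_hits(hits))]
        results = classify_and_name(loci, reference_set)
        by_symbol = {r.assigned_symbol: r for r in results}
        assert by_symbol["NAT1"].best_identity > by_symbol["NAT2"].best_identity

    def test_permutation_invariant(self, small_genome, nat_protein,
                                   reference_set):
        variants = [mutate_outside_motifs(nat_protein, rate,
                                          np.random.default_rng(i))
                    for i, rate in enumerate((0.02, 0.10, 0.20))]
        g = small_genome
        for i, v in enumerate(variants):
            g, _ = implant_locus(g, v, position=2000 + 6000 * i, seed=i)
        hits = translated_genome_search(nat_protein, g, min_identity=30)
        loci = [reconstruct_orf(grp, g, locus_id=f"L{i}")
                for i, grp in enumerate(group_hits(hits))]
        forward = classify_and_name(loci, reference_set)
        backward = classify_and_name(loci[::-1], reference_set)
        fwd = {r.locus_id: r.assigned_symbol for r in forward}
        bwd = {r.locus_id: r.assigned_symbol for r in backward}
        assert fwd == bwd

    def test_unrelated_protein_non_nat(self, small_genome, reference_set):
        junk = random_protein(200, seed=50)
        g, _ = implant_locus(small_genome, junk, position=4000, seed=1)
        from natminer.nat_annotate import NatLocus
        locus = NatLocus("junk1", g.contigs.records[0].id, "+",
                         ((4000, 4600, 2),), junk, False, False)
        results = classify_and_name([locus], reference_set)
        assert results[0].classification == "non_nat"
        assert results[0].assigned_symbol == ""

    def test_empty_references_rejected(self, nat_protein):
        from natminer.nat_annotate import NatLocus
        locus = NatLocus("x", "c", "+", ((0, 30, 1),), nat_protein)
        with pytest.raises(ValueError):
            classify_and_name([locus],
                              SeqRecordSet([], alphabet="protein"))
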