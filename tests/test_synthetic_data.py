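"""Tests for the synthetic-genome generator: determinism, composition
statistics, lesion models, and the evolved-family substitution process."""

import numpy as np
import pytest
from skbio import TreeNode

from natminer.synthetic_data import (FamilyConfig, back_translate,
                                     derive_seed, evolve_family,
                                     generate_genome, implant_cluster,
                                     implant_gc_island, implant_locus,
                                     make_nat_protein, random_protein)
from oracles import CODON_TABLE_11, translate_frame


class TestGenerateGenome:
    def test_deterministic_under_seed(self):
        a = generate_genome(10_000, gc=0.5, seed=42)
        b = generate_genome(10_000, gc=0.5, seed=42)
        assert [r.sequence for r in a.contigs] == \
            [r.sequence for r in b.contigs]
        assert generate_genome(10_000, gc=0.5, seed=43).contigs.records[0] \
            != a.contigs.records[0]

    def test_gc_concentration(self):
        g = generate_genome(1_000_000, gc=0.7, seed=5)
        seq = g.contigs.records[0].sequence
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.7) < 0.01

    def test_contig_split_conserves_length(self):
        g = generate_genome(10_000, gc=0.5, n_contigs=3, seed=1)
        assert len(g.contigs) == 3
        assert g.total_length() == 10_000
        assert all(len(r.sequence) >= 1000 for r in g.contigs)

    @pytest.mark.parametrize("gc", [0.0, 1.0, -0.2, 1.5])
    def test_gc_out_of_range_rejected(self, gc):
        with pytest.raises(ValueError):
            generate_genome(10_000, gc=gc, seed=1)

    def test_too_short_for_contigs_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(2500, gc=0.5, n_contigs=3, seed=1)


class TestBackTranslate:
    def test_translates_back_to_protein(self):
        prot = random_protein(50, seed=2)
        orf = back_translate(prot, seed=3)
        assert len(orf) == 3 * 50 + 3
        translated = "".join(
            CODON_TABLE_11[orf[i:i + 3]] for i in range(0, 150, 3))
        assert translated == prot
        assert CODON_TABLE_11[orf[-3:]] == "*"

    def test_deterministic(self):
        prot = random_protein(30, seed=2)
        assert back_translate(prot, seed=9) == back_translate(prot, seed=9)


class TestImplantLocus:
    def test_lesion_free_retranslates_exactly(self, small_genome, nat_protein):
        g, entry = implant_locus(small_genome, nat_protein, position=4000,
                                 strand="+", lesion="none", seed=1)
        assert len(entry.segments) == 1
        s, e, frame = entry.segments[0]
        assert translate_frame(g.contig_seq(entry.contig)[s:e], 1) == \
            nat_protein
        assert frame == (s % 3) + 1

    def test_frameshift_del1_shifts_frame_down(self, small_genome, nat_protein):
        g, entry = implant_locus(small_genome, nat_protein, position=4000,
                                 strand="+", lesion="frameshift_del1", seed=1)
        (s1, e1, f1), (s2, e2, f2) = entry.segments
        assert ((f1 - 1) - (f2 - 1)) % 3 == 1  # downstream frame shifts by -1
        assert g.total_length() == small_genome.total_length() - 1
        # naive translation in the upstream frame hits a premature stop
        seq = g.contig_seq(entry.contig)
        naive = translate_frame(seq[s1: e2], 1)
        assert "*" in naive[: len(nat_protein) - 5]
        # the two segments together encode the lesioned protein exactly
        joined = translate_frame(seq[s1:e1], 1) + translate_frame(seq[s2:e2], 1)
        assert joined == entry.protein
        assert len(entry.protein) == len(nat_protein) - 1

    def test_frameshift_ins1_shifts_frame_up(self, small_genome, nat_protein):
        g, entry = implant_locus(small_genome, nat_protein, position=4000,
                                 strand="+", lesion="frameshift_ins1", seed=1)
        (_, _, f1), (_, _, f2) = entry.segments
        assert ((f2 - 1) - (f1 - 1)) % 3 == 1
        assert g.total_length() == small_genome.total_length() + 1
        assert entry.protein == nat_protein

    @pytest.mark.parametrize("lesion,flag", [("truncation_5p", "start"),
                                             ("truncation_3p", "end")])
    def test_truncations_clip_at_least_20pct(self, small_genome, nat_protein,
                                             lesion, flag):
        g, entry = implant_locus(small_genome, nat_protein, position=4000,
                                 strand="+", lesion=lesion, seed=1)
        assert len(entry.segments) == 1
        kept = len(entry.protein)
        assert kept <= 0.8 * len(nat_protein)
        if flag == "start":
            assert entry.protein == nat_protein[len(nat_protein) - kept:]
        else:
            assert entry.protein == nat_protein[:kept]

    def test_minus_strand_segments_encode_protein(self, small_genome,
                                                  nat_protein):
        g, entry = implant_locus(small_genome, nat_protein, position=4000,
                                 strand="-", lesion="none", seed=1)
        s, e, frame = entry.segments[0]
        assert frame < 0
        assert translate_frame(g.contig_seq(entry.contig), frame).find(
            nat_protein) >= 0

    def test_overlapping_implant_rejected(self, genome_with_intact_locus,
                                          nat_protein):
        g, _ = genome_with_intact_locus
        with pytest.raises(ValueError, match="overlap"):
            implant_locus(g, nat_protein, position=5100, seed=2)

    def test_out_of_bounds_rejected(self, small_genome, nat_protein):
        with pytest.raises(ValueError, match="fit"):
            implant_locus(small_genome, nat_protein, position=19_900, seed=2)


class TestImplantCluster:
    def test_nat_last_gene_rif_like_layout(self):
        g = generate_genome(40_000, gc=0.55, seed=21)
        g2, feats = implant_cluster(g, n_flank_genes=5, cluster_type="T1PKS",
                                    nat_position=6, seed=8)
        cds = feats.of_kind("CDS")
        assert len(cds) == 6
        nat_features = [f for f in cds
                        if "nat" in (f.qualifier("locus_tag") or "")]
        assert len(nat_features) == 1
        assert nat_features[0].start == max(f.start for f in cds)

    def test_cluster_span_covers_gene_union(self):
        g = generate_genome(40_000, gc=0.55, seed=22)
        _, feats = implant_cluster(g, n_flank_genes=3, cluster_type="NRPS",
                                   nat_position=2, seed=9)
        pc = feats.of_kind("protocluster")[0]
        cds = feats.of_kind("CDS")
        assert pc.start <= min(f.start for f in cds)
        assert pc.end >= max(f.end for f in cds)
        assert pc.qualifier("category") == "NRPS"

    def test_genes_non_overlapping_with_gaps(self):
        g = generate_genome(40_000, gc=0.55, seed=23)
        _, feats = implant_cluster(g, n_flank_genes=4, cluster_type="terpene",
                                   nat_position=3, seed=10)
        cds = sorted(feats.of_kind("CDS"), key=lambda f: f.start)
        for a, b in zip(cds, cds[1:]):
            assert b.start - a.end >= 50

    def test_overlapping_protoclusters_constructible(self):
        g = generate_genome(80_000, gc=0.5, seed=24)
        g, feats1 = implant_cluster(g, n_flank_genes=2, cluster_type="T1PKS",
                                    nat_position=3, seed=11, start=10_000,
                                    cluster_id="pcA")
        end_a = feats1.of_kind("protocluster")[0].end
        g, feats2 = implant_cluster(g, n_flank_genes=2, cluster_type="NRPS",
                                    nat_position=1, seed=12,
                                    start=end_a - 100, cluster_id="pcB")
        # 100 bp overlap between the two protocluster features by layout
        pc_a = feats1.of_kind("protocluster")[0]
        pc_b = feats2.of_kind("protocluster")[0]
        assert pc_a.end > pc_b.start  # overlapping protocluster features


class TestImplantGcIsland:
    def test_island_gc_within_tolerance(self):
        g = generate_genome(100_000, gc=0.60, seed=31)
        g2 = implant_gc_island(g, start=40_000, length=10_000,
                               island_gc=0.30, seed=9)
        seq = g2.contigs.records[0].sequence[40_000:50_000]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.30) < 0.02
        assert g2.total_length() == g.total_length()

    def test_two_islands_recorded_non_overlapping(self):
        g = generate_genome(100_000, gc=0.60, seed=32)
        g = implant_gc_island(g, 10_000, 5_000, 0.30, seed=1)
        g = implant_gc_island(g, 50_000, 5_000, 0.30, seed=2)
        assert len(g.islands) == 2
        with pytest.raises(ValueError, match="overlap"):
            implant_gc_island(g, 12_000, 5_000, 0.30, seed=3)

    def test_out_of_bounds_rejected(self):
        g = generate_genome(10_000, gc=0.5, seed=33)
        with pytest.raises(ValueError, match="bounds"):
            implant_gc_island(g, 8_000, 5_000, 0.3, seed=1)


class TestEvolveFamily:
    def test_zero_rate_identical(self):
        seed_prot = random_protein(100, seed=5)
        fam = evolve_family(FamilyConfig(seed_prot, n_taxa=4,
                                         substitution_rate=0.0, rng_seed=3))
        assert all(r.sequence == seed_prot for r in fam)

    def test_deterministic_under_seed(self):
        seed_prot = random_protein(100, seed=5)
        cfg = FamilyConfig(seed_prot, 5, 0.1, rng_seed=17)
        a = evolve_family(cfg)
        b = evolve_family(FamilyConfig(seed_prot, 5, 0.1, rng_seed=17))
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_star_tree_pairwise_distance_matches_site_oracle(self):
        # independent per-site Monte-Carlo oracle for the expected pairwise
        # difference between two taxa on a star tree of unit branches
        rate = 0.08
        rng = np.random.default_rng(99)
        n_sim = 200_000
        p = 1.0 - np.exp(-rate)
        mut_a = rng.random(n_sim) < p
        mut_b = rng.random(n_sim) < p
        # same target only when both mutate and pick the same of 19 residues
        same_target = rng.integers(0, 19, n_sim) == rng.integers(0, 19, n_sim)
        differ = (mut_a ^ mut_b) | (mut_a & mut_b & ~same_target)
        expected = float(differ.mean())

        seed_prot = random_protein(4000, seed=6)
        fam = evolve_family(FamilyConfig(seed_prot, n_taxa=6,
                                         substitution_rate=rate, rng_seed=4))
        arrs = [np.array(list(r.sequence)) for r in fam]
        observed = np.mean([
            (arrs[i] != arrs[j]).mean()
            for i in range(6) for j in range(i + 1, 6)
        ])
        assert observed == pytest.approx(expected, abs=0.01)

    def test_four_point_condition_on_guide_tree(self):
        # AB|CD topology: the within-pair distance sums stay below the
        # across-pair sums on average over seeded replicates
        newick = "((A:0.3,B:0.3):0.4,(C:0.3,D:0.3):0.4);"
        seed_prot = random_protein(300, seed=7)
        within, across = [], []
        for rep in range(100):
            tree = TreeNode.read(iter([newick]))
            fam = evolve_family(FamilyConfig(
                seed_prot, 4, substitution_rate=1.0, guide_tree=tree,
                rng_seed=1000 + rep))
            seqs = {r.id: np.array(list(r.sequence)) for r in fam}
            d = lambda x, y: float((seqs[x] != seqs[y]).mean())
            within.append(d("A", "B") + d("C", "D"))
            across.append(d("A", "C") + d("B", "D"))
        assert np.mean(within) < np.mean(across)

    def test_guide_tree_leaf_mismatch_rejected(self):
        tree = TreeNode.read(iter(["((A:1,B:1):1,C:1);"]))
        with pytest.raises(ValueError, match="leaves"):
            evolve_family(FamilyConfig(random_protein(50, seed=1), 4, 0.1,
                                       guide_tree=tree))


def test_seed_splitting_stable_and_distinct():
    assert derive_seed(1, "stage", "x") == derive_seed(1, "stage", "x")
    assert derive_seed(1, "stage", "x") != derive_seed(1, "stage", "y")
    assert derive_seed(1, "stage", "x") != derive_seed(2, "stage", "x")
    assert 0 <= derive_seed(123, "a") < 2 ** 63


def test_nat_seed_protein_contains_motifs_in_order():
    prot = make_nat_protein(seed=11)
    positions = [prot.find(m) for m in ("VPFENL", "RGGYC", "THRL", "VDV")]
    assert all(p >= 0 for p in positions)
    assert positions == sorted(positions)
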