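"""Biosynthetic-gene-cluster context of a NAT gene.

Implants a T1PKS-like neighborhood with the NAT gene as its last member
(the layout of ansamycin clusters, where the amide synthase sits at the end
of the core cluster), then asks which protoclusters the locus belongs to
and whether two copies of the cluster are 100% conserved syntenic units.
"""

from natminer import (assign_membership, generate_genome, implant_cluster,
                      map_synteny, protoclusters_from_features,
                      reconstruct_orf, translated_genome_search)
from natminer.synthetic_data import derive_seed, make_nat_protein

from natminer.cluster_context import Protocluster

genome = generate_genome(80_000, gc=0.6, seed=7, replicon_id="bgc_demo")
nat_protein = make_nat_protein(derive_seed(7, "natprot", "pksA"))
genome, featsA = implant_cluster(genome, n_flank_genes=5,
                                 cluster_type="T1PKS", nat_position=6,
                                 seed=7, start=10_000, cluster_id="pksA",
                                 nat_protein=nat_protein)
pksA = protoclusters_from_features(featsA)[0]
# a strain-level copy of the same cluster: identical gene content and order,
# living on another replicon
pksB = Protocluster("pksB", "other_replicon", pksA.span, pksA.cluster_type,
                    pksA.genes)
clusters = [pksA, pksB]
for pc in clusters:
    print(f"{pc.cluster_id}: span {pc.span}, type {pc.cluster_type}, "
          f"{len(pc.genes)} genes")

hits = translated_genome_search(nat_protein, genome)
locus = reconstruct_orf([hits[0]], genome, locus_id="nat_in_pksA")
print("locus", locus.segments[0][:2], "is member of:",
      assign_membership(locus, clusters))

sm = map_synteny(clusters)
print("conservation groups:", sm.groups())
# Two byte-identical cluster layouts collapse into one syntenic unit,
# represented by the lexicographically first cluster id.
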