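# natminer

A desk-scale, fully reproducible pipeline for surveying microbial
**arylamine N-acetyltransferase (NAT)** genes — the enzyme family
(E.C. 2.3.1.5) that transfers an acyl group from acyl-CoA to aromatic
amines, and whose homologues also serve secondary metabolism (e.g. the
amide synthase RifF that closes the rifamycin macrolactam at the end of its
biosynthetic gene cluster).

`natminer` is written for computational biologists who want every stage of
such a genomic survey as tested, importable Python, runnable end-to-end on a
laptop: no BLAST servers, no web portals, no database snapshots.  A seeded
synthetic-genome generator stands in for the genome downloads, providing
exact ground truth against which every stage is scored.

## What it does

- **Translated homology search** (`homology_search`) — the tBLASTn/BLASTp
  role, done by exact six-frame translation plus affine-gap local alignment
  (BLOSUM62, gap open 11 / extend 1; a gap of length *L* costs
  open + (L−1)·extend), with Karlin–Altschul expectation values
  E = K·m·n·e^(−λS) (K = 0.041, λ = 0.267).
- **NAT annotation** (`nat_annotate`) — ORF reconstruction including
  joining of frameshifted fragments into multi-segment pseudogene loci;
  scanning for the four semi-conserved motifs `VPFENL`, `RGGYC`, `THRL`,
  `VDV`; verification of the Cys-His-Asp catalytic triad (Glu-for-Asp
  variants flagged); species-level symbol assignment (NAT1, NAT2, …) by
  percent identity to a reference.
- **BGC context** (`cluster_context`) — 500 kb (prokaryote) / 1 Mb
  (eukaryote) flank extraction with partial-ORF trimming, overlap-based
  protocluster membership, and bidirectional-best-hit synteny with strict
  100%-conservation grouping.
- **Networks and trees** (`network_phylo`) — sequence similarity networks
  at an alignment-score threshold of −log₁₀E (default 29, i.e. E ≤ 1e−29),
  center-star alignment, p-distances, neighbor-joining trees and bootstrap
  supports.
- **Plasmids and islands** (`plasmid_island`) — plasmid screening at the
  relaxed 40% identity threshold; GC-deviation genomic-island detection and
  island/locus intersection.
- **Survey aggregation** (`survey_report`) — long-format survey tables
  (one row per locus-cluster membership) and bundled fixtures of the
  survey's printed tables for exact count reproduction.
- **Synthetic data** (`synthetic_data`) — seeded replicons with
  configurable GC, implanted NAT-like ORFs (intact / frameshifted /
  truncated), BGC-like neighborhoods, low-GC islands, and protein families
  evolved from a seed sequence; every implant recorded in an exact
  ground-truth manifest.

## Worked example

`examples/01_search_and_annotate.py` implants one intact NAT gene and one
frameshifted pseudogene into a 20 kb mock replicon, then runs
search → reconstruction → classification:

```
3 translated hits:
  demo_c1:3000-3840 frame +1 identity 100.0% E 5.87e-184
  demo_c1:12003-12486 frame -2 identity 98.1% E 3.64e-101
  demo_c1:12476-12842 frame -3 identity 100.0% E 2.81e-77
locus1: 1 segment(s), intact, triad canonical_CHD, symbol NAT1, identity 100.0%
locus2: 2 segment(s), frameshifted_pseudogene, triad canonical_CHD, symbol NAT2, identity 99.6%
```

The intact gene is found as a single full-identity hit in one reading
frame.  The pseudogene surfaces as two abutting hits in frames differing by
one — the signature of a single-nucleotide frameshift — which the annotator
joins into a two-segment locus, classifies as a frameshifted pseudogene,
and still names (NAT2: lower identity than the intact copy within the same
species).  The other scripts in `examples/` cover BGC context and synteny,
SSNs and bootstrapped NJ trees, plasmid/island screening, and the bundled
survey tables; each prints a few annotated lines like the above.

A thin CLI mirrors the library for shell use:

```bash
natminer search --query ref.faa --genome genome.fna --out hits.tsv
natminer ssn --proteins nat.faa --threshold 29 --out ssn.tsv
natminer tree --proteins nat.faa --bootstrap 1000 --seed 7 --out tree.nwk
natminer islands --genome plasmid.fna --out islands.tsv
natminer fixtures --check
```

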