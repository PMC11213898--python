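# Methods

This note records the models, rules and numerical choices behind
`natminer`, and what its synthetic benchmarks do and do not demonstrate
about real data.

## Detection model

Candidate NAT genes are detected by exact translated search: every contig
is translated in all six reading frames (codon table 11; stops rendered
`*`, ambiguity codes `X`), and the protein query is aligned to each frame
by optimal affine-gap local alignment (Gotoh dynamic programming, via
biotite's C kernel).  Scoring follows BLAST-family defaults — BLOSUM62,
gap open 11, gap extension 1 — with the convention that a gap of length
*L* costs `open + (L-1)·extend`.  Within a frame, multiple loci are found
by repeated optimal alignment with masking of previously aligned subject
residues, which also collapses overlapping same-frame hits to the
best-scoring one.  There is no heuristic seeding: results are deterministic
and exactly reproducible, at the price of speed — the intended scale is
kilobase-to-megabase replicons, not database-wide scans.

Expectation values use the Karlin–Altschul form `E = K·m·n·exp(-λS)` with
fixed gapped-BLOSUM62 constants K = 0.041, λ = 0.267, where *m* is the
query length and *n* the database size in residues (for translated
searches, 2 nt per residue summed over six frames ≈ 2× genome length).
Fixing the constants keeps E-values comparable across runs; they are not
re-estimated per search.

Frame-joining is deliberately *not* done by the search: a frameshifted
pseudogene appears as two same-strand hits in frames differing by one,
and interpreting that pattern is the annotator's job.

## Annotation model

`reconstruct_orf` extends hits in-frame — the 5'-most hit upstream to the
nearest ATG (stopping at an in-frame stop codon, or at the contig edge
which sets `partial_5p`), the 3'-most hit downstream to the nearest stop
(contig edge sets `partial_3p`) — merges same-frame hits, and joins
different-frame neighbours at the midpoint of their genomic gap, rounded
to codon boundaries.  The midpoint rule bounds the reconstruction error by
the gap length; for single-nucleotide indels the joined protein is within
edit distance 2 of the lesioned original (boundary-codon ambiguity).
Slightly overlapping hits around a lesion are disjoined in codon steps.

Motif annotation operationalizes "semi-conserved": each window of
consensus length is scored with BLOSUM62 against the consensus
(`VPFENL`, `RGGYC`, `THRL`, `VDV`), and a window is a candidate when it
reaches ≥ 60% of the consensus self-score *and* carries the catalytic
residue exactly (Cys in `RGGYC`, His in `THRL`, Asp in `VDV`, with Glu
accepted but flagged as the variant triad).  The best mutually compatible
combination with motif order M1 < M2 < M3 < M4 is selected by dynamic
programming.  The 0.6 fraction admits all four consensi and single
conservative substitutions while rejecting random 280-residue proteins
(measured: ≤ 2/50 random proteins reach three motifs).

Classification: a locus is `non_nat` unless at least three motifs are
found, the triad is not absent, and its best reference identity/coverage
reach the callable thresholds (defaults 25% identity, 75% coverage —
deliberately permissive; the motif/triad rule is the primary filter).
Callable loci are `frameshifted_pseudogene` if multi-segment, `truncated`
if partial, else `intact`.  Within a species, symbols NAT1, NAT2, … are
assigned in descending best identity, ties broken by genomic coordinate,
making nomenclature invariant to input order.  The exact identity bands of
the formal nomenclature guidelines are not public; the thresholds here are
configuration with documented defaults.

## Cluster context

Flank extraction takes 500 kb per side around prokaryotic loci and 1 Mb
around eukaryotic ones, clipped at contig ends; any feature crossing a
window edge is dropped entirely, mirroring the partial-ORF trimming
required before cluster prediction.  Cluster prediction itself is out of
scope: protoclusters are consumed as feature tables (antiSMASH-style
GenBank/GFF3 or synthetic), and a locus overlapping several protoclusters
by ≥ 1 base belongs to all of them — the overlap threshold is one base
because the membership rule is stated without a minimum.

Synteny between clusters is mapped by bidirectional best hits of their
gene products (identity measured over the aligned span).  Two clusters are
100%-conserved only if the BBH links form a bijection covering every gene
of both, in identical or fully reversed order, with all identities exactly
100%; conservation groups are the transitive closure, represented by the
lexicographically smallest cluster id.  The strictness is intentional — a
single 95%-identical gene separates two clusters.

## Networks and trees

The multiple alignment is a center-star construction: the center maximizes
its summed pairwise global alignment score; every other sequence is
aligned globally to the center; columns are the center positions
(insertions relative to the center are not columns).  Distances are
p-distances over shared non-gap columns — the protein neighbor-joining
default of the common tree packages; a distance correction can be applied
by the caller before tree building.  For the synthetic families the model
generates (substitutions only, no indels) the projection is exact.

Neighbor-joining uses the standard Saitou–Nei agglomeration (delegated to
scikit-bio) with negative branch-length estimates clamped to zero; it is
exactly consistent on additive matrices, which the tests verify by path
length.  Two-taxon inputs return the single-edge tree directly.  Bootstrap
resamples alignment columns with replacement, rebuilds the tree per
replicate, and reports the percentage of replicates containing each
original bipartition; runs are bit-reproducible under a fixed seed.
Maximum-likelihood trees are out of scope.

The SSN edge rule interprets the "alignment score" threshold as
−log₁₀ E under this package's E-value model, computed per pair with *n* =
total residues in the set.  At the default threshold of 29 an edge means
E ≤ 1e−29; identical ~200-residue proteins connect, unrelated random
100-mers do not (≥ 99/100 seeded replicates).  Absolute edge sets will
differ from web tools with different E-value models; only the threshold
semantics are reproduced.

## Plasmids and islands

Plasmid screening is the translated search with the identity threshold
relaxed to 40%, the value that maximizes non-redundant plasmid hits;
per-plasmid hit counts are reported because plasmids often carry several
NAT genes.  The threshold is interpreted as percent identity of the local
alignment (configurable), since the screening tool's exact HSP semantics
are not published.

Genomic islands are detected from sliding-window GC content (window
1000 bp, step 500 bp — resolving islands ≥ 5 kb): a window is flagged when
its GC deviates from the replicon mean by ≥ 2 standard deviations of the
window distribution *and* by ≥ 0.05 in absolute GC fraction.  The absolute
floor is needed because on a compositionally uniform replicon the window
standard deviation collapses toward binomial sampling noise (and to zero
on a literally constant sequence), where a pure z-rule would flag noise or
everything; 0.05 is far above sampling noise for 1 kb windows (~1.5%) and
far below real island contrasts (10–30%).  Adjacent flagged windows of one
direction merge into maximal calls.  This compositional detector is an
explicit, documented proxy for codon-usage/HMM island finders
(SIGI-HMM, IslandPath-DIMOB), which are external tools; it detects
composition, not mobility genes.

## Synthetic data: what it emulates, and what it does not

The generator produces i.i.d. background sequence at a requested GC,
back-translates proteins with uniform synonymous codon choice (table 11),
and applies exactly one lesion per implant: a single-nucleotide deletion
(downstream frame −1, one residue lost), a single-nucleotide insertion at
a codon boundary (frame +1, no residue lost), or truncation of 20–40% of
the codons at one end.  Islands are i.i.d. resampled intervals.  Families
evolve by per-site substitution with probability 1 − e^(−rate·branch),
uniform over the other 19 residues, on a star tree of unit branches or a
supplied guide tree.  One global 64-bit seed is split per stage by stable
hashing of (seed, stage, entity), so reproducibility does not depend on
call order; all derived seeds stay below 2⁶³.

What this does *not* emulate: codon-usage bias, repeats and mobile
elements, real intergenic structure, sequencing error, multi-indel
pseudogenes, fungal introns (generated genes are intron-less), and
horizontal transfer itself (islands are compositional only).  Passing the
recovery benchmarks therefore shows the pipeline's logic is correct under
the stated model — exact coordinate-level recovery, correct lesion
classification, no false calls on i.i.d. background — not that its
thresholds are optimal for any particular real genome collection.

## Benchmarks and problem sizes

The recovery benchmark implants 50 mixed-lesion loci (30 intact, 10
frameshifted, 10 truncated, alternating strands, up to 10% divergence
outside the motif windows) across 20 replicons of 12 kb and runs the full
pipeline with one reference query; the island benchmark implants one
10 kb low-GC island (0.30 vs 0.60 background) in each of five 100 kb
replicons.  These sizes keep a complete run in tens of seconds while
exercising every code path; all rates are computed against the generator
manifest, never against the pipeline's own output.

## Bundled fixtures

The printed survey tables (fungal BGCs, plasmid counts, plasmid-BGC genes,
MIBiG-characterized NAT homologues) ship as TSV fixtures transcribed
verbatim, and the fungal genus→class map (Aspergillus, Penicillium →
Eurotiomycetes; Acremonium, Myceliophthora, Verticillium →
Sordariomycetes) is an explicit fixture rather than a taxonomy-service
lookup, for determinism.  Percentages are displayed integer-rounded, full
precision retained internally.  The named reference accessions (e.g. the
geldanamycin amide synthase pair) are not redistributable here; the
corresponding checks load user-supplied FASTA/TSV from `data/external/`,
and synthetic generator-derived references are the default everywhere
else.

## Known limitations

- Exact DP search does not scale to database-wide surveys; it is the
  desk-scale replacement for heuristic search, not a competitor.
- E-values use fixed constants; for unusual compositions the absolute
  values (not the ordering) will be off.
- Center-star alignment degrades for deeply diverged, indel-rich families;
  the distance matrix is exact only under the generator's indel-free model.
- The island detector is compositional; islands whose GC matches the host
  are invisible to it by construction.
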