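"""End-to-end recovery benchmarks on synthetic genomes.

These harnesses generate seeded replicons with implanted NAT-like loci (and
GC islands), run the full detection → reconstruction → classification
pipeline, and score the result against the generator's exact ground truth.
They are used by the test suite and the reproduction script; the problem
sizes default to a desk-scale setting (tens of replicons of ~12 kb) chosen
so a full run completes in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from .homology_search import SearchHit, translated_genome_search
from .formats_io import Record, SeqRecordSet
from .nat_annotate import classify_and_name, reconstruct_orf, scan_motifs
from .plasmid_island import detect_gc_islands
from .synthetic_data import (derive_seed, generate_genome, implant_gc_island,
                             implant_locus, make_nat_protein)

LESION_CYCLE = (
    "none", "none", "none", "frameshift_del1", "none",
    "frameshift_ins1", "none", "truncation_5p", "none", "truncation_3p",
)


def mutate_outside_motifs(protein: str, rate: float, rng: np.random.Generator,
                          motif_hits=None) -> str:
    """Substitute residues at ``rate`` everywhere except inside the four
    NAT motif windows (so motif/triad annotation stays intact)."""
    from .synthetic_data import AMINO_ACIDS

    if motif_hits is None:
        motif_hits = scan_motifs(protein)
    protected = set()
    for hit in motif_hits.values():
        if hit is not None:
            protected.update(range(hit.position, hit.position + len(hit.matched)))
    out = list(protein)
    for i in range(1, len(out)):  # keep the start Met
        if i in protected:
            continue
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def group_hits(hits: list[SearchHit], max_gap: int = 500
               ) -> list[list[SearchHit]]:
    """Group search hits into candidate loci: same contig and strand, with
    genomic gaps of at most ``max_gap`` bases (frameshift fragments abut
    within a few codons; distinct genes lie much further apart)."""
    groups: list[list[SearchHit]] = []
    for hit in sorted(hits, key=lambda h: (h.contig, h.strand, h.start)):
        if (groups
                and groups[-1][-1].contig == hit.contig
                and groups[-1][-1].strand == hit.strand
                and hit.start - groups[-1][-1].end <= max_gap):
            groups[-1].append(hit)
        else:
            groups.append([hit])
    return groups


def run_recovery_benchmark(
    seed: int,
    n_replicons: int = 20,
    n_implants: int = 50,
    replicon_length: int = 12_000,
    divergence: float = 0.10,
    min_identity: float = 40.0,
    max_evalue: float = 1e-6,
) -> dict[str, float]:
    """Implant ``n_implants`` NAT-like loci (mixed lesions) across
    ``n_replicons`` replicons, run the search/annotation pipeline with one
    reference query, and score recovery against the manifest.

    Returns intact recovery and frameshift-flagging percentages, the number
    of false NAT calls on non-implanted sequence, and the raw counts.
    """
    reference = make_nat_protein(derive_seed(seed, "reference"))
    refs = SeqRecordSet([Record("NATref", "survey reference", reference)],
                        alphabet="protein")
    slots = [1000, 5000, 9000]
    per_replicon = [n_implants // n_replicons] * n_replicons
    for i in range(n_implants - sum(per_replicon)):
        per_replicon[i] += 1
    if max(per_replicon) > len(slots):
        raise ValueError("too many implants per replicon for the slot layout")

    rng = np.random.default_rng(derive_seed(seed, "benchmark"))
    implant_idx = 0
    n_intact = n_intact_ok = 0
    n_frameshift = n_frameshift_ok = 0
    n_truncated = 0
    false_calls = 0

    for rep in range(n_replicons):
        genome = generate_genome(
            replicon_length, gc=float(rng.uniform(0.35, 0.65)),
            seed=derive_seed(seed, "replicon", rep),
            replicon_id=f"bench{rep}")
        for j in range(per_replicon[rep]):
            lesion = LESION_CYCLE[implant_idx % len(LESION_CYCLE)]
            protein = mutate_outside_motifs(
                reference, divergence,
                np.random.default_rng(derive_seed(seed, "mut", implant_idx)))
            strand = "+" if implant_idx % 2 == 0 else "-"
            genome, _ = implant_locus(
                genome, protein, position=slots[j], strand=strand,
                lesion=lesion, seed=derive_seed(seed, "implant", implant_idx),
                locus_id=f"bench{rep}_L{j}")
            implant_idx += 1

        hits = translated_genome_search(
            reference, genome, min_identity=min_identity,
            max_evalue=max_evalue)
        loci = [
            reconstruct_orf(group, genome, locus_id=f"called{rep}_{gi}")
            for gi, group in enumerate(group_hits(hits))
        ]
        annotations = classify_and_name(loci, refs)

        called = [
            (locus, ann) for locus, ann in zip(loci, annotations)
            if ann.classification != "non_nat"
        ]
        for entry in genome.implants:
            span = entry.span
            match = [
                (locus, ann) for locus, ann in called
                if locus.contig == entry.contig
                and min(e for _, e, _ in locus.segments) > span[0] - 1000
                and max(s for s, _, _ in locus.segments) < span[1] + 1000
                and max(e for _, e, _ in locus.segments) > span[0]
                and min(s for s, _, _ in locus.segments) < span[1]
            ]
            if entry.lesion == "none":
                n_intact += 1
                if match and match[0][1].classification == "intact":
                    n_intact_ok += 1
            elif entry.lesion.startswith("frameshift"):
                n_frameshift += 1
                if match and match[0][1].classification == "frameshifted_pseudogene":
                    n_frameshift_ok += 1
            else:
                n_truncated += 1
        implant_spans = [e.span for e in genome.implants]
        for locus, ann in called:
            l_start = min(s for s, _, _ in locus.segments)
            l_end = max(e for _, e, _ in locus.segments)
            if not any(l_start < e and l_end > s for s, e in implant_spans):
                false_calls += 1

    return {
        "n_implants": float(implant_idx),
        "n_intact": float(n_intact),
        "n_frameshift": float(n_frameshift),
        "n_truncated": float(n_truncated),
        "intact_recovery_pct": 100.0 * n_intact_ok / max(n_intact, 1),
        "frameshift_flagged_pct": 100.0 * n_frameshift_ok / max(n_frameshift, 1),
        "false_nat_calls": float(false_calls),
    }


def run_island_benchmark(
    seed: int,
    n_genomes: int = 5,
    genome_length: int = 100_000,
    background_gc: float = 0.60,
    island_gc: float = 0.30,
    island_length: int = 10_000,
) -> dict[str, float]:
    """Implant one low-GC island per genome and measure how much of each
    implanted interval the GC-deviation detector recovers."""
    overlaps = []
    extra_calls = 0
    for rep in range(n_genomes):
        genome = generate_genome(
            genome_length, gc=background_gc,
            seed=derive_seed(seed, "islandgenome", rep),
            replicon_id=f"isl{rep}")
        start = 20_000 + 10_000 * rep
        genome = implant_gc_island(
            genome, start=start, length=island_length, island_gc=island_gc,
            seed=derive_seed(seed, "island", rep))
        calls = detect_gc_islands(genome)
        truth = genome.islands[0]
        covered = 0
        for call in calls:
            ov = (min(call.span[1], truth.end) - max(call.span[0], truth.start))
            if ov > 0:
                covered += ov
            else:
                extra_calls += 1
        overlaps.append(100.0 * min(covered, island_length) / island_length)
    return {
        "island_overlap_pct": float(np.mean(overlaps)),
        "island_min_overlap_pct": float(np.min(overlaps)),
        "island_extra_calls": float(extra_calls),
    }
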