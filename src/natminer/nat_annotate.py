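"""Annotation of candidate NAT loci.

Arylamine N-acetyltransferases are recognized by four semi-conserved motifs
("VPFENL", "RGGYC", "THRL", "VDV") that together house the Cys-His-Asp
catalytic triad (Cys in RGGYC, His in THRL, Asp in VDV; a Glu-for-Asp variant
is tolerated but flagged).  This module reconstructs open reading frames from
translated search hits — joining frameshifted fragments into multi-segment
loci — scans the translated product for the motifs, verifies the triad, and
assigns species-specific gene symbols (NAT1, NAT2, ...) by percent identity
to a reference sequence.

"Semi-conserved" is operationalized as a BLOSUM62 window score of at least
``min_score_fraction`` (default 0.6) of the consensus self-score, with the
catalytic residue required to match exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formats_io import Feature, FeatureTable, SeqRecordSet
from .homology_search import (BLOSUM62, SearchHit, align_proteins,
                              translate_six_frames)
from .synthetic_data import GenomeRecord, _revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


@dataclass(frozen=True)
class MotifDefinition:
    motif_id: str
    consensus: str
    catalytic_index: int | None = None  # position of the triad residue
    catalytic_residue: str | None = None
    min_score_fraction: float = 0.6

    @property
    def self_score(self) -> int:
        return sum(BLOSUM62.get_score(a, a) for a in self.consensus)


DEFAULT_MOTIFS = (
    MotifDefinition("M1", "VPFENL"),
    MotifDefinition("M2", "RGGYC", catalytic_index=4, catalytic_residue="C"),
    MotifDefinition("M3", "THRL", catalytic_index=1, catalytic_residue="H"),
    MotifDefinition("M4", "VDV", catalytic_index=1, catalytic_residue="D"),
)


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    position: int  # 0-based start of the window in the protein
    matched: str
    score_fraction: float
    catalytic_variant: bool = False  # Glu instead of Asp in M4


@dataclass(frozen=True)
class NatLocus:
    """A candidate NAT gene as an ordered list of coordinate segments.

    Segments are (start, end, frame) in forward contig coordinates, ordered
    5'->3' on the coding strand; consecutive segments differ in frame (a
    frameshift join).  ``protein`` is the concatenated per-segment
    translation.
    """

    locus_id: str
    contig: str
    strand: str
    segments: tuple[tuple[int, int, int], ...]
    protein: str
    partial_5p: bool = False
    partial_3p: bool = False


@dataclass
class AnnotationResult:
    locus_id: str
    motif_hits: dict[str, MotifHit | None] = field(default_factory=dict)
    triad_status: str = "absent"
    classification: str = "non_nat"
    best_reference: str = ""
    best_identity: float = 0.0
    best_coverage: float = 0.0
    assigned_symbol: str = ""


# ---------------------------------------------------------------------------
# ORF reconstruction
# ---------------------------------------------------------------------------

def _translate_codons(seq: str) -> str:
    from Bio.Seq import Seq
    sub = seq[: len(seq) - (len(seq) % 3)]
    return str(Seq(sub).translate(table=11)) if sub else ""


def reconstruct_orf(
    hits: list[SearchHit],
    genome: GenomeRecord,
    locus_id: str = "locus",
    max_upstream_scan: int = 300,
    max_downstream_scan: int = 3000,
) -> NatLocus:
    """Reconstruct an open reading frame from translated search hits of one
    genomic locus.

    Each hit is extended in-frame: the 5'-most hit upstream to the nearest
    start codon (stopping at a stop codon or the contig edge, the latter
    setting ``partial_5p``), the 3'-most hit downstream to the nearest stop
    codon (contig edge sets ``partial_3p``).  Same-frame hits are merged;
    different-frame hits are joined at the midpoint of their genomic gap,
    yielding a multi-segment locus whose protein is the concatenation of the
    per-segment translations.
    """
    if not hits:
        raise ValueError("reconstruct_orf needs at least one hit")
    contigs = {h.contig for h in hits}
    strands = {h.strand for h in hits}
    if len(contigs) > 1 or len(strands) > 1:
        raise ValueError("hits span multiple contigs or strands")
    contig, strand = contigs.pop(), strands.pop()
    fwd = genome.contig_seq(contig)
    n = len(fwd)
    # work on the coding strand: for '-' loci, flip into reverse-complement
    # coordinates so that downstream means increasing position
    coding = fwd if strand == "+" else _revcomp(fwd)

    def to_coding(span: tuple[int, int]) -> tuple[int, int]:
        if strand == "+":
            return span
        return n - span[1], n - span[0]

    spans = sorted(to_coding(h.genomic_span) for h in hits)
    # merge same-frame overlapping/adjacent spans
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s % 3 == merged[-1][0] % 3 and s <= merged[-1][1] + 3:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    partial_5p = partial_3p = False
    # extend the 5'-most segment upstream to the nearest start codon
    s0 = merged[0][0]
    pos = s0
    found_start = False
    while pos >= 0 and s0 - pos <= max_upstream_scan:
        codon = coding[pos:pos + 3]
        if codon in STOP_CODONS and pos != s0:
            break
        if codon == START_CODON:
            found_start = True
            merged[0][0] = pos
            break
        pos -= 3
    if not found_start and merged[0][0] < 3:
        partial_5p = True

    # extend the 3'-most segment downstream to the nearest stop codon
    e_last = merged[-1][1]
    pos = e_last
    while True:
        if pos + 3 > len(coding):
            partial_3p = True
            merged[-1][1] = pos
            break
        codon = coding[pos:pos + 3]
        if codon in STOP_CODONS:
            merged[-1][1] = pos
            break
        if pos - e_last >= max_downstream_scan:
            merged[-1][1] = pos
            break
        pos += 3

    # join different-frame neighbours at the midpoint of their genomic gap
    for i in range(len(merged) - 1):
        end_i, start_j = merged[i][1], merged[i + 1][0]
        if start_j < end_i:
            # slight overlap around the lesion: trim the downstream segment
            # in codon steps so segments stay disjoint and in phase
            merged[i + 1][0] = start_j + 3 * ((end_i - start_j + 2) // 3)
            continue
        mid = (end_i + start_j) // 2
        merged[i][1] = end_i + 3 * ((mid - end_i) // 3)
        merged[i + 1][0] = start_j - 3 * ((start_j - merged[i][1]) // 3)

    protein = "".join(_translate_codons(coding[s:e]) for s, e in merged)

    segments = []
    for s, e in merged:
        if strand == "+":
            fs, fe = s, e
            frame = (fs % 3) + 1
        else:
            fs, fe = n - e, n - s
            frame = -(((n - fe) % 3) + 1)
        segments.append((fs, fe, frame))
    return NatLocus(
        locus_id=locus_id, contig=contig, strand=strand,
        segments=tuple(segments), protein=protein,
        partial_5p=partial_5p, partial_3p=partial_3p,
    )


# ---------------------------------------------------------------------------
# Motif scanning and triad verification
# ---------------------------------------------------------------------------

def _window_candidates(protein: str, mdef: MotifDefinition) -> list[MotifHit]:
    w = len(mdef.consensus)
    self_score = mdef.self_score
    out = []
    for pos in range(len(protein) - w + 1):
        window = protein[pos:pos + w]
        if any(ch not in BLOSUM62.get_alphabet1() for ch in window):
            continue
        variant = False
        if mdef.catalytic_index is not None:
            res = window[mdef.catalytic_index]
            if mdef.catalytic_residue == "D" and res == "E":
                variant = True
            elif res != mdef.catalytic_residue:
                continue
        score = sum(BLOSUM62.get_score(a, b)
                    for a, b in zip(mdef.consensus, window))
        frac = score / self_score
        if frac >= mdef.min_score_fraction:
            out.append(MotifHit(mdef.motif_id, pos, window, frac, variant))
    return out


def scan_motifs(
    protein: str,
    defs: tuple[MotifDefinition, ...] = DEFAULT_MOTIFS,
) -> dict[str, MotifHit | None]:
    """Scan a protein for the semi-conserved NAT motifs.

    Every window of consensus length is scored with BLOSUM62; a window is a
    candidate if it reaches the score fraction and carries the catalytic
    residue.  The best compatible combination with motif positions in order
    M1 < M2 < M3 < M4 is selected by dynamic programming (maximizing number
    of motifs found, then total score fraction).
    """
    if len(protein) < 30:
        return {d.motif_id: None for d in defs}
    candidates = [_window_candidates(protein, d) for d in defs]
    # DP over motifs: state = (motif index, chosen hit or skip), positions
    # strictly increasing and windows non-overlapping
    best: dict[tuple[int, int], tuple[int, float, list[MotifHit | None]]] = {}

    def solve(i: int, min_pos: int) -> tuple[int, float, list[MotifHit | None]]:
        if i == len(defs):
            return (0, 0.0, [])
        key = (i, min_pos)
        if key in best:
            return best[key]
        # option: skip this motif
        cnt, tot, rest = solve(i + 1, min_pos)
        result = (cnt, tot, [None] + rest)
        for hit in candidates[i]:
            if hit.position < min_pos:
                continue
            cnt2, tot2, rest2 = solve(i + 1, hit.position + len(hit.matched))
            cand = (cnt2 + 1, tot2 + hit.score_fraction, [hit] + rest2)
            if (cand[0], cand[1]) > (result[0], result[1]):
                result = cand
        best[key] = result
        return result

    _, _, chosen = solve(0, 0)
    return {d.motif_id: h for d, h in zip(defs, chosen)}


def verify_triad(motif_hits: dict[str, MotifHit | None]) -> str:
    """Catalytic-triad status from motif hits: ``canonical_CHD`` (Cys, His,
    Asp all present), ``variant_CHE`` (Glu for Asp), ``incomplete`` (one or
    two present) or ``absent``."""
    c = motif_hits.get("M2")
    h = motif_hits.get("M3")
    d = motif_hits.get("M4")
    present = sum(x is not None for x in (c, h, d))
    if present == 3:
        return "variant_CHE" if d.catalytic_variant else "canonical_CHD"
    if present >= 1:
        return "incomplete"
    return "absent"


# ---------------------------------------------------------------------------
# Classification and nomenclature
# ---------------------------------------------------------------------------

def classify_and_name(
    loci: list[NatLocus],
    references: SeqRecordSet,
    motif_results: list[dict[str, MotifHit | None]] | None = None,
    triad_statuses: list[str] | None = None,
    min_identity: float = 25.0,
    min_coverage: float = 75.0,
    symbol_prefix: str = "NAT",
) -> list[AnnotationResult]:
    """Classify loci and assign species-specific gene symbols.

    A locus is ``non_nat`` if fewer than three motifs are found, the triad is
    absent, or its best reference identity/coverage falls below the callable
    thresholds.  Otherwise it is ``frameshifted_pseudogene`` (more than one
    segment), ``truncated`` (partial flags), or ``intact``.  Callable loci of
    one species are numbered NAT1, NAT2, ... in descending best identity
    (ties by genomic coordinate), which makes the assignment invariant to
    input order.
    """
    if len(references) == 0:
        raise ValueError("references must be non-empty")
    if motif_results is None:
        motif_results = [scan_motifs(l.protein) for l in loci]
    if triad_statuses is None:
        triad_statuses = [verify_triad(m) for m in motif_results]

    results = []
    for locus, motifs, triad in zip(loci, motif_results, triad_statuses):
        n_motifs = sum(h is not None for h in motifs.values())
        best_ref, best_id, best_cov = "", 0.0, 0.0
        for ref in references:
            res = align_proteins(locus.protein, ref.sequence,
                                 query_id=locus.locus_id, subject_id=ref.id)
            if (res.identity, res.coverage) > (best_id, best_cov):
                best_ref, best_id, best_cov = ref.id, res.identity, res.coverage
        callable_nat = (
            n_motifs >= 3 and triad != "absent"
            and best_id >= min_identity and best_cov >= min_coverage
        )
        if not callable_nat:
            classification = "non_nat"
        elif len(locus.segments) > 1:
            classification = "frameshifted_pseudogene"
        elif locus.partial_5p or locus.partial_3p:
            classification = "truncated"
        else:
            classification = "intact"
        results.append(AnnotationResult(
            locus_id=locus.locus_id, motif_hits=motifs, triad_status=triad,
            classification=classification, best_reference=best_ref,
            best_identity=best_id, best_coverage=best_cov,
        ))

    # symbol numbering: descending identity, ties by genomic coordinate
    order = sorted(
        (i for i, r in enumerate(results) if r.classification != "non_nat"),
        key=lambda i: (-results[i].best_identity,
                       loci[i].contig, loci[i].segments[0][0]),
    )
    for rank, i in enumerate(order, start=1):
        results[i].assigned_symbol = f"{symbol_prefix}{rank}"
    return results


def loci_to_gff(loci: list[NatLocus],
                results: list[AnnotationResult] | None = None) -> FeatureTable:
    """Export loci as gene features (multi-segment loci as one feature per
    segment, exon-style)."""
    feats = []
    for i, locus in enumerate(loci):
        quals = [("locus_id", locus.locus_id)]
        if results is not None:
            quals += [("classification", results[i].classification),
                      ("symbol", results[i].assigned_symbol)]
        for j, (s, e, frame) in enumerate(locus.segments):
            feats.append(Feature(
                contig=locus.contig, start=s, end=e, strand=locus.strand,
                kind="gene",
                qualifiers=tuple(quals + [("segment", str(j)),
                                          ("frame", str(frame))]),
            ))
    return FeatureTable(feats)
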