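"""Seeded generator of mock microbial replicons with known ground truth.

This module stands in for the genome downloads of a full-scale survey: it
produces replicons of configurable GC content, implants NAT-like open reading
frames (intact, frameshifted or truncated), builds biosynthetic-gene-cluster
style neighborhoods, inserts GC-deviant islands, and evolves protein families
from a seed sequence.  Every operation is deterministic under a 64-bit seed,
and every implant is recorded in a manifest precise enough to score recovery
exactly.

Back-translation uses the bacterial/archaeal codon table (NCBI table 11) with
uniform synonymous codon choice.  Frameshift lesions are single-nucleotide
indels, matching the single-indel pseudogenes the survey methodology targets.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from skbio import TreeNode

from .formats_io import Feature, FeatureTable, Record, SeqRecordSet

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS = tuple(sorted(_TABLE11.stop_codons))

_CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_TABLE11.forward_table.items()):
    _CODONS_BY_AA.setdefault(_aa, ())
    _CODONS_BY_AA[_aa] = _CODONS_BY_AA[_aa] + (_codon,)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

LESIONS = ("none", "frameshift_del1", "frameshift_ins1",
           "truncation_5p", "truncation_3p")


def derive_seed(seed: int, *parts) -> int:
    """Split one global seed into independent per-stage streams by stable
    hashing of (seed, stage name, entity id)."""
    key = ":".join([str(seed)] + [str(p) for p in parts])
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2 ** 63)


def _rng(seed: int, *parts) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *parts))


class Taxon(NamedTuple):
    domain: str
    phylum: str
    klass: str
    genus: str
    species: str
    strain: str

    @property
    def binomial(self) -> str:
        return f"{self.genus} {self.species}"


def mock_taxonomy() -> list[Taxon]:
    ref = importlib.resources.files("natminer.data") / "mock_taxonomy.tsv"
    df = pd.read_csv(str(ref), sep="\t")
    return [
        Taxon(r.domain, r.phylum, getattr(r, "_2"), r.genus, r.species, r.strain)
        for r in df.itertuples(index=False)
    ]


@dataclass(frozen=True)
class ImplantEntry:
    """Ground truth for one implanted NAT-like locus.

    ``segments`` are (start, end, frame) triples in forward contig
    coordinates, ordered 5'->3' on the coding strand.  ``frame`` follows the
    six-frame convention: +1..+3 from the forward strand, -1..-3 from the
    reverse complement.
    """

    locus_id: str
    contig: str
    segments: tuple[tuple[int, int, int], ...]
    strand: str
    lesion: str
    in_cluster: str | None
    seed_protein_id: str
    protein: str  # residues actually encoded by the segments

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _, _ in self.segments),
                max(e for _, e, _ in self.segments))


@dataclass(frozen=True)
class IslandTruth:
    contig: str
    start: int
    end: int
    island_gc: float


@dataclass
class GenomeRecord:
    """A replicon (contig set) with taxon labels and synthetic ground truth.

    Circular replicons are represented linearly with the ``topology`` flag;
    generated features never wrap the origin.
    """

    replicon_id: str
    contigs: SeqRecordSet
    taxon: Taxon
    topology: str = "linear"  # "linear" | "circular"
    replicon_class: str = "chromosome"  # "chromosome" | "plasmid"
    background_gc: float = 0.5
    implants: list[ImplantEntry] = field(default_factory=list)
    islands: list[IslandTruth] = field(default_factory=list)

    def contig_seq(self, contig: str) -> str:
        return self.contigs[contig].sequence

    def total_length(self) -> int:
        return self.contigs.total_residues()

    def _with_contig(self, contig: str, new_seq: str) -> "GenomeRecord":
        records = [
            Record(r.id, r.description, new_seq if r.id == contig else r.sequence)
            for r in self.contigs
        ]
        return replace(self, contigs=SeqRecordSet(records, alphabet="dna"),
                       implants=list(self.implants), islands=list(self.islands))


def generate_genome(
    length: int,
    gc: float,
    n_contigs: int = 1,
    replicon_class: str = "chromosome",
    seed: int = 0,
    replicon_id: str | None = None,
    topology: str = "linear",
    taxon: Taxon | None = None,
) -> GenomeRecord:
    """Generate a replicon of i.i.d. bases with P(G) + P(C) = ``gc``.

    Contig lengths are an even split of ``length`` (remainder on the last
    contig); taxon labels are drawn from the bundled mock taxonomy.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    if length < n_contigs * 1000:
        raise ValueError(
            f"length {length} too short for {n_contigs} contigs of >= 1 kb"
        )
    rng = _rng(seed, "genome", replicon_id or "")
    if replicon_id is None:
        replicon_id = f"synrep{seed}"
    if taxon is None:
        taxa = mock_taxonomy()
        taxon = taxa[int(rng.integers(len(taxa)))]
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base = length // n_contigs
    sizes = [base] * (n_contigs - 1) + [length - base * (n_contigs - 1)]
    records = []
    for i, size in enumerate(sizes):
        draws = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=size, p=probs)
        records.append(Record(
            f"{replicon_id}_c{i + 1}", "synthetic contig",
            draws.tobytes().decode(),
        ))
    return GenomeRecord(
        replicon_id=replicon_id,
        contigs=SeqRecordSet(records, alphabet="dna"),
        taxon=taxon,
        topology=topology,
        replicon_class=replicon_class,
        background_gc=gc,
    )


def back_translate(protein: str, seed: int, entity: str = "orf") -> str:
    """Back-translate a protein with uniform synonymous codon choice
    (codon table 11) and append a random stop codon."""
    rng = _rng(seed, "backtranslate", entity)
    codons = []
    for pos, aa in enumerate(protein):
        if aa not in _CODONS_BY_AA:
            raise ValueError(f"cannot back-translate residue {aa!r} at {pos}")
        options = _CODONS_BY_AA[aa]
        codons.append(options[int(rng.integers(len(options)))])
    codons.append(STOP_CODONS[int(rng.integers(len(STOP_CODONS)))])
    return "".join(codons)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _frame_of(start: int, end: int, strand: str, contig_len: int) -> int:
    """Six-frame index of a coding segment given in forward coordinates."""
    if strand == "+":
        return (start % 3) + 1
    return -(((contig_len - end) % 3) + 1)


def _shift_ground_truth(genome: GenomeRecord, contig: str, edit_pos: int,
                        delta: int) -> None:
    """Shift recorded coordinates after an insertion/deletion at edit_pos."""
    if delta == 0:
        return
    def shift(x: int) -> int:
        return x + delta if x >= edit_pos else x
    genome.implants = [
        replace(e, segments=tuple(
            (shift(s), shift(en), f) for s, en, f in e.segments))
        if e.contig == contig else e
        for e in genome.implants
    ]
    genome.islands = [
        replace(i, start=shift(i.start), end=shift(i.end))
        if i.contig == contig else i
        for i in genome.islands
    ]


def implant_locus(
    genome: GenomeRecord,
    protein: str,
    position: int,
    strand: str = "+",
    lesion: str = "none",
    seed: int = 0,
    contig: str | None = None,
    locus_id: str | None = None,
    in_cluster: str | None = None,
    seed_protein_id: str = "seed",
) -> tuple[GenomeRecord, ImplantEntry]:
    """Implant a back-translated ORF at ``position`` and record ground truth.

    Lesions: ``frameshift_del1`` deletes one nucleotide inside an internal
    codon (the downstream frame shifts by -1 and one residue is lost);
    ``frameshift_ins1`` inserts one nucleotide at an internal codon boundary
    (frame shifts by +1, no residue lost); truncations clip 20-40% of the
    codons at the stated end.  Conservation: the contig length changes only by
    the lesion's +/-1 nt.
    """
    if lesion not in LESIONS:
        raise ValueError(f"unknown lesion {lesion!r}; choose from {LESIONS}")
    if contig is None:
        contig = genome.contigs.records[0].id
    if locus_id is None:
        locus_id = f"implant{len(genome.implants) + 1}"
    seq = genome.contig_seq(contig)
    L = len(protein)
    if L < 10:
        raise ValueError("implanted protein must have >= 10 residues")
    rng = _rng(seed, "lesion", locus_id)

    orf = back_translate(protein, seed, locus_id)  # 3L + 3 nt incl. stop
    window = len(orf)
    # coding-strand segment offsets relative to ORF start, with the residues
    # they encode
    if lesion == "none":
        implant_seq = orf
        rel_segments = [(0, 3 * L)]
        encoded = protein
    elif lesion == "frameshift_del1":
        k = int(rng.integers(max(1, int(0.2 * L)), int(0.8 * L)))
        implant_seq = orf[: 3 * k + 2] + orf[3 * k + 3:]
        rel_segments = [(0, 3 * k), (3 * k + 2, 3 * L - 1)]
        encoded = protein[:k] + protein[k + 1:]
    elif lesion == "frameshift_ins1":
        k = int(rng.integers(max(1, int(0.2 * L)), int(0.8 * L)))
        ins = "ACGT"[int(rng.integers(4))]
        implant_seq = orf[: 3 * k] + ins + orf[3 * k:]
        rel_segments = [(0, 3 * k), (3 * k + 1, 3 * L + 1)]
        encoded = protein
    elif lesion == "truncation_5p":
        t = int(rng.integers(math.ceil(0.2 * L), int(0.4 * L) + 1))
        implant_seq = orf[3 * t:]
        window = len(implant_seq)
        rel_segments = [(0, 3 * (L - t))]
        encoded = protein[t:]
    else:  # truncation_3p
        t = int(rng.integers(math.ceil(0.2 * L), int(0.4 * L) + 1))
        implant_seq = orf[: 3 * (L - t)]  # no stop codon either
        window = len(implant_seq)
        rel_segments = [(0, 3 * (L - t))]
        encoded = protein[: L - t]

    if position < 0 or position + window > len(seq):
        raise ValueError(
            f"implant [{position}, {position + window}) does not fit on "
            f"contig {contig} (length {len(seq)})"
        )
    for prev in genome.implants:
        if prev.contig != contig:
            continue
        s, e = prev.span
        if position < e and position + window > s:
            raise ValueError(
                f"implant at [{position}, {position + window}) overlaps "
                f"existing locus {prev.locus_id}"
            )

    if strand == "-":
        placed = _revcomp(implant_seq)
    else:
        placed = implant_seq
    new_seq = seq[:position] + placed + seq[position + window:]
    delta = len(placed) - window

    out = genome._with_contig(contig, new_seq)
    _shift_ground_truth(out, contig, position + window, delta)
    n = len(new_seq)
    total = len(placed)
    segments = []
    for a, b in rel_segments:
        if strand == "+":
            fs, fe = position + a, position + b
        else:
            fs, fe = position + total - b, position + total - a
        segments.append((fs, fe, _frame_of(fs, fe, strand, n)))
    entry = ImplantEntry(
        locus_id=locus_id, contig=contig, segments=tuple(segments),
        strand=strand, lesion=lesion, in_cluster=in_cluster,
        seed_protein_id=seed_protein_id, protein=encoded,
    )
    out.implants.append(entry)
    return out, entry


def random_protein(length: int, seed: int, entity: str = "prot",
                   start_met: bool = True) -> str:
    rng = _rng(seed, "protein", entity)
    aas = rng.choice(list(AMINO_ACIDS), size=length)
    prot = "".join(aas)
    if start_met:
        prot = "M" + prot[1:]
    return prot


def make_nat_protein(seed: int, length: int = 280,
                     entity: str = "natseed") -> str:
    """A random protein carrying the four semi-conserved NAT motifs
    (VPFENL, RGGYC, THRL, VDV) in order, with the Cys-His-Asp triad."""
    if length < 200:
        raise ValueError("NAT-like seed proteins need length >= 200")
    prot = list(random_protein(length, seed, entity))
    for motif, frac in (("VPFENL", 0.22), ("RGGYC", 0.37),
                        ("THRL", 0.47), ("VDV", 0.55)):
        pos = int(frac * length)
        prot[pos:pos + len(motif)] = list(motif)
    return "".join(prot)


def implant_cluster(
    genome: GenomeRecord,
    n_flank_genes: int,
    cluster_type: str,
    nat_position: int,
    seed: int = 0,
    contig: str | None = None,
    start: int | None = None,
    nat_protein: str | None = None,
    cluster_id: str | None = None,
    nat_lesion: str = "none",
    nat_strand: str = "+",
) -> tuple[GenomeRecord, FeatureTable]:
    """Implant a BGC-like neighborhood: ``n_flank_genes`` random ORFs plus one
    NAT-like gene at ordinal ``nat_position`` (1-based within the cluster).

    Returns the updated genome and a feature table holding the gene/CDS
    features (with their translations as qualifiers) and a ``protocluster``
    feature spanning the whole neighborhood with qualifier
    ``category=<cluster_type>``.  Genes are non-overlapping with >= 50 bp
    intergenic gaps.
    """
    n_genes = n_flank_genes + 1
    if not 1 <= nat_position <= n_genes:
        raise ValueError(
            f"nat_position must be in 1..{n_genes}, got {nat_position}"
        )
    if contig is None:
        contig = genome.contigs.records[0].id
    if cluster_id is None:
        cluster_id = f"cluster{len([f for f in genome.implants if f.in_cluster]) + 1}"
    rng = _rng(seed, "cluster", cluster_id)
    if nat_protein is None:
        nat_protein = make_nat_protein(derive_seed(seed, "natprot", cluster_id))

    gene_lengths = []
    for i in range(n_genes):
        if i == nat_position - 1:
            gene_lengths.append(3 * len(nat_protein) + 3)
        else:
            # flanking ORFs 0.3-3 kb
            n_codons = int(rng.integers(100, 1000))
            gene_lengths.append(3 * n_codons + 3)
    gaps = [int(rng.integers(150, 300)) for _ in range(n_genes)]
    total = sum(gene_lengths) + sum(gaps)

    if start is None:
        start = _find_free_interval(genome, contig, total, rng)
    seq_len = len(genome.contig_seq(contig))
    if start < 0 or start + total > seq_len:
        raise ValueError(
            f"insufficient space for cluster of {total} bp at {start} on "
            f"contig {contig}"
        )

    out = genome
    features = []
    pos = start
    nat_entry = None
    for i in range(n_genes):
        pos += gaps[i]
        glen = gene_lengths[i]
        if i == nat_position - 1:
            out, nat_entry = implant_locus(
                out, nat_protein, pos, strand=nat_strand, lesion=nat_lesion,
                seed=derive_seed(seed, "natgene", cluster_id),
                contig=contig, locus_id=f"{cluster_id}_nat",
                in_cluster=cluster_id, seed_protein_id="nat_seed",
            )
            gstart, gend = nat_entry.span
            prot = nat_protein
            strand = nat_strand
            name = f"{cluster_id}_nat"
        else:
            prot = random_protein(glen // 3 - 1,
                                  derive_seed(seed, "flank", cluster_id, i))
            out, entry = implant_locus(
                out, prot, pos, strand="+", lesion="none",
                seed=derive_seed(seed, "flankgene", cluster_id, i),
                contig=contig, locus_id=f"{cluster_id}_g{i + 1}",
                in_cluster=cluster_id, seed_protein_id="flank",
            )
            gstart, gend = entry.span
            gend += 3  # include the stop codon in the gene feature
            strand = "+"
            name = f"{cluster_id}_g{i + 1}"
        features.append(Feature(
            contig=contig, start=gstart, end=gend, strand=strand, kind="CDS",
            qualifiers=(("locus_tag", name), ("translation", prot)),
        ))
        pos += glen + (
            -1 if i == nat_position - 1 and nat_lesion == "frameshift_del1"
            else 1 if i == nat_position - 1 and nat_lesion == "frameshift_ins1"
            else 0)

    # the protocluster feature spans the whole laid-out neighborhood (from
    # the requested start to the end of the last gene), covering the union
    # of its genes; overlapping neighborhoods yield overlapping protoclusters
    features.append(Feature(
        contig=contig, start=start, end=max(f.end for f in features),
        strand="+", kind="protocluster",
        qualifiers=(("cluster_id", cluster_id), ("category", cluster_type)),
    ))
    return out, FeatureTable(features)


def _find_free_interval(genome: GenomeRecord, contig: str, size: int,
                        rng: np.random.Generator) -> int:
    seq_len = len(genome.contig_seq(contig))
    occupied = sorted(
        e.span for e in genome.implants if e.contig == contig
    )
    for _ in range(200):
        cand = int(rng.integers(0, max(1, seq_len - size)))
        if all(not (cand < e and cand + size > s) for s, e in occupied):
            return cand
    raise ValueError(f"no free interval of {size} bp found on {contig}")


def implant_gc_island(
    genome: GenomeRecord,
    start: int,
    length: int,
    island_gc: float,
    seed: int = 0,
    contig: str | None = None,
) -> GenomeRecord:
    """Resample a contiguous interval i.i.d. at ``island_gc`` and record the
    island in the genome's ground-truth manifest."""
    if not 0.0 < island_gc < 1.0:
        raise ValueError(f"island_gc must be in (0, 1), got {island_gc}")
    if contig is None:
        contig = genome.contigs.records[0].id
    seq = genome.contig_seq(contig)
    if start < 0 or start + length > len(seq):
        raise ValueError(
            f"island [{start}, {start + length}) out of bounds for contig "
            f"{contig} (length {len(seq)})"
        )
    for isl in genome.islands:
        if isl.contig == contig and start < isl.end and start + length > isl.start:
            raise ValueError("islands must not overlap")
    rng = _rng(seed, "island", contig, start)
    probs = np.array([(1 - island_gc) / 2, island_gc / 2, island_gc / 2,
                      (1 - island_gc) / 2])
    draws = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)
    new_seq = seq[:start] + draws.tobytes().decode() + seq[start + length:]
    out = genome._with_contig(contig, new_seq)
    out.islands.append(IslandTruth(contig, start, start + length, island_gc))
    return out


@dataclass
class FamilyConfig:
    """Configuration for evolving a protein family from a seed sequence."""

    seed_protein: str
    n_taxa: int
    substitution_rate: float  # expected substitutions per site per unit branch
    guide_tree: TreeNode | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.substitution_rate < 0:
            raise ValueError("substitution_rate must be >= 0")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")


def evolve_family(config: FamilyConfig) -> SeqRecordSet:
    """Evolve ``n_taxa`` sequences from the seed protein.

    Each site substitutes along a branch of length ``b`` with probability
    ``1 - exp(-rate * b)``, uniformly among the other 19 residues.  Without a
    guide tree a star tree of unit branches is used.  Deterministic under
    ``rng_seed``.
    """
    rng = _rng(config.rng_seed, "family")
    aas = np.array(list(AMINO_ACIDS))
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}

    def mutate(seq: np.ndarray, branch_length: float) -> np.ndarray:
        p = 1.0 - math.exp(-config.substitution_rate * branch_length)
        mask = rng.random(len(seq)) < p
        if mask.any():
            seq = seq.copy()
            # uniform over the 19 non-identical residues
            offsets = rng.integers(1, 20, size=int(mask.sum()))
            current = np.array([aa_index[a] for a in seq[mask]])
            seq[mask] = aas[(current + offsets) % 20]
        return seq

    root = np.array(list(config.seed_protein))
    records: list[Record] = []
    if config.guide_tree is None:
        for i in range(config.n_taxa):
            records.append(Record(
                f"taxon{i + 1}", "evolved from seed (star tree)",
                "".join(mutate(root, 1.0)),
            ))
    else:
        tips = list(config.guide_tree.tips())
        if len(tips) != config.n_taxa:
            raise ValueError(
                f"guide tree has {len(tips)} leaves, expected {config.n_taxa}"
            )

        def descend(node: TreeNode, seq: np.ndarray) -> None:
            for child in node.children:
                branch = child.length if child.length is not None else 1.0
                child_seq = mutate(seq, branch)
                if child.is_tip():
                    records.append(Record(
                        str(child.name), "evolved from seed (guide tree)",
                        "".join(child_seq),
                    ))
                else:
                    descend(child, child_seq)

        descend(config.guide_tree, root)
    return SeqRecordSet(records, alphabet="protein")


def write_ground_truth(genome: GenomeRecord, outdir) -> None:
    """Export a synthetic genome as FASTA + GFF3 + manifest TSV."""
    from pathlib import Path

    from .formats_io import write_fasta, write_feature_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genome.contigs, outdir / f"{genome.replicon_id}.fna")
    feats = []
    for e in genome.implants:
        for i, (s, en, frame) in enumerate(e.segments):
            feats.append(Feature(
                contig=e.contig, start=s, end=en, strand=e.strand, kind="gene",
                qualifiers=(("locus_id", e.locus_id), ("segment", str(i)),
                            ("frame", str(frame)), ("lesion", e.lesion)),
            ))
    for isl in genome.islands:
        feats.append(Feature(
            contig=isl.contig, start=isl.start, end=isl.end, strand="+",
            kind="island", qualifiers=(("island_gc", f"{isl.island_gc:.3f}"),),
        ))
    write_feature_table(FeatureTable(feats), outdir / f"{genome.replicon_id}.gff3",
                        dialect="gff3")
    rows = [{
        "locus_id": e.locus_id, "contig": e.contig,
        "segments": ";".join(f"{s}-{en}/{f}" for s, en, f in e.segments),
        "strand": e.strand, "lesion": e.lesion,
        "in_cluster": e.in_cluster or "", "seed_protein_id": e.seed_protein_id,
    } for e in genome.implants]
    pd.DataFrame(rows, columns=["locus_id", "contig", "segments", "strand",
                                "lesion", "in_cluster", "seed_protein_id"]
                 ).to_csv(outdir / f"{genome.replicon_id}.manifest.tsv",
                          sep="\t", index=False)
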