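"""Readers and writers for the external representations the pipeline touches.

All internal coordinates are 0-based half-open; conversion to the 1-based
inclusive convention of GFF3/GenBank happens only at file boundaries, so that
``read(write(x)) == x`` for every supported format.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord as BioSeqRecord
from skbio import TreeNode

DNA_ALPHABET = set("ACGTNRYSWKMBDHV")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

FEATURE_KINDS = ("gene", "CDS", "protocluster", "island", "other")


@dataclass(frozen=True)
class Record:
    """A single sequence record: identifier, free-text description, residues."""

    id: str
    description: str
    sequence: str


@dataclass
class SeqRecordSet:
    """An ordered collection of sequence records over one alphabet.

    Invariants: identifiers are unique; every sequence draws from a single
    alphabet (DNA with IUPAC ambiguity, or protein with X and ``*``).
    """

    records: list[Record] = field(default_factory=list)
    alphabet: str = "auto"  # "dna" | "protein" | "auto"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence identifier: {rec.id!r}")
            seen.add(rec.id)
        if self.alphabet == "auto":
            self.alphabet = _infer_alphabet(self.records)
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        for rec in self.records:
            for pos, ch in enumerate(rec.sequence):
                if ch not in allowed:
                    raise ValueError(
                        f"illegal {self.alphabet} residue {ch!r} at position "
                        f"{pos} of record {rec.id!r}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key: str) -> Record:
        for rec in self.records:
            if rec.id == key:
                return rec
        raise KeyError(key)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def total_residues(self) -> int:
        return sum(len(r.sequence) for r in self.records)


def _infer_alphabet(records: list[Record]) -> str:
    chars: set[str] = set()
    for rec in records:
        chars.update(rec.sequence)
    if not chars:
        return "dna"
    if chars <= DNA_ALPHABET and not (chars - set("ACGTN")):
        return "dna"
    if chars <= DNA_ALPHABET:
        return "dna"
    return "protein"


@dataclass(frozen=True)
class Feature:
    """A genomic feature in internal (0-based, half-open) coordinates."""

    contig: str
    start: int
    end: int
    strand: str  # "+" or "-"
    kind: str  # one of FEATURE_KINDS
    qualifiers: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"feature on {self.contig}: start ({self.start}) must be < "
                f"end ({self.end})"
            )
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind: {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def qualifier(self, key: str, default: str | None = None) -> str | None:
        for k, v in self.qualifiers:
            if k == key:
                return v
        return default


@dataclass
class FeatureTable:
    """Features sorted by (contig, start); coordinates 0-based half-open."""

    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(
            self.features, key=lambda f: (f.contig, f.start, f.end)
        )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def on_contig(self, contig: str) -> list[Feature]:
        return [f for f in self.features if f.contig == contig]

    def of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


@dataclass
class EdgeTable:
    """An undirected, simple graph as an edge list with node attributes.

    Edge endpoints are stored with ``node_a < node_b`` lexicographically;
    scores are finite and non-negative (-log10 E-value units).
    """

    edges: list[tuple[str, str, float]] = field(default_factory=list)
    node_attrs: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = []
        seen = set()
        for a, b, s in self.edges:
            if s < 0 or s != s or s in (float("inf"), float("-inf")):
                raise ValueError(f"edge score must be finite and >= 0: {s}")
            a, b = (a, b) if a < b else (b, a)
            if (a, b) in seen:
                raise ValueError(f"duplicate edge: {(a, b)}")
            seen.add((a, b))
            canon.append((a, b, float(s)))
        self.edges = sorted(canon)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "auto") -> SeqRecordSet:
    """Read a FASTA file into a :class:`SeqRecordSet`.

    Sequence case is normalized to upper and whitespace within sequence lines
    is stripped.  An empty file yields an empty set with a warning; duplicate
    identifiers and illegal residues raise ``ValueError``.
    """
    path = Path(path)
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(
                Record(rec.id, desc, str(rec.seq).upper().replace(" ", ""))
            )
    if not records:
        warnings.warn(f"empty FASTA file: {path}", stacklevel=2)
    return SeqRecordSet(records, alphabet=alphabet)


def write_fasta(recset: SeqRecordSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for rec in recset:
            header = f">{rec.id} {rec.description}".rstrip()
            out.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Feature tables (GFF3 / GenBank feature-table subset / TSV)
# ---------------------------------------------------------------------------

_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def _qualifiers_to_attr(qualifiers: tuple[tuple[str, str], ...]) -> str:
    if not qualifiers:
        return "."
    return ";".join(f"{k}={v}" for k, v in qualifiers)


def _attr_to_qualifiers(attr: str) -> tuple[tuple[str, str], ...]:
    if attr in (".", ""):
        return ()
    out = []
    for item in attr.split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out.append((key, value))
    return tuple(out)


def read_feature_table(
    path: str | Path, dialect: str, sequences: bool = False
) -> FeatureTable | tuple[FeatureTable, SeqRecordSet]:
    """Read a feature table, converting external 1-based inclusive coordinates
    to the internal 0-based half-open convention.

    ``dialect`` is one of ``gff3``, ``genbank-ft`` or ``tsv``.  For
    ``genbank-ft``, pass ``sequences=True`` to also return the ORIGIN
    sequences as a :class:`SeqRecordSet`.
    """
    path = Path(path)
    if dialect == "gff3":
        feats = _read_gff3(path)
    elif dialect == "genbank-ft":
        feats, seqs = _read_genbank(path)
        if sequences:
            return FeatureTable(feats), seqs
    elif dialect == "tsv":
        feats = _read_feature_tsv(path)
    else:
        raise ValueError(f"unknown feature-table dialect: {dialect!r}")
    return FeatureTable(feats)


def _external_to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    start, end = start_1based - 1, end_inclusive
    if start >= end:
        raise ValueError(
            f"invalid coordinates after conversion: start {start_1based}, "
            f"end {end_inclusive}"
        )
    return start, end


def _read_gff3(path: Path) -> list[Feature]:
    feats = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attr = fields
            istart, iend = _external_to_internal(int(start), int(end))
            kind = ftype if ftype in FEATURE_KINDS else "other"
            quals = _attr_to_qualifiers(attr)
            if kind == "other" and ftype not in FEATURE_KINDS:
                if not any(k == "orig_type" for k, _ in quals) and ftype != "other":
                    quals = quals + (("orig_type", ftype),)
            feats.append(Feature(
                contig=seqid, start=istart, end=iend,
                strand=strand if strand in "+-" else "+",
                kind=kind, qualifiers=quals,
            ))
    return feats


def _read_feature_tsv(path: Path) -> list[Feature]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"contig", "start", "end", "strand", "kind", "qualifiers"}
    if not required <= set(df.columns):
        raise ValueError(f"feature TSV must have columns {sorted(required)}")
    feats = []
    for row in df.itertuples(index=False):
        feats.append(Feature(
            contig=row.contig, start=int(row.start), end=int(row.end),
            strand=row.strand, kind=row.kind,
            qualifiers=_attr_to_qualifiers(
                "" if pd.isna(row.qualifiers) else row.qualifiers),
        ))
    return feats


def _read_genbank(path: Path) -> tuple[list[Feature], SeqRecordSet]:
    feats = []
    seqs = []
    for rec in SeqIO.parse(str(path), "genbank"):
        seq = str(rec.seq).upper()
        if seq and set(seq) <= DNA_ALPHABET:
            seqs.append(Record(rec.id, rec.description, seq))
        for feat in rec.features:
            if feat.type == "source":
                continue
            kind = feat.type if feat.type in FEATURE_KINDS else "other"
            quals = []
            if kind == "other" and feat.type != "other":
                quals.append(("orig_type", feat.type))
            for key, values in feat.qualifiers.items():
                for v in values:
                    quals.append((key, str(v)))
            # Biopython locations are already 0-based half-open.
            feats.append(Feature(
                contig=rec.id,
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand="-" if feat.location.strand == -1 else "+",
                kind=kind,
                qualifiers=tuple(quals),
            ))
    return feats, SeqRecordSet(seqs, alphabet="dna")


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    dialect: str,
    sequences: SeqRecordSet | None = None,
    source: str = "natminer",
) -> None:
    """Write a feature table; coordinates become 1-based inclusive on disk
    (GFF3/GenBank) so that re-import restores the original table."""
    path = Path(path)
    if dialect == "gff3":
        with open(path, "w") as out:
            out.write("##gff-version 3\n")
            for f in table:
                ftype = f.qualifier("orig_type") or f.kind
                quals = tuple(
                    (k, v) for k, v in f.qualifiers if k != "orig_type"
                )
                out.write("\t".join([
                    f.contig, source, ftype, str(f.start + 1), str(f.end),
                    ".", f.strand, ".", _qualifiers_to_attr(quals),
                ]) + "\n")
    elif dialect == "tsv":
        rows = [{
            "contig": f.contig, "start": f.start, "end": f.end,
            "strand": f.strand, "kind": f.kind,
            "qualifiers": _qualifiers_to_attr(f.qualifiers),
        } for f in table]
        pd.DataFrame(
            rows, columns=["contig", "start", "end", "strand", "kind",
                           "qualifiers"]
        ).to_csv(path, sep="\t", index=False)
    elif dialect == "genbank-ft":
        _write_genbank(table, path, sequences)
    else:
        raise ValueError(f"unknown feature-table dialect: {dialect!r}")


def _write_genbank(
    table: FeatureTable, path: Path, sequences: SeqRecordSet | None
) -> None:
    contigs = sorted({f.contig for f in table})
    if sequences is not None:
        contigs = sorted(set(contigs) | set(sequences.ids()))
    bio_records = []
    for contig in contigs:
        feats = table.on_contig(contig)
        if sequences is not None and contig in set(sequences.ids()):
            seq = sequences[contig].sequence
        else:
            # sequence-less tables are padded so coordinates stay valid
            seq = "N" * max((f.end for f in feats), default=1)
        rec = BioSeqRecord(Seq(seq), id=contig, name=contig[:16],
                           description="")
        rec.annotations["molecule_type"] = "DNA"
        for f in feats:
            ftype = f.qualifier("orig_type") or f.kind
            quals: dict[str, list[str]] = {}
            for k, v in f.qualifiers:
                if k == "orig_type":
                    continue
                quals.setdefault(k, []).append(v)
            rec.features.append(SeqFeature(
                SimpleLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1),
                type=ftype, qualifiers=quals,
            ))
        bio_records.append(rec)
    with open(path, "w") as out:
        SeqIO.write(bio_records, out, "genbank")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize a tree to Newick; bootstrap supports are emitted as
    internal-node labels."""
    tree = tree.copy()
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise ValueError("branch lengths must be >= 0")
    with open(path, "w") as out:
        tree.write(out)


def read_newick(path: str | Path) -> TreeNode:
    with open(path) as handle:
        return TreeNode.read(handle)


def newick_string(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# Edge tables (Cytoscape-importable TSV)
# ---------------------------------------------------------------------------

def write_edge_table(graph: EdgeTable, path: str | Path) -> None:
    """Write edges as TSV plus a sidecar ``<path>.nodes.tsv`` with node
    attributes; row order is deterministic."""
    path = Path(path)
    pd.DataFrame(
        graph.edges, columns=["node_a", "node_b", "score"]
    ).to_csv(path, sep="\t", index=False)
    node_rows = [
        {"node": n, "taxon": t, "cluster_type": c}
        for n, (t, c) in sorted(graph.node_attrs.items())
    ]
    pd.DataFrame(
        node_rows, columns=["node", "taxon", "cluster_type"]
    ).to_csv(path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t", index=False)


def read_edge_table(path: str | Path) -> EdgeTable:
    path = Path(path)
    edges_df = pd.read_csv(path, sep="\t")
    edges = [
        (str(r.node_a), str(r.node_b), float(r.score))
        for r in edges_df.itertuples(index=False)
    ]
    node_path = path.with_suffix(path.suffix + ".nodes.tsv")
    attrs: dict[str, tuple[str, str]] = {}
    if node_path.exists():
        nodes_df = pd.read_csv(node_path, sep="\t", dtype=str).fillna("")
        for r in nodes_df.itertuples(index=False):
            attrs[str(r.node)] = (str(r.taxon), str(r.cluster_type))
    return EdgeTable(edges, attrs)
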