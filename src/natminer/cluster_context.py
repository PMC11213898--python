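"""Biosynthetic-gene-cluster context bookkeeping.

Cluster predictions themselves (antiSMASH-style protoclusters) are consumed
as feature tables; this module implements the survey's localization rules:
fixed-width flank extraction around a NAT locus (500 kb per side for
prokaryotes, 1 Mb for eukaryotes) with removal of window-edge-crossing ORFs,
overlap-based protocluster membership (a locus in the shared region of
several protoclusters belongs to all of them), and cross-cluster synteny by
bidirectional best hits with a strict 100%-conservation grouping rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx

from .formats_io import Feature, FeatureTable
from .homology_search import align_proteins
from .nat_annotate import NatLocus
from .synthetic_data import GenomeRecord

PROKARYOTE_FLANK = 500_000
EUKARYOTE_FLANK = 1_000_000


@dataclass(frozen=True)
class ContextWindow:
    contig: str
    span: tuple[int, int]
    domain_kind: str  # "prokaryote" | "eukaryote"
    trimmed_features: FeatureTable


@dataclass(frozen=True)
class Protocluster:
    """A typed genomic interval with member genes (each carrying a
    ``translation`` qualifier)."""

    cluster_id: str
    contig: str
    span: tuple[int, int]
    cluster_type: str
    genes: tuple[Feature, ...] = ()

    def gene_proteins(self) -> list[tuple[str, str]]:
        out = []
        for g in self.genes:
            prot = g.qualifier("translation")
            if prot is None:
                raise ValueError(
                    f"gene at {g.contig}:{g.start}-{g.end} in cluster "
                    f"{self.cluster_id} has no translation qualifier"
                )
            out.append((g.qualifier("locus_tag") or f"{g.start}", prot))
        return out


@dataclass
class SyntenyMap:
    pairs: list[tuple[str, str, list[tuple[str, str, float]]]] = field(
        default_factory=list)
    conservation_groups: dict[str, str] = field(default_factory=dict)
    # cluster_id -> representative (lexicographically smallest of its group)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cid, rep in self.conservation_groups.items():
            out.setdefault(rep, []).append(cid)
        return {rep: sorted(members) for rep, members in out.items()}


def protoclusters_from_features(table: FeatureTable) -> list[Protocluster]:
    """Build Protocluster objects from a feature table containing
    ``protocluster`` features and their member CDS/gene features."""
    clusters = []
    for i, pc in enumerate(table.of_kind("protocluster")):
        cid = pc.qualifier("cluster_id") or f"protocluster{i + 1}"
        genes = tuple(
            f for f in table.on_contig(pc.contig)
            if f.kind in ("CDS", "gene")
            and f.start >= pc.start and f.end <= pc.end
        )
        clusters.append(Protocluster(
            cluster_id=cid, contig=pc.contig, span=(pc.start, pc.end),
            cluster_type=pc.qualifier("category") or "unknown", genes=genes,
        ))
    return clusters


def extract_window(
    locus: NatLocus,
    genome: GenomeRecord,
    features: FeatureTable,
    domain_kind: str = "prokaryote",
    flank: int | None = None,
) -> ContextWindow:
    """Extract the genomic neighborhood of a locus.

    The window spans ``flank`` bases either side (500 kb for prokaryotes,
    1 Mb for eukaryotes), clipped at contig ends.  Features crossing a window
    edge are removed entirely, mirroring the partial-ORF trimming required
    before cluster prediction.
    """
    if flank is None:
        if domain_kind == "prokaryote":
            flank = PROKARYOTE_FLANK
        elif domain_kind == "eukaryote":
            flank = EUKARYOTE_FLANK
        else:
            raise ValueError(f"unknown domain_kind: {domain_kind!r}")
    contig_len = len(genome.contig_seq(locus.contig))
    locus_start = min(s for s, _, _ in locus.segments)
    locus_end = max(e for _, e, _ in locus.segments)
    span = (max(0, locus_start - flank), min(contig_len, locus_end + flank))
    kept = [
        f for f in features.on_contig(locus.contig)
        if f.start >= span[0] and f.end <= span[1]
    ]
    covers_locus = any(
        f.start <= locus_start and f.end >= locus_end for f in kept
        if f.kind in ("gene", "CDS")
    )
    if not covers_locus:
        warnings.warn(
            f"locus {locus.locus_id} not covered by any gene feature; "
            "window produced anyway", stacklevel=2,
        )
    return ContextWindow(
        contig=locus.contig, span=span, domain_kind=domain_kind,
        trimmed_features=FeatureTable(kept),
    )


def assign_membership(
    locus: NatLocus, protoclusters: list[Protocluster]
) -> list[str]:
    """Every protocluster whose span overlaps the locus span by >= 1 base."""
    locus_start = min(s for s, _, _ in locus.segments)
    locus_end = max(e for _, e, _ in locus.segments)
    out = []
    for pc in protoclusters:
        if pc.contig != locus.contig:
            continue
        if pc.span[0] < locus_end and pc.span[1] > locus_start:
            out.append(pc.cluster_id)
    return sorted(out)


def _bbh_links(a: Protocluster, b: Protocluster) -> list[tuple[str, str, float]]:
    """Bidirectional best hits between the gene sets of two clusters;
    identities computed over the aligned span."""
    genes_a = a.gene_proteins()
    genes_b = b.gene_proteins()
    scores: dict[tuple[int, int], tuple[float, float]] = {}
    for i, (_, pa) in enumerate(genes_a):
        for j, (_, pb) in enumerate(genes_b):
            res = align_proteins(pa, pb)
            scores[(i, j)] = (res.score, res.identity)
    links = []
    for i, (name_a, _) in enumerate(genes_a):
        best_j = max(range(len(genes_b)), key=lambda j: scores[(i, j)][0])
        best_i = max(range(len(genes_a)), key=lambda i2: scores[(i2, best_j)][0])
        if best_i == i:
            links.append((name_a, genes_b[best_j][0],
                          scores[(i, best_j)][1], i, best_j))
    return [(na, nb, ident) for na, nb, ident, _, _ in links], [
        (i, j) for _, _, _, i, j in links]


def _fully_conserved(a: Protocluster, b: Protocluster,
                     index_pairs: list[tuple[int, int]]) -> bool:
    """100% conservation: a bijection of BBH links covering all genes of both
    clusters, in identical order or full reversal, all identities 100%."""
    if len(a.genes) != len(b.genes):
        return False
    if len(index_pairs) != len(a.genes):
        return False
    if sorted(i for i, _ in index_pairs) != list(range(len(a.genes))):
        return False
    if sorted(j for _, j in index_pairs) != list(range(len(b.genes))):
        return False
    ordered = [j for _, j in sorted(index_pairs)]
    return ordered == sorted(ordered) or ordered == sorted(ordered)[::-1]


def map_synteny(clusters: list[Protocluster]) -> SyntenyMap:
    """Pairwise bidirectional-best-hit mapping between clusters plus
    transitive grouping of 100%-conserved syntenic units.

    Each conservation group is represented by its lexicographically smallest
    cluster id, mirroring the redundancy-collapsing rule used when displaying
    syntenic clusters.
    """
    if len(clusters) < 2:
        raise ValueError("map_synteny needs at least two clusters")
    ids = [c.cluster_id for c in clusters]
    if len(set(ids)) != len(ids):
        raise ValueError("cluster ids must be unique")
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    out = SyntenyMap()
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            a, b = clusters[i], clusters[j]
            links, index_pairs = _bbh_links(a, b)
            out.pairs.append((a.cluster_id, b.cluster_id, links))
            conserved = (
                _fully_conserved(a, b, index_pairs)
                and all(abs(ident - 100.0) < 1e-9 for _, _, ident in links)
            )
            if conserved:
                graph.add_edge(a.cluster_id, b.cluster_id)
    for component in nx.connected_components(graph):
        rep = min(component)
        for cid in component:
            out.conservation_groups[cid] = rep
    return out
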