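"""Sequence-similarity networks and neighbor-joining phylogenies.

The multiple alignment behind the distance matrix is a center-star
construction: the center sequence maximizes its summed pairwise alignment
score, every other sequence is aligned globally to the center, and columns
are merged on center coordinates (insertions relative to the center are not
columns of the merged alignment).  Distances are p-distances — the fraction
of differing residues among shared non-gap columns — matching the protein
neighbor-joining default of the common tree packages.

The SSN "alignment score" of an edge is -log10 of the Karlin-Altschul
E-value of the pairwise local alignment, so a threshold of 29 keeps pairs
with E <= 1e-29.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .formats_io import EdgeTable, SeqRecordSet
from .homology_search import align_proteins, evalue, neg_log10_evalue

import biotite.sequence as bseq
import biotite.sequence.align as balign

from .homology_search import BLOSUM62, DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN


def center_star_msa(proteins: SeqRecordSet) -> tuple[list[str], list[str]]:
    """Center-star multiple alignment projected onto center columns.

    Returns (labels, aligned strings); every aligned string has the length
    of the center sequence, with ``-`` where a sequence has no residue
    aligned to that center position.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two sequences")
    for rec in proteins:
        if len(rec.sequence) == 0:
            raise ValueError(f"zero-length sequence: {rec.id}")
    records = list(proteins)
    n = len(records)
    # choose the center: maximal summed pairwise global score
    scores = np.zeros((n, n))
    pair_alns: dict[tuple[int, int], object] = {}
    seqs = [bseq.ProteinSequence(r.sequence) for r in records]
    for i in range(n):
        for j in range(i + 1, n):
            aln = balign.align_optimal(
                seqs[i], seqs[j], BLOSUM62,
                gap_penalty=(-DEFAULT_GAP_OPEN, -DEFAULT_GAP_EXTEND),
                local=False, terminal_penalty=False, max_number=1)[0]
            scores[i, j] = scores[j, i] = aln.score
            pair_alns[(i, j)] = aln
    center = int(np.argmax(scores.sum(axis=1)))
    center_len = len(records[center].sequence)

    aligned = []
    for i in range(n):
        if i == center:
            aligned.append(records[center].sequence)
            continue
        key = (min(i, center), max(i, center))
        aln = pair_alns[key]
        trace = aln.trace
        col_center = 0 if center == key[0] else 1
        col_other = 1 - col_center
        row = ["-"] * center_len
        other_seq = records[i].sequence
        for c_idx, o_idx in zip(trace[:, col_center], trace[:, col_other]):
            if c_idx != -1 and o_idx != -1:
                row[int(c_idx)] = other_seq[int(o_idx)]
        aligned.append("".join(row))
    return [r.id for r in records], aligned


def p_distances(labels: list[str], aligned: list[str]) -> DistanceMatrix:
    """Pairwise p-distances over shared non-gap columns of an alignment."""
    arr = np.array([list(s) for s in aligned])
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = (arr[i] != "-") & (arr[j] != "-")
            total = int(shared.sum())
            if total == 0:
                dist = 1.0
            else:
                dist = float((arr[i][shared] != arr[j][shared]).sum()) / total
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids=labels)


def distance_matrix(proteins: SeqRecordSet) -> DistanceMatrix:
    """p-distance matrix from the center-star alignment of a protein set."""
    labels, aligned = center_star_msa(proteins)
    return p_distances(labels, aligned)


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (Saitou-Nei agglomeration, standard
    Q-criterion); negative branch-length estimates are clamped to zero.

    A two-taxon matrix returns the single-edge tree with the distance split
    evenly."""
    if len(d.ids) == 2:
        a, b = d.ids
        half = d[a, b] / 2
        tree = TreeNode(children=[TreeNode(name=a, length=half),
                                  TreeNode(name=b, length=half)])
        return tree
    arr = np.asarray(d.data)
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    return nj(d, neg_as_zero=True)


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalized as
    the smaller (then lexicographically first) leaf set."""
    leaves = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), sorted(s)))
        splits.add(canon)
    return splits


def bootstrap(
    proteins: SeqRecordSet,
    n_reps: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """Neighbor-joining tree with bootstrap supports.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of each internal edge of the original tree is the percentage of
    replicates whose tree contains the same bipartition.  Deterministic
    under ``seed``."""
    if len(proteins) < 4:
        raise ValueError("bootstrap needs at least four sequences")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels, aligned = center_star_msa(proteins)
    tree = nj_tree(p_distances(labels, aligned))
    original = tree_splits(tree)
    counts = {split: 0 for split in original}
    arr = np.array([list(s) for s in aligned])
    n_cols = arr.shape[1]
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = ["".join(row) for row in arr[:, cols]]
        rep_tree = nj_tree(p_distances(labels, resampled))
        rep_splits = tree_splits(rep_tree)
        for split in original:
            if split in rep_splits:
                counts[split] += 1
    leaves = frozenset(labels)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = min(side, leaves - side, key=lambda s: (len(s), sorted(s)))
        if canon in counts:
            node.name = str(round(100.0 * counts[canon] / n_reps))
    return tree


def build_ssn(
    proteins: SeqRecordSet,
    threshold: float = 29.0,
    node_attrs: dict[str, tuple[str, str]] | None = None,
) -> "SSNGraph":
    """Sequence similarity network: an edge connects two proteins when the
    -log10 E-value of their local alignment reaches ``threshold``."""
    import networkx as nx

    if len(proteins) < 2:
        raise ValueError("need at least two sequences")
    records = list(proteins)
    db_residues = proteins.total_residues()
    graph = nx.Graph()
    for rec in records:
        graph.add_node(rec.id)
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            res = align_proteins(
                records[i].sequence, records[j].sequence,
                query_id=records[i].id, subject_id=records[j].id,
                db_residues=db_residues,
            )
            score = neg_log10_evalue(res.evalue)
            if score >= threshold:
                graph.add_edge(records[i].id, records[j].id,
                               score=min(score, 1e6))
    for comp_idx, comp in enumerate(sorted(
            nx.connected_components(graph), key=lambda c: sorted(c)[0])):
        for node in comp:
            graph.nodes[node]["component"] = comp_idx
    if node_attrs:
        for node, (taxon, ctype) in node_attrs.items():
            if node in graph:
                graph.nodes[node]["taxon"] = taxon
                graph.nodes[node]["cluster_type"] = ctype
    return SSNGraph(graph=graph, threshold=threshold)


class SSNGraph:
    """Thresholded similarity graph with Cytoscape-importable export."""

    def __init__(self, graph, threshold: float):
        self.graph = graph
        self.threshold = threshold

    @property
    def n_components(self) -> int:
        import networkx as nx
        return nx.number_connected_components(self.graph)

    def edge_table(self) -> EdgeTable:
        edges = [
            (a, b, float(data["score"]))
            for a, b, data in self.graph.edges(data=True)
        ]
        attrs = {
            n: (str(d.get("taxon", "")), str(d.get("cluster_type", "")))
            for n, d in self.graph.nodes(data=True)
        }
        return EdgeTable(edges, attrs)
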