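"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles — plain
recursion, explicit lookup tables, brute-force loops — so it shares no code
path with the package implementation it checks.
"""

from functools import lru_cache

from Bio.Align import substitution_matrices

# BLOSUM62 loaded from Biopython's data files (the implementation uses
# biotite's copy), so even the matrix source is independent.
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> int:
    return int(_BLOSUM62[a][b])


def local_align_score(query: str, subject: str,
                      gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal Smith-Waterman score by exhaustive recursion with
    memoization.  Gap convention: a gap of length L costs
    gap_open + (L - 1) * gap_extend.  Feasible for sequences up to a few
    dozen residues."""

    @lru_cache(maxsize=None)
    def match(i: int, j: int) -> int:
        # best local alignment ending with query[i] aligned to subject[j]
        best_prev = 0
        if i > 0 and j > 0:
            best_prev = max(best_prev, match(i - 1, j - 1),
                            gap_q(i - 1, j - 1), gap_s(i - 1, j - 1))
        return blosum62(query[i], subject[j]) + best_prev

    @lru_cache(maxsize=None)
    def gap_s(i: int, j: int) -> int:
        # ends with query[i] aligned to a gap (subject position j last used)
        if i == 0:
            return -(10 ** 9)
        return max(match(i - 1, j) - gap_open, gap_s(i - 1, j) - gap_extend)

    @lru_cache(maxsize=None)
    def gap_q(i: int, j: int) -> int:
        if j == 0:
            return -(10 ** 9)
        return max(match(i, j - 1) - gap_open, gap_q(i, j - 1) - gap_extend)

    best = 0
    for i in range(len(query)):
        for j in range(len(subject)):
            best = max(best, match(i, j))
    return best


# NCBI translation table 11 written out explicitly.
CODON_TABLE_11 = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def translate_frame(dna: str, frame: int) -> str:
    """Per-codon translation of one of the six frames, via the explicit
    codon dictionary (ambiguous codons become X)."""
    if frame < 0:
        dna = dna.translate(_COMPLEMENT)[::-1]
    offset = abs(frame) - 1
    out = []
    for i in range(offset, len(dna) - 2, 3):
        out.append(CODON_TABLE_11.get(dna[i:i + 3], "X"))
    return "".join(out)


def overlapping_clusters(locus_span, cluster_spans) -> list[int]:
    """Brute-force interval overlap: indices of clusters sharing >= 1 base
    with the locus."""
    out = []
    for idx, (s, e) in enumerate(cluster_spans):
        hit = False
        for pos in range(max(locus_span[0], s), min(locus_span[1], e)):
            hit = True
            break
        if hit:
            out.append(idx)
    return out


def interval_overlap_length(a, b) -> int:
    """Brute-force overlap length by position counting."""
    count = 0
    for pos in range(min(a[0], b[0]), max(a[1], b[1])):
        if a[0] <= pos < a[1] and b[0] <= pos < b[1]:
            count += 1
    return count


def best_window_score(protein: str, consensus: str) -> tuple[int, float]:
    """Exhaustive scan: best BLOSUM62 window score against a consensus and
    its fraction of the consensus self-score."""
    w = len(consensus)
    self_score = sum(blosum62(a, a) for a in consensus)
    best = -(10 ** 9)
    best_pos = -1
    for pos in range(len(protein) - w + 1):
        try:
            score = sum(blosum62(a, b)
                        for a, b in zip(consensus, protein[pos:pos + w]))
        except KeyError:
            continue
        if score > best:
            best, best_pos = score, pos
    return best_pos, best / self_score
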