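"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately written from first principles (own codon
table, own DP, own cumulative-sum-free N50) so that agreement with the
package is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

# Standard genetic code, written out by hand.
CODON_TABLE = {
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

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def translate(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(out)


def brute_longest_orf(seq: str):
    """Enumerate every stop-free stretch in all six frames.

    Returns (aa_seq, frame, nt_start, nt_end) under the tie-break rule:
    longest, then frame order +1,+2,+3,-1,-2,-3, then smaller nt_start.
    """
    L = len(seq)
    candidates = []
    for rank, frame in enumerate((1, 2, 3, -1, -2, -3)):
        off = abs(frame) - 1
        aa = translate((seq if frame > 0 else rc(seq))[off:])
        # every maximal stop-free substring
        i = 0
        while i < len(aa):
            if aa[i] == "*":
                i += 1
                continue
            j = i
            while j < len(aa) and aa[j] != "*":
                j += 1
            if frame > 0:
                nt0, nt1 = off + 3 * i, off + 3 * j
            else:
                nt0, nt1 = L - (off + 3 * j), L - (off + 3 * i)
            candidates.append((-(j - i), rank, nt0, nt1, aa[i:j], frame))
            i = j
    if not candidates:
        return "", 1, 0, 0
    neg_len, rank, nt0, nt1, aa, frame = min(candidates, key=lambda c: c[:3])
    return aa, frame, nt0, nt1


def sw_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Plain-Python affine-gap local alignment score, full three matrices."""
    mat = substitution_matrices.load("BLOSUM62")
    NEG = float("-inf")
    m, n = len(a), len(b)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + mat[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def biopython_local_score(a: str, b: str) -> int:
    """Library oracle: Biopython's exact local aligner, same gap convention."""
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12  # first gap residue: open 11 + extend 1
    aligner.extend_gap_score = -1
    return int(aligner.score(a, b))


def brute_n50(lengths) -> int:
    """N50 straight from the definition, no sorting-and-accumulating."""
    total = sum(lengths)
    best = None
    for cand in set(lengths):
        covered = sum(l for l in lengths if l >= cand)
        if covered * 2 >= total and (best is None or cand > best):
            best = cand
    return best
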