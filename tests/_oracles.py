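"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: the motif oracle
enumerates every (start, spacer) assignment symbol-by-symbol with its own
IUPAC table, and the alignment oracle is a plain O(nm) Gotoh local-DP
scoring pass.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def brute_scan(
    seq: str,
    fixed1: str,
    spacer_min: int,
    spacer_max: int,
    fixed2: str,
    min_dist: int,
    max_dist: int,
) -> list[tuple[int, int, int]]:
    """All (start 1-based, spacer_len, gene_distance) matches, enumerated."""
    seq = seq.upper()
    n = len(seq)
    out = []
    for start in range(n):
        for spacer in range(spacer_min, spacer_max + 1):
            end = start + len(fixed1) + spacer + len(fixed2)  # exclusive
            if end > n:
                continue
            gd = n - end
            if not (min_dist <= gd <= max_dist):
                continue
            ok = True
            for k, sym in enumerate(fixed1):
                if seq[start + k] not in _IUPAC[sym]:
                    ok = False
                    break
            if ok:
                off = start + len(fixed1) + spacer
                for k, sym in enumerate(fixed2):
                    if seq[off + k] not in _IUPAC[sym]:
                        ok = False
                        break
            if ok:
                out.append((start + 1, spacer, gd))
    return out


def sw_score(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Optimal local-alignment score, exhaustive Gotoh DP.

    Gap convention: a gap of length L costs gap_open + (L-1)*gap_extend.
    """
    sub = substitution_matrices.load(matrix)
    n, m = len(a), len(b)
    NEG = float("-inf")
    best = 0.0
    # H: best ending in match; E: gap in a (consuming b); F: gap in b
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = sub[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best
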