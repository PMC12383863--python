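"""Independent brute-force oracles used by the tests.

Everything here is deliberately written from first principles, without
importing the implementation under test.
"""

from __future__ import annotations


def affine_local_score(
    ref: str,
    read: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
    bisulfite_rule: bool = True,
) -> float:
    """Smith-Waterman score with affine gaps by plain O(nm) Gotoh DP.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  With the
    bisulfite rule, reference C against read T scores as a match.
    """

    def sub(a: str, b: str) -> float:
        if a == b or (bisulfite_rule and a == "C" and b == "T"):
            return match
        return mismatch

    n, m = len(ref), len(read)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in reference (read consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in read (reference consumed)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + sub(ref[i - 1], read[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


def scan_cg_sites(sequence: str) -> list[int]:
    """All 0-based offsets p with sequence[p:p+2] == 'CG', by linear scan."""
    return [p for p in range(len(sequence) - 1) if sequence[p : p + 2] == "CG"]
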