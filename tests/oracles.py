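"""Independent brute-force oracles used to cross-check the package.

These deliberately share no code with the implementation: coverage is counted
by per-position membership, k-mer matches by naive substring comparison, and
local alignment by a plain, score-only Gotoh dynamic program.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def naive_coverage(alignments, seq_len: int) -> np.ndarray:
    """O(n*L) per-position membership count."""
    counts = np.zeros(seq_len, dtype=np.int64)
    for aln in alignments:
        for pos in range(seq_len):
            if any(b.start <= pos < b.end for b in aln.blocks):
                counts[pos] += 1
    return counts


def naive_kmer_matches(a: str, b: str, k: int, include_revcomp: bool = False):
    """O(n*m) substring comparison; returns a set of (i, j, orientation)."""
    a, b = a.upper(), b.upper()
    out = set()
    for i in range(len(a) - k + 1):
        ka = a[i : i + k]
        if "N" in ka:
            continue
        ka_rc = ka.translate(_COMPLEMENT)[::-1]
        for j in range(len(b) - k + 1):
            kb = b[j : j + k]
            if "N" in kb:
                continue
            if ka == kb:
                out.add((i, j, "forward"))
            if include_revcomp and ka_rc == kb:
                out.add((i, j, "revcomp"))
    return out


def naive_local_score(query: str, subject: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Score-only affine-gap Smith-Waterman (Gotoh, three matrices).

    A gap of length L costs gap_open + (L - 1) * gap_extend.
    """
    n, m = len(query), len(subject)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in query (along subject)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in subject
    best = 0.0
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            diag = H[i - 1][j - 1] + matrix[qi, subject[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best
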