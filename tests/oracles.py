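"""Independent reference implementations used only by the test suite.

These deliberately share no code with the package: a memoized recursive
affine-gap local-alignment scorer, a linear-scan gap finder, a brute-force
N50, and an edit-distance identity.
"""

from __future__ import annotations

import sys
from functools import lru_cache
from typing import List, Tuple

NEG = float("-inf")


def gotoh_best_score(q: str, t: str, match: int, mismatch: int, gap_open: int, gap_extend: int) -> int:
    """Best local affine-gap alignment score by memoized recursion.

    A gap of length k costs gap_open + k * gap_extend.  N (or any
    non-ACGT symbol) never matches.  Returns 0 when no positive-scoring
    alignment exists.
    """
    sys.setrecursionlimit(max(10000, 10 * (len(q) + len(t))))

    def sub(i: int, j: int) -> int:
        a, b = q[i - 1], t[j - 1]
        return match if (a == b and a in "ACGT") else mismatch

    @lru_cache(maxsize=None)
    def H(i: int, j: int) -> float:
        if i == 0 or j == 0:
            return 0
        return max(0, H(i - 1, j - 1) + sub(i, j), E(i, j), F(i, j))

    @lru_cache(maxsize=None)
    def E(i: int, j: int) -> float:  # ends with a gap column consuming t[j-1]
        if j == 0:
            return NEG
        best = H(i, j - 1) + gap_open + gap_extend
        if j > 1:
            best = max(best, E(i, j - 1) + gap_extend)
        return best

    @lru_cache(maxsize=None)
    def F(i: int, j: int) -> float:  # ends with a gap column consuming q[i-1]
        if i == 0:
            return NEG
        best = H(i - 1, j) + gap_open + gap_extend
        if i > 1:
            best = max(best, F(i - 1, j) + gap_extend)
        return best

    best = 0
    for i in range(len(q) + 1):
        for j in range(len(t) + 1):
            best = max(best, H(i, j))
    return int(best)


def linear_scan_gaps(seq: str, min_gap_len: int = 1) -> List[Tuple[int, int]]:
    """Explicit character-by-character N-run scanner."""
    out: List[Tuple[int, int]] = []
    start = None
    for i, ch in enumerate(seq):
        if ch == "N":
            if start is None:
                start = i
        else:
            if start is not None:
                if i - start >= min_gap_len:
                    out.append((start, i))
                start = None
    if start is not None and len(seq) - start >= min_gap_len:
        out.append((start, len(seq)))
    return out


def brute_n50(lengths: List[int]) -> int:
    """Largest candidate L in the multiset with sum(len >= L) >= total/2."""
    if not lengths:
        return 0
    total = sum(lengths)
    winners = [L for L in set(lengths) if 2 * sum(x for x in lengths if x >= L) >= total]
    return max(winners)


def levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def edit_identity(a: str, b: str) -> float:
    """1 - edit distance / max length; 1.0 for two empty strings."""
    if not a and not b:
        return 1.0
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))
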