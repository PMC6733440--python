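"""Strand-aware local alignment of reads against scaffold regions.

The scorer is an exact affine-gap Smith-Waterman (Gotoh) over the full
query x target matrix — targets here are gap flanks of a few hundred bp, so
exactness is cheap and determinism is guaranteed.  A gap of length k costs
``gap_open_penalty + k * gap_extend_penalty`` (the open term is charged once
when the gap is opened).

Default thresholds are deliberately strict: permissive BLAST-style defaults
(raw score 25, 70% identity) accept hits between highly dissimilar
sequences and lead to incorrect fills, so this module floors acceptance at
raw score 50, 80% identity, 100 aligned columns, and a single best hit.
All thresholds are configuration, not constants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np
from numba import njit

NEG_INF = np.int64(-(10**15))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ENCODE = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))
_MASKED = 5  # sentinel that matches nothing; used to exclude claimed target spans


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring and hit-acceptance thresholds.

    ``match_reward`` > 0; the three penalties are <= 0.  ``min_raw_score``,
    ``min_identity`` and ``min_aln_len`` gate hit acceptance; ``max_hits``
    caps how many non-overlapping-on-target hits are reported.
    """

    match_reward: int = 1
    mismatch_penalty: int = -2
    gap_open_penalty: int = -5
    gap_extend_penalty: int = -2
    min_raw_score: int = 50
    min_identity: float = 0.80
    min_aln_len: int = 100
    max_hits: int = 1

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be > 0")
        if self.mismatch_penalty > 0 or self.gap_open_penalty > 0 or self.gap_extend_penalty > 0:
            raise ValueError("penalties must be <= 0")
        if not (0.0 <= self.min_identity <= 1.0):
            raise ValueError("min_identity must be in [0, 1]")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")

    def with_(self, **kw) -> "ScoringParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class AlignmentHit:
    """A scored local alignment of a read (either strand) vs a target region.

    ``read_start``/``read_end`` are 0-based half-open on the FORWARD read,
    whatever the strand; ``target_*`` likewise on the target.  ``identity``
    is matches / aln_len where aln_len counts alignment columns including
    gap columns.
    """

    read_id: str
    strand: str  # '+' | '-'
    read_start: int
    read_end: int
    target_start: int
    target_end: int
    raw_score: int
    identity: float
    aln_len: int
    matches: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.read_end <= self.read_start or self.target_end <= self.target_start:
            raise ValueError("alignment intervals must be non-empty")


def reverse_complement(seq: str) -> str:
    """Standard reverse complement over {A, C, G, T, N}."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"cannot align characters {sorted(bad)}")
    return np.frombuffer(seq.encode("ascii").translate(_ENCODE), dtype=np.uint8).astype(np.int8)


@njit(cache=False)
def _gotoh_fill(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover - jitted
    """Fill Gotoh local-alignment matrices; return (H, E, F, best, bi, bj).

    H: best score of a local alignment ending at (i, j).
    E: ... ending with a gap column consuming target (t[j-1] vs -).
    F: ... ending with a gap column consuming query (q[i-1] vs -).
    The best cell is the first (row-major) cell attaining the maximum.
    """
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = H[i, j - 1] + gap_open + gap_extend
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] + gap_open + gap_extend
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            tj = t[j - 1]
            if qi == tj and qi < 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def _traceback(H, E, F, q, t, end_i, end_j, params: ScoringParams):
    """Walk back from (end_i, end_j) in state H until a zero cell.

    Preference order diagonal > E (gap in query row) > F is fixed for
    determinism.  Returns (start_i, start_j, matches, columns).
    """
    go, ge = params.gap_open_penalty, params.gap_extend_penalty
    i, j = end_i, end_j
    matches = 0
    cols = 0
    state = "H"
    score_check = 0
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            is_match = q[i - 1] == t[j - 1] and q[i - 1] < 4
            s = params.match_reward if is_match else params.mismatch_penalty
            if H[i, j] == H[i - 1, j - 1] + s:
                cols += 1
                score_check += s
                if is_match:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("inconsistent traceback")
        elif state == "E":
            cols += 1
            score_check += ge
            if E[i, j] == H[i, j - 1] + go + ge:
                score_check += go
                state = "H"
            j -= 1
        else:  # state == "F"
            cols += 1
            score_check += ge
            if F[i, j] == H[i - 1, j] + go + ge:
                score_check += go
                state = "H"
            i -= 1
    if score_check != H[end_i, end_j]:  # pragma: no cover - DP consistency guard
        raise AssertionError("traceback score disagrees with DP score")
    return i, j, matches, cols


def local_align(
    query: str,
    target: str,
    params: ScoringParams,
    query_id: str = "query",
) -> List[AlignmentHit]:
    """Best local alignments of ``query`` (both strands) against ``target``.

    Returns up to ``params.max_hits`` hits, non-overlapping on the target
    (each accepted hit's target span is masked before searching for the
    next), sorted by raw score descending.  Hits below ``min_raw_score``
    are never returned.  On a score tie between strands, '+' wins.
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    q_fwd = encode(query)
    q_rev = encode(reverse_complement(query))
    t_arr = encode(target).copy()
    read_len = len(query)

    score_floor = max(params.min_raw_score, 1)
    hits: List[AlignmentHit] = []
    while len(hits) < params.max_hits:
        best = None  # (score, strand_rank, strand, q, H, E, F, bi, bj)
        for strand_rank, (strand, q) in enumerate((("+", q_fwd), ("-", q_rev))):
            H, E, F, score, bi, bj = _gotoh_fill(
                q, t_arr,
                np.int64(params.match_reward), np.int64(params.mismatch_penalty),
                np.int64(params.gap_open_penalty), np.int64(params.gap_extend_penalty),
            )
            if score < score_floor:
                continue
            if best is None or score > best[0]:
                best = (int(score), strand_rank, strand, q, H, E, F, int(bi), int(bj))
        if best is None:
            break
        score, _, strand, q, H, E, F, bi, bj = best
        si, sj, matches, cols = _traceback(H, E, F, q, t_arr, bi, bj, params)
        if strand == "+":
            read_start, read_end = si, bi
        else:  # mirror [si, bi) on the reverse strand back to forward coords
            read_start, read_end = read_len - bi, read_len - si
        hits.append(
            AlignmentHit(
                read_id=query_id,
                strand=strand,
                read_start=read_start,
                read_end=read_end,
                target_start=sj,
                target_end=bj,
                raw_score=score,
                identity=matches / cols,
                aln_len=cols,
                matches=matches,
            )
        )
        t_arr[sj:bj] = _MASKED  # exclude this target span from further hits
    hits.sort(key=_hit_order)
    return hits


def _hit_order(h: AlignmentHit):
    return (-h.raw_score, h.target_start, 0 if h.strand == "+" else 1, h.read_id)


def filter_hits(hits: List[AlignmentHit], params: ScoringParams) -> List[AlignmentHit]:
    """Apply score/identity/length thresholds, then truncate to ``max_hits``.

    Survivors are sorted by raw score descending with ties broken by
    (target_start, '+' strand first, read_id).
    """
    kept = [
        h
        for h in hits
        if h.raw_score >= params.min_raw_score
        and h.identity >= params.min_identity
        and h.aln_len >= params.min_aln_len
    ]
    kept.sort(key=_hit_order)
    return kept[: params.max_hits]


def hits_to_tsv(hits: List[AlignmentHit]) -> str:
    """Tab-separated hit report with 1-based inclusive intervals."""
    lines = ["read_id\tstrand\tread_start\tread_end\ttarget_start\ttarget_end\traw_score\tidentity\taln_len"]
    for h in hits:
        lines.append(
            f"{h.read_id}\t{h.strand}\t{h.read_start + 1}\t{h.read_end}\t"
            f"{h.target_start + 1}\t{h.target_end}\t{h.raw_score}\t{h.identity:.4f}\t{h.aln_len}"
        )
    return "\n".join(lines) + "\n"
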