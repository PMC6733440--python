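"""Locating N-gaps in scaffolds and extracting alignment flanks around them.

Coordinates are 0-based half-open throughout the library; reports render
them 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .seqio import SequenceRecord

DEFAULT_FLANK_LEN = 300
DEFAULT_MIN_FLANK_LEN = 50

_N_RUN = re.compile(r"N+")


@dataclass(frozen=True)
class GapInterval:
    """A maximal run of N inside a scaffold, 0-based half-open."""

    scaffold_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gap interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def key(self) -> Tuple[str, int, int]:
        return (self.scaffold_id, self.start, self.end)


@dataclass(frozen=True)
class Flank:
    """Contiguous non-N anchor sequence immediately adjacent to a gap."""

    gap: GapInterval
    side: str  # "left" | "right"
    sequence: str
    scaffold_start: int
    scaffold_end: int

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if "N" in self.sequence:
            raise ValueError("flank sequence must be N-free")
        if len(self.sequence) != self.scaffold_end - self.scaffold_start:
            raise ValueError("flank coordinates disagree with sequence length")


def find_gaps(seq: str, min_gap_len: int = 1, scaffold_id: str = "") -> List[GapInterval]:
    """Return maximal N-runs of length >= ``min_gap_len``, sorted by start."""
    if min_gap_len < 1:
        raise ValueError(f"min_gap_len must be >= 1, got {min_gap_len}")
    return [
        GapInterval(scaffold_id, m.start(), m.end())
        for m in _N_RUN.finditer(seq)
        if m.end() - m.start() >= min_gap_len
    ]


def extract_flanks(
    scaffold: SequenceRecord,
    gap: GapInterval,
    flank_len: int = DEFAULT_FLANK_LEN,
    min_flank_len: int = DEFAULT_MIN_FLANK_LEN,
) -> Tuple[Optional[Flank], Optional[Flank]]:
    """Extract up to ``flank_len`` non-N bp on each side of ``gap``.

    Flanks never cross another gap: the scan stops at the nearest N (or the
    scaffold boundary).  A side shorter than ``min_flank_len`` is returned
    as None — callers treat that side as having no usable anchor.
    """
    if flank_len < 1:
        raise ValueError(f"flank_len must be >= 1, got {flank_len}")
    seq = scaffold.sequence
    if gap.end > len(seq) or seq[gap.start : gap.end].strip("N"):
        raise ValueError(
            f"gap [{gap.start}, {gap.end}) does not address an N-run of scaffold {scaffold.id!r}"
        )

    # left: scan backwards from gap.start until N, boundary, or flank_len
    ls = gap.start
    while ls > 0 and gap.start - ls < flank_len and seq[ls - 1] != "N":
        ls -= 1
    left: Optional[Flank] = None
    if gap.start - ls >= min_flank_len:
        left = Flank(gap, "left", seq[ls : gap.start], ls, gap.start)

    # right: scan forwards from gap.end
    re_ = gap.end
    n = len(seq)
    while re_ < n and re_ - gap.end < flank_len and seq[re_] != "N":
        re_ += 1
    right: Optional[Flank] = None
    if re_ - gap.end >= min_flank_len:
        right = Flank(gap, "right", seq[gap.end : re_], gap.end, re_)

    return left, right


def gaps_to_bed(gaps: List[GapInterval]) -> str:
    """Render gap intervals as BED lines (0-based half-open)."""
    return "".join(f"{g.scaffold_id}\t{g.start}\t{g.end}\n" for g in gaps)
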