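"""PacBio-style read-name parsing and same-well fill-conflict detection.

Subreads sharing a (movie, ZMW well) pair come from one sequenced molecule
and must therefore anchor consistent genomic locations.  When subreads from
one well anchor two or more distinct gaps, all of those fills are aborted
and the conflict is reported — conflicting origins also flag potential
errors made earlier, at scaffolding time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

logger = logging.getLogger(__name__)

GapKey = Tuple[str, int, int]  # (scaffold_id, gap_start, gap_end)

_RANGE_RE = re.compile(r"^(\d+)_(\d+)$")


@dataclass(frozen=True)
class ReadOrigin:
    """Physical origin of a subread: movie, ZMW well, optional bp range."""

    movie: str
    well: int
    subread_range: Optional[Tuple[int, int]] = None

    @property
    def key(self) -> Tuple[str, int]:
        return (self.movie, self.well)


@dataclass
class ConflictReport:
    """One same-well conflict: reads from one molecule anchoring >= 2 gaps."""

    movie: str
    well: int
    read_ids: List[str]
    gap_keys: List[GapKey]
    action: str = "aborted"


def parse_read_name(name: str) -> Optional[ReadOrigin]:
    """Parse ``movie/well/start_end`` read names; return None when unparseable.

    Names with a movie and a numeric well but no (or malformed) range parse
    with ``subread_range=None`` — the range is not needed for conflict keys.
    Unparseable names disable origin checking for that read (None is a
    value, not an error).
    """
    parts = name.split("/")
    if len(parts) < 2:
        return None
    movie, well = parts[0], parts[1]
    if not movie or not well.isdigit():
        return None
    subread_range: Optional[Tuple[int, int]] = None
    if len(parts) >= 3:
        m = _RANGE_RE.match(parts[2])
        if m:
            subread_range = (int(m.group(1)), int(m.group(2)))
    return ReadOrigin(movie=movie, well=int(well), subread_range=subread_range)


def check_conflicts(
    assignments: Sequence[Tuple[str, Optional[ReadOrigin], GapKey]],
) -> Tuple[List[Tuple[str, Optional[ReadOrigin], GapKey]], List[ConflictReport]]:
    """Split fill assignments into allowed ones and same-well conflicts.

    For every (movie, well) whose subreads anchor >= 2 distinct gaps, ALL
    assignments under that key are removed and one ConflictReport emitted.
    Reads with unknown origin always pass through unchecked.
    """
    by_key: Dict[Tuple[str, int], List[int]] = {}
    for idx, (_read_id, origin, _gap) in enumerate(assignments):
        if origin is None:
            continue
        by_key.setdefault(origin.key, []).append(idx)

    conflicted_idx: set = set()
    reports: List[ConflictReport] = []
    for key in sorted(by_key):
        idxs = by_key[key]
        gap_keys = sorted({assignments[i][2] for i in idxs})
        if len(gap_keys) < 2:
            continue
        conflicted_idx.update(idxs)
        read_ids = sorted({assignments[i][0] for i in idxs})
        report = ConflictReport(movie=key[0], well=key[1], read_ids=read_ids, gap_keys=gap_keys)
        reports.append(report)
        logger.warning(
            "same-well conflict: movie=%s well=%d reads=%s anchor %d distinct gaps %s; "
            "aborting these fills (possible scaffolding error)",
            key[0], key[1], ",".join(read_ids), len(gap_keys), gap_keys,
        )
    allowed = [a for i, a in enumerate(assignments) if i not in conflicted_idx]
    return allowed, reports
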