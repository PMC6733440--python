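"""Assembly and gap statistics, and before/after fill summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, List, Optional, Sequence

from .gaps import find_gaps
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)


def round_half_up_ratio(numerator: int, denominator: int, ndigits: int) -> float:
    """Exact half-up rounding of numerator/denominator to ``ndigits`` decimals.

    Computed over rationals so printed report figures are reproducible
    bit-for-bit (Python's built-in round is banker's rounding).
    """
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    scaled = Fraction(numerator, denominator) * 10**ndigits
    whole, frac = divmod(scaled.numerator, scaled.denominator)
    if 2 * frac >= scaled.denominator:
        whole += 1
    return whole / 10**ndigits


@dataclass(frozen=True)
class AssemblyStats:
    """Per-assembly summary: counts, total bp, N50, and gap content.

    ``gap_pct`` is 100 * gap_bp / total_bp half-up rounded to 2 decimals,
    the precision used in reports.
    """

    n_seqs: int
    total_bp: int
    n50: int
    gap_count: int
    gap_bp: int
    gap_pct: float


def n50(lengths: Iterable[int]) -> int:
    """Largest L such that sequences of length >= L cover half the total.

    Empty input returns 0 with a warning.
    """
    lens: List[int] = sorted(lengths, reverse=True)
    if not lens:
        logger.warning("n50 of empty length set; returning 0")
        return 0
    if lens[-1] <= 0:
        raise ValueError("lengths must be positive")
    total = sum(lens)
    cum = 0
    for length in lens:
        cum += length
        if 2 * cum >= total:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def assembly_stats(records: Sequence[SequenceRecord], min_gap_len: int = 1) -> AssemblyStats:
    """Compute the standard report columns for a set of sequences."""
    if not records:
        logger.warning("assembly_stats of zero records")
        return AssemblyStats(0, 0, 0, 0, 0, 0.0)
    total_bp = sum(len(r) for r in records)
    gap_count = 0
    gap_bp = 0
    for rec in records:
        for gap in find_gaps(rec.sequence, min_gap_len, rec.id):
            gap_count += 1
            gap_bp += gap.length
    return AssemblyStats(
        n_seqs=len(records),
        total_bp=total_bp,
        n50=n50([len(r) for r in records]),
        gap_count=gap_count,
        gap_bp=gap_bp,
        gap_pct=round_half_up_ratio(100 * gap_bp, total_bp, 2),
    )


@dataclass(frozen=True)
class FillSummary:
    """Before/after comparison of one gap-filling run.

    ``pct_gap_bp_filled`` is None (not applicable) when the input had no
    gapped bases.  Percentages are half-up rounded to 1 decimal.
    """

    pct_gap_bp_filled: Optional[float]
    pct_seq_reduction: float
    gap_bp_before: int
    gap_bp_after: int
    n_seqs_before: int
    n_seqs_after: int


def fill_summary(before: AssemblyStats, after: AssemblyStats) -> FillSummary:
    if before.gap_bp == 0:
        pct_filled: Optional[float] = None
    else:
        pct_filled = round_half_up_ratio(100 * (before.gap_bp - after.gap_bp), before.gap_bp, 1)
    pct_reduction = (
        0.0
        if before.n_seqs == 0
        else round_half_up_ratio(100 * (before.n_seqs - after.n_seqs), before.n_seqs, 1)
    )
    return FillSummary(
        pct_gap_bp_filled=pct_filled,
        pct_seq_reduction=pct_reduction,
        gap_bp_before=before.gap_bp,
        gap_bp_after=after.gap_bp,
        n_seqs_before=before.n_seqs,
        n_seqs_after=after.n_seqs,
    )


def stats_to_tsv(stats: AssemblyStats, label: str = "assembly") -> str:
    header = "label\tn_seqs\ttotal_bp\tn50\tgap_count\tgap_bp\tgap_pct"
    row = (
        f"{label}\t{stats.n_seqs}\t{stats.total_bp}\t{stats.n50}\t"
        f"{stats.gap_count}\t{stats.gap_bp}\t{stats.gap_pct:.2f}"
    )
    return header + "\n" + row + "\n"
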