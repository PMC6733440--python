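"""The gap-fill engine: per-scaffold serial loop, fill decisions, and the
whole-assembly pipeline.

Discipline enforced here:

* two-anchor rule — a gap is filled only when each flank has exactly one
  surviving hit against the read, both on the same strand and in flank
  order along the read; the replacement is the read subsequence between
  the anchors;
* single use — a read is consumed by its first FILLED decision and attempts
  no further gaps;
* scaffold locality — a read only ever touches the scaffold it is listed
  under in the evidence map;
* origin guard — fills whose same-well siblings anchor a different gap are
  aborted (see :mod:`flankfill.origin`);
* serial re-scan — after every applied fill the draft is re-scanned for
  gaps, since coordinates shift.
"""

from __future__ import annotations

import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from .align import ScoringParams, filter_hits, local_align, reverse_complement
from .gaps import (
    DEFAULT_FLANK_LEN,
    DEFAULT_MIN_FLANK_LEN,
    Flank,
    GapInterval,
    extract_flanks,
    find_gaps,
)
from .origin import ConflictReport, GapKey, ReadOrigin, check_conflicts, parse_read_name
from .seqio import EvidenceMap, EvidenceError, SequenceRecord, parse_evidence, read_fasta
from .stats import AssemblyStats, FillSummary, assembly_stats, fill_summary

logger = logging.getLogger(__name__)

DEFAULT_MAX_TRIM = 10
DEFAULT_MIN_GAP_LEN = 1

# decision statuses
FILLED = "FILLED"
REJECTED = "REJECTED"
ABORTED_CONFLICT = "ABORTED_CONFLICT"

# rejection reasons, in the order plan_fill tests them
REASONS = (
    "no_left_anchor",
    "no_right_anchor",
    "strand_mismatch",
    "disordered_anchors",
    "below_threshold",
    "conflict",
    "already_used",
)


@dataclass
class FillDecision:
    """Outcome for one (gap, read) pair."""

    gap: GapInterval
    read_id: str
    status: str
    replacement: str = ""
    left_trim: int = 0
    right_trim: int = 0
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status not in (FILLED, REJECTED, ABORTED_CONFLICT):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == FILLED and (not self.replacement or "N" in self.replacement):
            raise ValueError("FILLED decision requires a non-empty, N-free replacement")
        if self.reason and self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")


@dataclass
class FillReport:
    """Per-scaffold fill outcome: one terminal decision per input gap."""

    scaffold_id: str
    decisions: List[FillDecision] = field(default_factory=list)
    gap_count_before: int = 0
    gap_bp_before: int = 0
    gap_count_after: int = 0
    gap_bp_after: int = 0
    reads_consumed: List[str] = field(default_factory=list)
    conflicts: List[ConflictReport] = field(default_factory=list)


class StaleDecisionError(ValueError):
    """A fill decision was applied to a sequence it no longer fits."""


def _one_anchor(
    read: SequenceRecord, flank: Optional[Flank], params: ScoringParams
):
    """Exactly-one surviving hit of ``read`` against ``flank``, else None."""
    if flank is None:
        return None
    hits = filter_hits(local_align(read.sequence, flank.sequence, params, query_id=read.id), params)
    if len(hits) != 1:
        return None
    return hits[0]


def plan_fill(
    scaffold: SequenceRecord,
    gap: GapInterval,
    read: SequenceRecord,
    params: ScoringParams,
    flank_len: int = DEFAULT_FLANK_LEN,
    max_trim: int = DEFAULT_MAX_TRIM,
    min_flank_len: int = DEFAULT_MIN_FLANK_LEN,
) -> FillDecision:
    """Decide whether ``read`` can fill ``gap`` on ``scaffold``.

    FILLED requires, in order: a unique left-flank anchor, a unique
    right-flank anchor, strand agreement, flank order preserved along the
    (oriented) read, an N-free replacement, and edge trims within
    ``max_trim``.  The first failing condition becomes the reason.
    """

    def reject(reason: str) -> FillDecision:
        return FillDecision(gap=gap, read_id=read.id, status=REJECTED, reason=reason)

    left_flank, right_flank = extract_flanks(scaffold, gap, flank_len, min_flank_len)
    left_hit = _one_anchor(read, left_flank, params)
    if left_hit is None:
        return reject("no_left_anchor")
    right_hit = _one_anchor(read, right_flank, params)
    if right_hit is None:
        return reject("no_right_anchor")
    if left_hit.strand != right_hit.strand:
        return reject("strand_mismatch")

    # orient the read so the gap reads left-to-right
    rlen = len(read)
    if left_hit.strand == "+":
        oriented = read.sequence
        left_end = left_hit.read_end
        right_start = right_hit.read_start
    else:
        oriented = reverse_complement(read.sequence)
        left_end = rlen - left_hit.read_start
        right_start = rlen - right_hit.read_end
    if left_end >= right_start:
        return reject("disordered_anchors")

    replacement = oriented[left_end:right_start]
    if "N" in replacement:
        return reject("below_threshold")

    assert left_flank is not None and right_flank is not None
    left_trim = gap.start - (left_flank.scaffold_start + left_hit.target_end)
    right_trim = (right_flank.scaffold_start + right_hit.target_start) - gap.end
    if left_trim > max_trim or right_trim > max_trim:
        return reject("below_threshold")

    return FillDecision(
        gap=gap,
        read_id=read.id,
        status=FILLED,
        replacement=replacement,
        left_trim=left_trim,
        right_trim=right_trim,
    )


def apply_fill(scaffold: SequenceRecord, decision: FillDecision) -> SequenceRecord:
    """Splice a FILLED decision into the scaffold sequence.

    Everything outside [gap.start - left_trim, gap.end + right_trim) is
    byte-identical to the input.
    """
    if decision.status != FILLED:
        raise ValueError("apply_fill requires a FILLED decision")
    gap = decision.gap
    seq = scaffold.sequence
    if gap.end > len(seq) or seq[gap.start : gap.end].strip("N"):
        raise StaleDecisionError(
            f"gap [{gap.start}, {gap.end}) is not an N-run on the current sequence of "
            f"{scaffold.id!r}; the decision is stale"
        )
    new_seq = (
        seq[: gap.start - decision.left_trim]
        + decision.replacement
        + seq[gap.end + decision.right_trim :]
    )
    return SequenceRecord(id=scaffold.id, sequence=new_seq, description=scaffold.description)


@dataclass
class _TrackedGap:
    orig: GapInterval      # coordinates on the input scaffold (stable id)
    cur_start: int         # coordinates on the current draft
    cur_end: int
    decision: Optional[FillDecision] = None
    last_reason: str = "no_left_anchor"  # default when never attempted


def fill_scaffold(
    scaffold: SequenceRecord,
    reads: Sequence[SequenceRecord],
    params: ScoringParams,
    flank_len: int = DEFAULT_FLANK_LEN,
    max_trim: int = DEFAULT_MAX_TRIM,
    min_flank_len: int = DEFAULT_MIN_FLANK_LEN,
    min_gap_len: int = DEFAULT_MIN_GAP_LEN,
    blocked_gaps: Optional[Set[GapKey]] = None,
) -> Tuple[SequenceRecord, FillReport]:
    """Serial fill loop over one scaffold.

    For each read in evidence order, the current draft is re-scanned for
    gaps and each remaining gap attempted in coordinate order; the first
    FILLED decision is applied immediately and consumes the read.  Gaps
    whose stable key is in ``blocked_gaps`` are never filled and end as
    ABORTED_CONFLICT.
    """
    blocked_gaps = blocked_gaps or set()
    orig_gaps = find_gaps(scaffold.sequence, min_gap_len, scaffold.id)
    tracked = [_TrackedGap(g, g.start, g.end) for g in orig_gaps]
    report = FillReport(
        scaffold_id=scaffold.id,
        gap_count_before=len(orig_gaps),
        gap_bp_before=sum(g.length for g in orig_gaps),
    )
    current = scaffold

    def open_gaps() -> List[_TrackedGap]:
        return [t for t in tracked if t.decision is None and t.orig.key() not in blocked_gaps]

    for read in reads:
        remaining = open_gaps()
        if not remaining:
            break
        # serial re-scan: gaps on the current draft must match the tracked set
        rescanned = find_gaps(current.sequence, min_gap_len, scaffold.id)
        live = sorted(
            [(t.cur_start, t.cur_end) for t in tracked if t.decision is None or t.decision.status != FILLED]
        )
        if [(g.start, g.end) for g in rescanned] != live:  # pragma: no cover - invariant guard
            raise AssertionError(f"gap tracking out of sync on scaffold {scaffold.id!r}")

        for t in remaining:
            gap_now = GapInterval(scaffold.id, t.cur_start, t.cur_end)
            decision = plan_fill(
                current, gap_now, read, params, flank_len, max_trim, min_flank_len
            )
            if decision.status != FILLED:
                t.last_reason = decision.reason
                continue
            current = apply_fill(current, decision)
            delta = len(decision.replacement) - gap_now.length - decision.left_trim - decision.right_trim
            for other in tracked:
                if other is not t and other.cur_start > t.cur_start:
                    other.cur_start += delta
                    other.cur_end += delta
            # report the fill against the gap's stable (input) coordinates
            t.decision = FillDecision(
                gap=t.orig,
                read_id=decision.read_id,
                status=FILLED,
                replacement=decision.replacement,
                left_trim=decision.left_trim,
                right_trim=decision.right_trim,
            )
            report.reads_consumed.append(read.id)
            break  # a read is only used once

    for t in tracked:
        if t.decision is not None:
            report.decisions.append(t.decision)
        elif t.orig.key() in blocked_gaps:
            report.decisions.append(
                FillDecision(gap=t.orig, read_id="", status=ABORTED_CONFLICT, reason="conflict")
            )
        else:
            report.decisions.append(
                FillDecision(gap=t.orig, read_id="", status=REJECTED, reason=t.last_reason)
            )

    after = find_gaps(current.sequence, min_gap_len, scaffold.id)
    report.gap_count_after = len(after)
    report.gap_bp_after = sum(g.length for g in after)
    return current, report


def _fill_worker(args):
    """Top-level worker so scaffold batches can cross process boundaries."""
    scaffold, reads, params, flank_len, max_trim, min_flank_len, min_gap_len, blocked = args
    return fill_scaffold(
        scaffold, reads, params, flank_len, max_trim, min_flank_len, min_gap_len, blocked
    )


@dataclass
class RunReport:
    """Whole-run outcome: per-scaffold reports plus global bookkeeping."""

    scaffold_reports: Dict[str, FillReport] = field(default_factory=dict)
    conflicts: List[ConflictReport] = field(default_factory=list)
    stats_before: Optional[AssemblyStats] = None
    stats_after: Optional[AssemblyStats] = None

    @property
    def decisions(self) -> List[FillDecision]:
        out: List[FillDecision] = []
        for rep in self.scaffold_reports.values():
            out.extend(rep.decisions)
        return out

    def summary(self) -> FillSummary:
        assert self.stats_before is not None and self.stats_after is not None
        return fill_summary(self.stats_before, self.stats_after)

    def summary_dict(self) -> dict:
        s = self.summary()
        filled = sum(1 for d in self.decisions if d.status == FILLED)
        aborted = sum(1 for d in self.decisions if d.status == ABORTED_CONFLICT)
        return {
            "n_gaps": len(self.decisions),
            "n_filled": filled,
            "n_rejected": len(self.decisions) - filled - aborted,
            "n_aborted_conflict": aborted,
            "gap_bp_before": s.gap_bp_before,
            "gap_bp_after": s.gap_bp_after,
            "pct_gap_bp_filled": s.pct_gap_bp_filled,
            "n_seqs_before": s.n_seqs_before,
            "n_seqs_after": s.n_seqs_after,
            "conflicts": [
                {
                    "movie": c.movie,
                    "well": c.well,
                    "read_ids": c.read_ids,
                    "gap_keys": [list(k) for k in c.gap_keys],
                }
                for c in self.conflicts
            ],
        }


def run_pipeline(
    scaffolds: Union[str, Path, Sequence[SequenceRecord]],
    reads: Union[str, Path, Sequence[SequenceRecord]],
    evidence: Union[str, Path, EvidenceMap],
    params: Optional[ScoringParams] = None,
    flank_len: int = DEFAULT_FLANK_LEN,
    max_trim: int = DEFAULT_MAX_TRIM,
    min_flank_len: int = DEFAULT_MIN_FLANK_LEN,
    min_gap_len: int = DEFAULT_MIN_GAP_LEN,
    threads: int = 1,
) -> Tuple[List[SequenceRecord], RunReport]:
    """Fill every scaffold that has read evidence; pass the rest through.

    Output order and sequence count equal the input's.  Same-well origin
    conflicts are resolved globally (across scaffolds): conflicting fills
    are re-planned away and their gaps reported as ABORTED_CONFLICT.
    ``threads`` > 1 partitions scaffolds across worker processes; the
    output is byte-identical to the single-threaded run.
    """
    params = params or ScoringParams()
    if isinstance(scaffolds, (str, Path)):
        scaffolds = read_fasta(scaffolds)
    if isinstance(reads, (str, Path)):
        reads = read_fasta(reads)
    if isinstance(evidence, (str, Path)):
        evidence = parse_evidence(evidence)

    scaffold_ids = {s.id for s in scaffolds}
    unknown_scaffolds = [sid for sid in evidence.entries if sid not in scaffold_ids]
    if unknown_scaffolds:
        raise EvidenceError(f"evidence references unknown scaffold ids: {unknown_scaffolds}")
    reads_by_id = {r.id: r for r in reads}
    unknown_reads = [rid for rid in evidence.all_read_ids() if rid not in reads_by_id]
    if unknown_reads:
        raise EvidenceError(f"evidence references unknown read ids: {unknown_reads}")

    stats_before = assembly_stats(list(scaffolds), min_gap_len)

    def scaffold_reads(sid: str) -> List[SequenceRecord]:
        return [reads_by_id[rid] for rid in evidence.reads_for(sid)]

    todo = [s for s in scaffolds if evidence.reads_for(s.id)]
    blocked: Set[GapKey] = set()
    results: Dict[str, Tuple[SequenceRecord, FillReport]] = {}
    conflicts_by_key: Dict[Tuple[str, int], ConflictReport] = {}

    def run_batch(batch: List[SequenceRecord]) -> None:
        jobs = [
            (s, scaffold_reads(s.id), params, flank_len, max_trim, min_flank_len, min_gap_len, blocked)
            for s in batch
        ]
        if threads > 1 and len(jobs) > 1:
            with ProcessPoolExecutor(max_workers=threads) as pool:
                outs = list(pool.map(_fill_worker, jobs))
        else:
            outs = [_fill_worker(j) for j in jobs]
        for s, out in zip(batch, outs):
            results[s.id] = out

    run_batch(todo)

    # global origin-guard fixpoint: abort fills whose same-well siblings
    # anchor a different gap, then re-plan the affected scaffolds
    for _ in range(len(todo) + 1):
        assignments = []
        for sid, (_rec, rep) in results.items():
            for d in rep.decisions:
                if d.status == FILLED:
                    assignments.append((d.read_id, parse_read_name(d.read_id), d.gap.key()))
        _allowed, reports = check_conflicts(assignments)
        newly_blocked: Set[GapKey] = set()
        for rep in reports:
            conflicts_by_key[(rep.movie, rep.well)] = rep
            newly_blocked.update(k for k in rep.gap_keys if k not in blocked)
        if not newly_blocked:
            break
        blocked.update(newly_blocked)
        affected_ids = {k[0] for k in newly_blocked}
        run_batch([s for s in todo if s.id in affected_ids])
    else:  # pragma: no cover - bounded by construction
        raise AssertionError("origin-conflict resolution did not converge")

    run_report = RunReport(conflicts=sorted(conflicts_by_key.values(), key=lambda c: (c.movie, c.well)))
    out_records: List[SequenceRecord] = []
    for s in scaffolds:
        if s.id in results:
            rec, rep = results[s.id]
            out_records.append(rec)
            run_report.scaffold_reports[s.id] = rep
        else:
            out_records.append(s)
            run_report.scaffold_reports[s.id] = FillReport(scaffold_id=s.id)
            gs = find_gaps(s.sequence, min_gap_len, s.id)
            rep = run_report.scaffold_reports[s.id]
            rep.gap_count_before = rep.gap_count_after = len(gs)
            rep.gap_bp_before = rep.gap_bp_after = sum(g.length for g in gs)
            for g in gs:
                rep.decisions.append(
                    FillDecision(gap=g, read_id="", status=REJECTED, reason="no_left_anchor")
                )

    run_report.stats_before = stats_before
    run_report.stats_after = assembly_stats(out_records, min_gap_len)
    return out_records, run_report


REPORT_COLUMNS = (
    "scaffold",
    "gap_start",
    "gap_end",
    "status",
    "read_id",
    "reason",
    "replacement_len",
    "left_trim",
    "right_trim",
)


def write_report(report: RunReport, path: Union[str, Path]) -> None:
    """Write the per-gap TSV report (gap intervals 1-based inclusive)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for sid, rep in report.scaffold_reports.items():
            for d in sorted(rep.decisions, key=lambda d: d.gap.start):
                fh.write(
                    f"{sid}\t{d.gap.start + 1}\t{d.gap.end}\t{d.status}\t{d.read_id}\t"
                    f"{d.reason}\t{len(d.replacement)}\t{d.left_trim}\t{d.right_trim}\n"
                )


def read_report(path: Union[str, Path]) -> List[dict]:
    """Parse a report TSV back into row dicts (for summaries and tests)."""
    rows: List[dict] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != REPORT_COLUMNS:
            raise ValueError(f"unexpected report header in {path}: {header}")
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            row = dict(zip(header, vals))
            for k in ("gap_start", "gap_end", "replacement_len", "left_trim", "right_trim"):
                row[k] = int(row[k])
            rows.append(row)
    return rows


def write_summary_json(report: RunReport, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.summary_dict(), fh, indent=2)
        fh.write("\n")
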