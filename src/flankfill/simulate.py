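"""Self-contained fixture generation with known ground truth.

Produces a random reference, a gapped scaffold whose N-runs replace known
reference windows, gap-spanning long reads with a configurable error model,
and the matching evidence map.  Read names follow the PacBio subread
convention ``movie/well/start_end`` with one well per read, so the origin
guard stays quiet unless a conflict fixture is requested explicitly.

The error model draws, per reference base, substitution : insertion :
deletion at 6 : 2 : 2 of the configured rate — lighter on indels than real
CLR data, which keeps flank anchoring testable while still stressing the
aligner.  All randomness flows from a single seeded generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .align import reverse_complement
from .seqio import EvidenceMap, SequenceRecord, write_evidence_tsv, write_fasta

_BASES = np.array(list("ACGT"))


class GeometryError(ValueError):
    """The requested gap layout does not fit in the reference."""


@dataclass(frozen=True)
class SimConfig:
    """Knobs for one simulated dataset.  ``seed`` is mandatory."""

    seed: int
    ref_len: int = 6000
    n_scaffolds: int = 1
    n_gaps: int = 3
    gap_len_range: Tuple[int, int] = (50, 200)
    min_segment: int = 700
    end_margin: int = 400
    flank_margin: int = 400
    reads_per_gap: int = 2
    error_rate: float = 0.0
    gc_fraction: float = 0.5
    gap_length_jitter: int = 0

    def __post_init__(self) -> None:
        if self.ref_len < 1 or self.n_gaps < 0 or self.reads_per_gap < 1:
            raise ValueError("lengths and counts must be positive")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if self.gap_len_range[0] < 1 or self.gap_len_range[0] > self.gap_len_range[1]:
            raise ValueError("invalid gap_len_range")


@dataclass(frozen=True)
class GapTruth:
    """True sequence removed under one N-run (scaffold == reference coords)."""

    start: int
    end: int
    sequence: str


@dataclass
class SimTruth:
    """A complete fixture: references, gapped scaffolds, truths, reads, evidence."""

    references: Dict[str, str] = field(default_factory=dict)     # scaffold id -> reference
    scaffolds: List[SequenceRecord] = field(default_factory=list)
    gap_truths: Dict[str, List[GapTruth]] = field(default_factory=dict)
    reads: List[SequenceRecord] = field(default_factory=list)
    evidence: EvidenceMap = field(default_factory=EvidenceMap)


def _rng(rng_or_seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def simulate_reference(length: int, gc_fraction: float = 0.5, seed: Union[int, np.random.Generator] = 0) -> str:
    """I.i.d. random DNA with P(G or C) = ``gc_fraction``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = _rng(seed)
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    probs = [p_at, p_gc, p_gc, p_at]  # A C G T
    return "".join(_BASES[rng.choice(4, size=length, p=probs)])


def make_gapped_scaffold(
    reference: str,
    n_gaps: int,
    gap_len_range: Tuple[int, int],
    min_segment: int,
    seed: Union[int, np.random.Generator],
    end_margin: int = 400,
    scaffold_id: str = "scaffold_1",
    gap_length_jitter: int = 0,
) -> Tuple[SequenceRecord, List[GapTruth]]:
    """Replace ``n_gaps`` disjoint internal windows of the reference with N.

    Windows are separated by >= ``min_segment`` known bp and sit at least
    ``end_margin`` bp from either end.  By default each N-run has the same
    length as the removed truth; ``gap_length_jitter`` > 0 perturbs N-run
    lengths by up to that many bp to exercise length-agnostic filling.
    """
    rng = _rng(seed)
    if n_gaps == 0:
        return SequenceRecord(id=scaffold_id, sequence=reference), []
    lens = [int(rng.integers(gap_len_range[0], gap_len_range[1] + 1)) for _ in range(n_gaps)]
    required = sum(lens) + (n_gaps - 1) * min_segment + 2 * end_margin
    slack = len(reference) - required
    if slack < 0:
        raise GeometryError(
            f"reference of {len(reference)} bp cannot host {n_gaps} gaps "
            f"({required} bp required)"
        )
    extra = rng.multinomial(slack, [1.0 / (n_gaps + 1)] * (n_gaps + 1))
    truths: List[GapTruth] = []
    pos = end_margin + int(extra[0])
    for i, glen in enumerate(lens):
        truths.append(GapTruth(pos, pos + glen, reference[pos : pos + glen]))
        pos += glen + min_segment + int(extra[i + 1])

    pieces: List[str] = []
    prev = 0
    for t in truths:
        n_len = t.end - t.start
        if gap_length_jitter:
            n_len = max(1, n_len + int(rng.integers(-gap_length_jitter, gap_length_jitter + 1)))
        pieces.append(reference[prev : t.start])
        pieces.append("N" * n_len)
        prev = t.end
    pieces.append(reference[prev:])
    scaffold = SequenceRecord(id=scaffold_id, sequence="".join(pieces))
    if gap_length_jitter == 0 and len(scaffold.sequence) != len(reference):  # pragma: no cover
        raise AssertionError("scaffold length drifted from reference")
    return scaffold, truths


def mutate_sequence(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Apply per-base errors: substitution 60%, insertion 20%, deletion 20%."""
    if error_rate == 0.0:
        return seq
    out: List[str] = []
    for ch in seq:
        if rng.random() >= error_rate:
            out.append(ch)
            continue
        kind = rng.random()
        if kind < 0.6:  # substitute with one of the other three bases
            choices = [b for b in "ACGT" if b != ch]
            out.append(choices[int(rng.integers(3))])
        elif kind < 0.8:  # insert a random base after
            out.append(ch)
            out.append("ACGT"[int(rng.integers(4))])
        # else: deletion — emit nothing
    return "".join(out)


def simulate_spanning_reads(
    reference: str,
    truths: Sequence[GapTruth],
    flank_margin: int,
    error_rate: float,
    reads_per_gap: int,
    seed: Union[int, np.random.Generator],
    movie: str = "mSIM_000000_s1_p0",
    well_start: int = 1,
) -> List[SequenceRecord]:
    """For each gap, reads covering gap +/- ``flank_margin`` on the reference.

    Every other read is reverse-complemented.  Names are
    ``movie/well/0_len`` with a fresh well per read.
    """
    rng = _rng(seed)
    reads: List[SequenceRecord] = []
    well = well_start
    for t in truths:
        lo = max(0, t.start - flank_margin)
        hi = min(len(reference), t.end + flank_margin)
        for k in range(reads_per_gap):
            seq = mutate_sequence(reference[lo:hi], error_rate, rng)
            if k % 2 == 1:
                seq = reverse_complement(seq)
            name = f"{movie}/{well}/0_{len(seq)}"
            reads.append(SequenceRecord(id=name, sequence=seq))
            well += 1
    return reads


def simulate_dataset(config: SimConfig) -> SimTruth:
    """Generate a complete multi-scaffold fixture from one seed."""
    rng = np.random.default_rng(config.seed)
    truth = SimTruth()
    movie = f"mSIM{config.seed:06d}_s1_p0"
    well = 1
    for s in range(config.n_scaffolds):
        sid = f"scaffold_{s + 1}"
        reference = simulate_reference(config.ref_len, config.gc_fraction, rng)
        scaffold, gap_truths = make_gapped_scaffold(
            reference,
            config.n_gaps,
            config.gap_len_range,
            config.min_segment,
            rng,
            end_margin=config.end_margin,
            scaffold_id=sid,
            gap_length_jitter=config.gap_length_jitter,
        )
        reads = simulate_spanning_reads(
            reference,
            gap_truths,
            config.flank_margin,
            config.error_rate,
            config.reads_per_gap,
            rng,
            movie=movie,
            well_start=well,
        )
        well += len(reads)
        truth.references[sid] = reference
        truth.scaffolds.append(scaffold)
        truth.gap_truths[sid] = gap_truths
        truth.reads.extend(reads)
        truth.evidence.entries[sid] = [r.id for r in reads]
    return truth


def make_conflict_fixture(truth: SimTruth, seed: Union[int, np.random.Generator] = 0) -> SimTruth:
    """Add two same-well subreads, each spanning a different gap.

    Running the pipeline on the result must abort both implicated gaps.
    Requires at least two gaps across the fixture.
    """
    pairs = [
        (sid, t) for sid, ts in truth.gap_truths.items() for t in ts
    ]
    if len(pairs) < 2:
        raise ValueError("conflict fixture requires at least two gaps")
    (sid_a, gap_a), (sid_b, gap_b) = pairs[0], pairs[1]
    movie = "mCONFLICT_s1_p0"
    well = 999999
    margin = 400
    new_truth = SimTruth(
        references=dict(truth.references),
        scaffolds=list(truth.scaffolds),
        gap_truths={k: list(v) for k, v in truth.gap_truths.items()},
        reads=list(truth.reads),
        evidence=EvidenceMap(entries={k: list(v) for k, v in truth.evidence.entries.items()}),
    )
    offset = 0
    for sid, gap in ((sid_a, gap_a), (sid_b, gap_b)):
        ref = truth.references[sid]
        lo = max(0, gap.start - margin)
        hi = min(len(ref), gap.end + margin)
        seq = ref[lo:hi]
        name = f"{movie}/{well}/{offset}_{offset + len(seq)}"
        offset += len(seq)
        new_truth.reads.append(SequenceRecord(id=name, sequence=seq))
        # first in evidence order, so the conflicting pair anchors the gaps
        new_truth.evidence.entries.setdefault(sid, []).insert(0, name)
    return new_truth


def write_dataset(truth: SimTruth, out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Write the five fixture files; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out_dir / "reference.fasta",
        "scaffolds": out_dir / "scaffolds.fasta",
        "reads": out_dir / "reads.fasta",
        "evidence": out_dir / "evidence.tsv",
        "truth": out_dir / "truth.json",
    }
    write_fasta(
        [SequenceRecord(id=f"{sid}_ref", sequence=ref) for sid, ref in truth.references.items()],
        paths["reference"],
    )
    write_fasta(truth.scaffolds, paths["scaffolds"])
    write_fasta(truth.reads, paths["reads"])
    write_evidence_tsv(truth.evidence, paths["evidence"])
    payload = {
        sid: [{"start": t.start, "end": t.end, "sequence": t.sequence} for t in ts]
        for sid, ts in truth.gap_truths.items()
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    return paths
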