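import pytest

from flankfill import (
    ABORTED_CONFLICT,
    FILLED,
    REJECTED,
    FillDecision,
    GapInterval,
    ScoringParams,
    SequenceRecord,
    SimConfig,
    apply_fill,
    fill_scaffold,
    plan_fill,
    reverse_complement,
    run_pipeline,
    simulate_dataset,
)
from flankfill.fill import StaleDecisionError, read_report, write_report
from flankfill.seqio import EvidenceError, EvidenceMap
from flankfill.simulate import simulate_reference

# hand-sized fixtures need hand-sized thresholds
PARAMS = ScoringParams(min_raw_score=10, min_identity=0.8, min_aln_len=10, max_hits=1)
FLANK = 30
MINFLANK = 10


def build_case(rng_seed=11, gap_len=40, flank=120):
    """A scaffold with one gap plus the true gap sequence, built by hand."""
    ref = simulate_reference(400, seed=rng_seed)
    start, end = 180, 180 + gap_len
    scaffold = SequenceRecord(id="scf", sequence=ref[:start] + "N" * gap_len + ref[end:])
    truth = ref[start:end]
    gap = GapInterval("scf", start, end)
    return ref, scaffold, gap, truth


class TestPlanFill:
    def test_exact_spanning_read_fills(self):
        ref, scaffold, gap, truth = build_case()
        read = SequenceRecord(id="r1", sequence=ref[gap.start - 100 : gap.end + 100])
        d = plan_fill(scaffold, gap, read, PARAMS, flank_len=FLANK, min_flank_len=MINFLANK)
        assert d.status == FILLED
        assert d.replacement == truth
        assert d.left_trim == 0 and d.right_trim == 0

    def test_reverse_strand_read_fills_identically(self):
        ref, scaffold, gap, truth = build_case()
        read = SequenceRecord(
            id="r1", sequence=reverse_complement(ref[gap.start - 100 : gap.end + 100])
        )
        d = plan_fill(scaffold, gap, read, PARAMS, flank_len=FLANK, min_flank_len=MINFLANK)
        assert d.status == FILLED and d.replacement == truth

    def test_left_only_read_rejected(self):
        ref, scaffold, gap, truth = build_case()
        read = SequenceRecord(id="r1", sequence=ref[gap.start - 100 : gap.start])
        d = plan_fill(scaffold, gap, read, PARAMS, flank_len=FLANK, min_flank_len=MINFLANK)
        assert (d.status, d.reason) == (REJECTED, "no_right_anchor")

    def test_no_anchor_at_all(self):
        ref, scaffold, gap, truth = build_case()
        read = SequenceRecord(id="r1", sequence=simulate_reference(200, seed=99))
        d = plan_fill(scaffold, gap, read, PARAMS, flank_len=FLANK, min_flank_len=MINFLANK)
        assert (d.status, d.reason) == (REJECTED, "no_left_anchor")

    def test_opposite_strand_flanks_rejected(self):
        ref, scaffold, gap, truth = build_case()
        left = ref[gap.start - 60 : gap.start]
        right = ref[gap.end : gap.end + 60]
        chimera = left + truth + reverse_complement(right)
        d = plan_fill(
            scaffold, gap, SequenceRecord(id="r1", sequence=chimera),
            PARAMS, flank_len=FLANK, min_flank_len=MINFLANK,
        )
        assert (d.status, d.reason) == (REJECTED, "strand_mismatch")

    def test_disordered_anchors_rejected(self):
        ref, scaffold, gap, truth = build_case()
        left = ref[gap.start - 60 : gap.start]
        right = ref[gap.end : gap.end + 60]
        swapped = right + truth + left  # flanks out of order along the read
        d = plan_fill(
            scaffold, gap, SequenceRecord(id="r1", sequence=swapped),
            PARAMS, flank_len=FLANK, min_flank_len=MINFLANK,
        )
        assert (d.status, d.reason) == (REJECTED, "disordered_anchors")

    def test_excessive_trim_rejected(self):
        ref, scaffold, gap, truth = build_case()
        # read whose left anchor stops 20 bp short of the gap edge
        read_seq = ref[gap.start - 100 : gap.start - 20] + "GTCA" * 10 + truth[25:] + ref[gap.end : gap.end + 100]
        d = plan_fill(
            scaffold, gap, SequenceRecord(id="r1", sequence=read_seq),
            PARAMS, flank_len=FLANK, min_flank_len=MINFLANK, max_trim=10,
        )
        assert d.status == REJECTED
        assert d.reason in ("below_threshold", "no_left_anchor")

    def test_filled_requires_nonempty_replacement(self):
        with pytest.raises(ValueError):
            FillDecision(gap=GapInterval("s", 0, 3), read_id="r", status=FILLED, replacement="")


class TestApplyFill:
    def test_simple_splice(self):
        scf = SequenceRecord(id="s", sequence="AAAANNNTTTT")
        d = FillDecision(gap=GapInterval("s", 4, 7), read_id="r", status=FILLED, replacement="GGG")
        assert apply_fill(scf, d).sequence == "AAAAGGGTTTT"

    def test_trim_accounting(self):
        scf = SequenceRecord(id="s", sequence="AAAANNNTTTT")
        d = FillDecision(
            gap=GapInterval("s", 4, 7), read_id="r", status=FILLED,
            replacement="AGGG", left_trim=1,
        )
        out = apply_fill(scf, d)
        assert out.sequence == "AAAAGGGTTTT"
        # length accounting: delta = len(replacement) - gap_len - trims
        assert len(out.sequence) - len(scf.sequence) == len(d.replacement) - 3 - 1 - 0

    def test_shorter_replacement_shrinks_scaffold(self):
        scf = SequenceRecord(id="s", sequence="AAAANNNNNTTTT")
        d = FillDecision(gap=GapInterval("s", 4, 9), read_id="r", status=FILLED, replacement="GG")
        out = apply_fill(scf, d)
        assert out.sequence == "AAAAGGTTTT"
        assert "N" not in out.sequence

    def test_stale_decision_raises(self):
        scf = SequenceRecord(id="s", sequence="AAAACGGTTTT")  # gap already filled
        d = FillDecision(gap=GapInterval("s", 4, 7), read_id="r", status=FILLED, replacement="GGG")
        with pytest.raises(StaleDecisionError):
            apply_fill(scf, d)

    def test_non_filled_rejected(self):
        scf = SequenceRecord(id="s", sequence="AAAANNNTTTT")
        d = FillDecision(gap=GapInterval("s", 4, 7), read_id="r", status=REJECTED, reason="no_left_anchor")
        with pytest.raises(ValueError):
            apply_fill(scf, d)


def two_gap_case(seed=21):
    ref = simulate_reference(900, seed=seed)
    g1, g2 = (200, 240), (600, 660)
    seq = ref[: g1[0]] + "N" * 40 + ref[g1[1] : g2[0]] + "N" * 60 + ref[g2[1] :]
    scaffold = SequenceRecord(id="scf", sequence=seq)
    return ref, scaffold, g1, g2


class TestFillScaffold:
    def test_two_gaps_two_reads(self):
        ref, scaffold, g1, g2 = two_gap_case()
        reads = [
            SequenceRecord(id="mA/1/0_1", sequence=ref[g1[0] - 100 : g1[1] + 100]),
            SequenceRecord(id="mA/2/0_1", sequence=ref[g2[0] - 100 : g2[1] + 100]),
        ]
        out, report = fill_scaffold(scaffold, reads, PARAMS, flank_len=FLANK, min_flank_len=MINFLANK)
        assert out.sequence == ref
        assert report.gap_bp_after == 0 and report.gap_count_after == 0
        assert [d.status for d in report.decisions] == [FILLED, FILLED]
        assert report.reads_consumed == ["mA/1/0_1", "mA/2/0_1"]

    def test_single_use_one_read_spanning_both_gaps(self):
        ref, scaffold, g1, g2 = two_gap_case()
        spanning = SequenceRecord(id="mA/1/0_1", sequence=ref[g1[0] - 100 : g2[1] + 100])
        out, report = fill_scaffold(scaffold, [spanning], PARAMS, flank_len=FLANK, min_flank_len=MINFLANK)
        # exactly one gap (the first in coordinate order) is filled
        statuses = [d.status for d in report.decisions]
        assert statuses == [FILLED, REJECTED]
        assert report.decisions[0].gap.start == g1[0]
        assert report.reads_consumed == ["mA/1/0_1"]

    def test_later_read_fills_remaining_gap(self):
        ref, scaffold, g1, g2 = two_gap_case()
        reads = [
            SequenceRecord(id="mA/1/0_1", sequence=ref[g1[0] - 100 : g2[1] + 100]),
            SequenceRecord(id="mA/2/0_1", sequence=ref[g2[0] - 100 : g2[1] + 100]),
        ]
        out, report = fill_scaffold(scaffold, reads, PARAMS, flank_len=FLANK, min_flank_len=MINFLANK)
        assert out.sequence == ref
        assert [d.status for d in report.decisions] == [FILLED, FILLED]
        assert report.decisions[1].read_id == "mA/2/0_1"

    def test_empty_read_list_unchanged(self):
        _, scaffold, _, _ = two_gap_case()
        out, report = fill_scaffold(scaffold, [], PARAMS, flank_len=FLANK, min_flank_len=MINFLANK)
        assert out.sequence == scaffold.sequence
        assert [d.status for d in report.decisions] == [REJECTED, REJECTED]
        assert report.gap_bp_after == report.gap_bp_before

    def test_blocked_gap_reports_conflict(self):
        ref, scaffold, g1, g2 = two_gap_case()
        read = SequenceRecord(id="mA/1/0_1", sequence=ref[g1[0] - 100 : g1[1] + 100])
        out, report = fill_scaffold(
            scaffold, [read], PARAMS, flank_len=FLANK, min_flank_len=MINFLANK,
            blocked_gaps={("scf", g1[0], g1[1])},
        )
        assert report.decisions[0].status == ABORTED_CONFLICT
        assert report.decisions[0].reason == "conflict"
        assert "N" in out.sequence  # the blocked gap stays


class TestRunPipeline:
    def test_empty_evidence_identity(self, small_truth):
        out, report = run_pipeline(small_truth.scaffolds, small_truth.reads, EvidenceMap())
        assert out == small_truth.scaffolds
        assert report.summary_dict()["n_filled"] == 0

    def test_simulated_fixture_full_recovery(self, small_truth):
        out, report = run_pipeline(small_truth.scaffolds, small_truth.reads, small_truth.evidence)
        assert len(out) == len(small_truth.scaffolds)
        for rec in out:
            assert rec.sequence == small_truth.references[rec.id]
        s = report.summary_dict()
        assert s["n_filled"] == s["n_gaps"] and s["gap_bp_after"] == 0
        # every replacement is byte-identical to the simulator truth
        truths = {
            (sid, t.start, t.end): t.sequence
            for sid, ts in small_truth.gap_truths.items()
            for t in ts
        }
        for d in report.decisions:
            assert d.replacement == truths[d.gap.key()]

    def test_unknown_scaffold_in_evidence(self, small_truth):
        ev = EvidenceMap(entries={"nope": [small_truth.reads[0].id]})
        with pytest.raises(EvidenceError, match="unknown scaffold"):
            run_pipeline(small_truth.scaffolds, small_truth.reads, ev)

    def test_unknown_read_in_evidence(self, small_truth):
        ev = EvidenceMap(entries={small_truth.scaffolds[0].id: ["ghost_read"]})
        with pytest.raises(EvidenceError, match="unknown read"):
            run_pipeline(small_truth.scaffolds, small_truth.reads, ev)

    def test_structure_and_locality_invariants(self):
        truth = simulate_dataset(
            SimConfig(seed=33, n_scaffolds=2, n_gaps=2, error_rate=0.05, reads_per_gap=3)
        )
        out, report = run_pipeline(truth.scaffolds, truth.reads, truth.evidence)
        # structure preservation and order
        assert [r.id for r in out] == [s.id for s in truth.scaffolds]
        # monotonicity
        s = report.summary_dict()
        assert s["gap_bp_after"] <= s["gap_bp_before"]
        # single use
        filled_by = [d.read_id for d in report.decisions if d.status == FILLED]
        assert len(filled_by) == len(set(filled_by))
        # locality: bytes outside fill windows match the input scaffold
        for rec, scf in zip(out, truth.scaffolds):
            rep = report.scaffold_reports[rec.id]
            filled = sorted(
                (d for d in rep.decisions if d.status == FILLED), key=lambda d: d.gap.start
            )
            # walk both sequences segment by segment between fill windows
            pos_in, pos_out = 0, 0
            for d in filled:
                w_start = d.gap.start - d.left_trim
                seg = scf.sequence[pos_in:w_start]
                assert rec.sequence[pos_out : pos_out + len(seg)] == seg
                pos_out += len(seg) + len(d.replacement)
                pos_in = d.gap.end + d.right_trim
            assert rec.sequence[pos_out:] == scf.sequence[pos_in:]

    def test_parallel_matches_serial(self, small_truth, tmp_path):
        from flankfill import write_fasta

        out1, _ = run_pipeline(small_truth.scaffolds, small_truth.reads, small_truth.evidence, threads=1)
        out2, _ = run_pipeline(small_truth.scaffolds, small_truth.reads, small_truth.evidence, threads=2)
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(out1, p1)
        write_fasta(out2, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestReport:
    def test_write_and_read_round_trip(self, small_truth, tmp_path):
        _, report = run_pipeline(small_truth.scaffolds, small_truth.reads, small_truth.evidence)
        path = tmp_path / "report.tsv"
        write_report(report, path)
        rows = read_report(path)
        assert len(rows) == len(report.decisions)
        assert {r["status"] for r in rows} <= {FILLED, REJECTED, ABORTED_CONFLICT}
        n_filled = sum(1 for r in rows if r["status"] == FILLED)
        assert n_filled == report.summary_dict()["n_filled"]
        # 1-based inclusive intervals round-trip to the 0-based gaps
        starts = sorted(r["gap_start"] - 1 for r in rows)
        assert starts == sorted(d.gap.start for d in report.decisions)

    def test_report_header_mismatch(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("wrong\theader\n")
        with pytest.raises(ValueError):
            read_report(p)
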