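# flankfill

Flank-anchored N-gap filling for long-read scaffolds.

Scaffolding joins contigs with runs of `N` marking unknown sequence. When the
scaffolder tracked *which* long reads created each scaffold, those same reads
usually contain the missing sequence. `flankfill` closes such gaps under a
deliberately strict discipline:

- **Two-anchor rule** — a gap is filled only when the known sequence on each
  side of the gap (the *flanks*) has exactly one accepted local alignment
  against the read, both anchors on the same strand and in flank order along
  the read. The replacement is the read subsequence between the anchors.
- **Strict acceptance thresholds** — raw score ≥ 50, identity ≥ 80%,
  alignment length ≥ 100 columns, one best hit, by default (all
  configurable). Permissive BLAST-style defaults accept hits between highly
  dissimilar sequences and cause incorrect fills.
- **Single use per read** — a read is consumed by its first successful fill
  and attempts no further gaps.
- **Scaffold locality** — a read only ever touches the scaffold it is listed
  under in the evidence map.
- **Read-origin guard** — PacBio subreads sharing a `movie/well` come from
  one molecule. If same-well subreads anchor two different gaps, both fills
  are aborted and the conflict logged (it usually indicates a scaffolding
  error).

The pipeline is serial per scaffold: reads are tried in evidence order, each
applied fill immediately becomes the new draft, and gaps are re-scanned
before the next read. Output sequence count and order always equal the
input's.

## CLI

```bash
# fill gaps
flankfill fill --scaffolds scaffolds.fasta --reads reads.fasta \
    --evidence evidence.tsv --out final.fasta \
    --report report.tsv --summary summary.json [-t 4]

# assembly statistics (sequence count, total bp, N50, gap count/bp/%)
flankfill stats --in scaffolds.fasta [--compare final.fasta] [--json]

# self-contained ground-truth fixture
flankfill simulate --out-dir fixture/ --seed 1 [--n-gaps 3 --error-rate 0.05 ...]
```

Exit codes: `0` success (even if no gap was filled), `2` usage error,
`3` data error. Every `fill` run echoes its resolved configuration to
`<out>.config.json`. With `-t/--threads > 1` scaffolds are partitioned
across worker processes; the output is byte-identical to a single-threaded
run.

### Evidence map dialects

The evidence map states which reads the scaffolder associated with each
scaffold (e.g. the per-scaffold read tracking SSPACE-LongRead emits with
`-k 1`). Two dialects are accepted:

1. a **directory** of per-scaffold files named `<scaffold_id>.*`, each either
   a FASTA whose record ids are read ids or a plain list of read ids, one
   per line;
2. a headerless two-column **TSV**: `scaffold_id<TAB>read_id`.

Duplicate pairs are dropped (first wins). A read listed under two scaffolds
is kept under the first and the cross-listing logged.

### FASTA index sidecar

`flankfill.seqio.build_index`/`fetch_sequence` provide O(1)-seek record
fetching. `save_index` persists the index as `<fasta>.fxi`, a tab-separated
text file with a `#flankfill-index` header line and one row per record:
`id  header_offset  seq_start  seq_end  length` (byte offsets, bp length).

## Per-gap report

`--report` writes one TSV row per gap with its terminal decision:
`scaffold, gap_start, gap_end` (1-based inclusive), `status`
(`FILLED | REJECTED | ABORTED_CONFLICT`), `read_id`, `reason`,
`replacement_len`, `left_trim`, `right_trim`. Trims are the few unaligned
flank bases (≤ `--max-trim`, default 10) replaced along with the gap when an
anchor stops short of the gap edge.

## Simulator

`flankfill simulate` (or `flankfill.simulate.simulate_dataset`) builds a
random reference, a scaffold whose N-runs replace known reference windows,
gap-spanning reads with a configurable error model (substitution :
insertion : deletion at 6 : 2 : 2 of the per-base rate, half of the reads
reverse-complemented, PacBio-convention names), the evidence map, and the
ground truth — used by the recovery and strictness test suites.
`make_conflict_fixture` adds a same-well read pair spanning two different
gaps to exercise the origin guard.

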