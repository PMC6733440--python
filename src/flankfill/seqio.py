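"""FASTA I/O, random-access record fetching, and scaffold read-evidence maps.

The index/fetch pair emulates the classic ``fastaindex``/``fastafetch``
behaviour: a one-pass byte-offset scan, then O(1)-seek retrieval of single
records without re-reading the file.  The evidence map captures which long
reads a scaffolder associated with each scaffold; two dialects are accepted
(a directory of per-scaffold files, or a two-column TSV), documented in the
README.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

VALID_BASES = frozenset("ACGTN")
# IUPAC ambiguity codes (plus U) tolerated only under lenient=True, mapped to N.
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVU")

_INDEX_MAGIC = "#flankfill-index\t1"


class FastaError(ValueError):
    """Malformed or unusable FASTA input."""


class DuplicateIdError(FastaError):
    """The same record id occurs more than once in one FASTA file."""


class UnknownIdError(KeyError):
    """A requested record id is absent from an index."""


class EvidenceError(ValueError):
    """Missing or malformed read-evidence input."""


@dataclass
class SequenceRecord:
    """One identified DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FastaError(f"record id must be a non-empty token, got {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def clean_sequence(seq: str, *, lenient: bool = False, record_id: str = "?") -> str:
    """Uppercase *seq* and enforce the ACGTN alphabet.

    With ``lenient=True`` IUPAC ambiguity codes are silently mapped to N;
    anything else always raises :class:`FastaError`.
    """
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if not bad:
        return seq
    if lenient and bad <= IUPAC_AMBIGUOUS:
        table = str.maketrans({c: "N" for c in bad})
        return seq.translate(table)
    raise FastaError(
        f"record {record_id!r} contains illegal characters: {sorted(bad)} "
        "(use lenient=True to map IUPAC ambiguity codes to N)"
    )


def _split_header(header: str) -> Tuple[str, str]:
    parts = header.split(None, 1)
    if not parts:
        raise FastaError("empty FASTA header line")
    return parts[0], parts[1] if len(parts) > 1 else ""


def read_fasta(path: PathLike, *, lenient: bool = False) -> List[SequenceRecord]:
    """Parse a FASTA file into records, in file order.

    Sequences are uppercased and alphabet-checked; multi-line sequences are
    concatenated.  Raises :class:`FastaError` on an empty file, text before
    the first header, duplicate ids, or empty sequences.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: List[SequenceRecord] = []
    seen: set = set()
    header: Optional[str] = None
    chunks: List[str] = []

    def flush() -> None:
        if header is None:
            return
        rid, desc = _split_header(header)
        if rid in seen:
            raise DuplicateIdError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        seq = clean_sequence("".join(chunks), lenient=lenient, record_id=rid)
        if not seq:
            raise FastaError(f"record {rid!r} in {path} has an empty sequence")
        records.append(SequenceRecord(id=rid, sequence=seq, description=desc))

    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            else:
                if header is None:
                    raise FastaError(f"{path}: sequence data before first '>' header")
                chunks.append(line.strip())
    flush()
    if not records:
        raise FastaError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    """Write records as wrapped FASTA. ``width`` is the column wrap (>= 1)."""
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class IndexEntry:
    id: str
    header_offset: int  # byte offset of the '>' character
    seq_start: int      # byte offset of the first sequence byte
    seq_end: int        # byte offset one past the last sequence line (incl. newline)
    length: int         # sequence length in bp


@dataclass
class FastaIndex:
    """Byte-offset index over one FASTA file for O(1)-seek record fetching."""

    fasta_path: Path
    entries: Dict[str, IndexEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, rid: str) -> bool:
        return rid in self.entries

    def ids(self) -> List[str]:
        return list(self.entries)


def build_index(path: PathLike) -> FastaIndex:
    """Scan a FASTA file once and record byte offsets and lengths per id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    entries: Dict[str, IndexEntry] = {}
    offset = 0
    cur_id: Optional[str] = None
    cur_header = 0
    cur_start = 0
    cur_end = 0
    cur_len = 0

    def flush() -> None:
        nonlocal cur_id
        if cur_id is None:
            return
        if cur_id in entries:
            raise DuplicateIdError(f"duplicate record id {cur_id!r} in {path}")
        entries[cur_id] = IndexEntry(cur_id, cur_header, cur_start, cur_end, cur_len)
        cur_id = None

    with open(path, "rb") as fh:
        for raw in fh:
            if raw.startswith(b">"):
                flush()
                rid, _ = _split_header(raw[1:].strip().decode("utf-8"))
                cur_id = rid
                cur_header = offset
                cur_start = offset + len(raw)
                cur_end = cur_start
                cur_len = 0
            elif raw.strip():
                if cur_id is None:
                    raise FastaError(f"{path}: sequence data before first '>' header")
                cur_len += len(raw.strip())
                cur_end = offset + len(raw)
            offset += len(raw)
    flush()
    if not entries:
        raise FastaError(f"no records in FASTA file {path}")
    return FastaIndex(fasta_path=path, entries=entries)


def fetch_sequence(index: FastaIndex, rid: str, *, lenient: bool = False) -> SequenceRecord:
    """Fetch one record by id using byte seeks only (no full-file rescan)."""
    try:
        entry = index.entries[rid]
    except KeyError:
        near = difflib.get_close_matches(rid, index.entries.keys(), n=3)
        hint = f"; nearest ids: {near}" if near else ""
        raise UnknownIdError(f"id {rid!r} not in index of {index.fasta_path}{hint}") from None
    with open(index.fasta_path, "rb") as fh:
        fh.seek(entry.header_offset)
        header = fh.readline()[1:].strip().decode("utf-8")
        fh.seek(entry.seq_start)
        raw = fh.read(entry.seq_end - entry.seq_start)
    seq = "".join(raw.decode("utf-8").split())
    if len(seq) != entry.length:
        raise FastaError(
            f"index for {rid!r} is stale: expected {entry.length} bp, got {len(seq)}"
        )
    rid2, desc = _split_header(header)
    return SequenceRecord(id=rid2, sequence=clean_sequence(seq, lenient=lenient, record_id=rid2), description=desc)


def save_index(index: FastaIndex, path: Optional[PathLike] = None) -> Path:
    """Persist an index as a tab-separated sidecar (default ``<fasta>.fxi``)."""
    path = Path(path) if path is not None else Path(str(index.fasta_path) + ".fxi")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_INDEX_MAGIC + "\n")
        for e in index.entries.values():
            fh.write(f"{e.id}\t{e.header_offset}\t{e.seq_start}\t{e.seq_end}\t{e.length}\n")
    return path


def load_index(path: PathLike, fasta_path: Optional[PathLike] = None) -> FastaIndex:
    path = Path(path)
    fasta = Path(fasta_path) if fasta_path is not None else Path(str(path)[: -len(".fxi")])
    entries: Dict[str, IndexEntry] = {}
    with open(path, "r", encoding="utf-8") as fh:
        magic = fh.readline().rstrip("\n")
        if magic != _INDEX_MAGIC:
            raise FastaError(f"{path} is not a flankfill index sidecar")
        for line in fh:
            rid, ho, ss, se, ln = line.rstrip("\n").split("\t")
            entries[rid] = IndexEntry(rid, int(ho), int(ss), int(se), int(ln))
    return FastaIndex(fasta_path=fasta, entries=entries)


@dataclass
class EvidenceMap:
    """Ordered map scaffold id -> read ids associated by the scaffolder.

    ``cross_listed`` records reads that appeared under more than one
    scaffold: they are kept under the first scaffold only (first wins) and
    each extra listing is logged, since cross-listings hint at scaffolding
    errors.
    """

    entries: Dict[str, List[str]] = field(default_factory=dict)
    cross_listed: List[Tuple[str, str, str]] = field(default_factory=list)  # (read, kept_scaffold, dropped_scaffold)

    def __len__(self) -> int:
        return len(self.entries)

    def reads_for(self, scaffold_id: str) -> List[str]:
        return self.entries.get(scaffold_id, [])

    def all_read_ids(self) -> List[str]:
        out: List[str] = []
        for reads in self.entries.values():
            out.extend(reads)
        return out


def _evidence_pairs_from_dir(path: Path) -> Iterable[Tuple[str, str]]:
    files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise EvidenceError(f"evidence directory {path} contains no files")
    for f in files:
        scaffold_id = f.name.split(".", 1)[0]
        with open(f, "r", encoding="utf-8") as fh:
            text = fh.read()
        fasta_mode = text.lstrip().startswith(">")
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if fasta_mode:
                if line.startswith(">"):
                    yield scaffold_id, line[1:].split()[0]
            else:
                # plain-text dialect: one read id per line
                yield scaffold_id, line.split()[0]


def _evidence_pairs_from_tsv(path: Path) -> Iterable[Tuple[str, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2 or not cols[0] or not cols[1]:
                raise EvidenceError(
                    f"{path}:{lineno}: expected two tab-separated columns "
                    f"(scaffold_id, read_id), got {line!r}"
                )
            yield cols[0], cols[1]


def parse_evidence(path: PathLike) -> EvidenceMap:
    """Parse a read-evidence map from a directory or a two-column TSV.

    Duplicate (scaffold, read) pairs are deduplicated keeping the first; a
    read listed under two scaffolds is kept under the first scaffold and the
    cross-listing logged.
    """
    path = Path(path)
    if not path.exists():
        raise EvidenceError(
            f"evidence path not found: {path}. Gap filling requires the "
            "per-scaffold read evidence produced by the scaffolding step "
            "(e.g. SSPACE-LongRead run with -k 1, or an equivalent "
            "scaffold_id<TAB>read_id table)."
        )
    pairs = _evidence_pairs_from_dir(path) if path.is_dir() else _evidence_pairs_from_tsv(path)

    emap = EvidenceMap()
    owner: Dict[str, str] = {}
    for scaffold_id, read_id in pairs:
        bucket = emap.entries.setdefault(scaffold_id, [])
        if read_id in owner:
            if owner[read_id] == scaffold_id:
                logger.warning("duplicate evidence pair (%s, %s) ignored", scaffold_id, read_id)
            else:
                logger.warning(
                    "read %s listed under scaffolds %s and %s; keeping first "
                    "(possible scaffolding error)",
                    read_id, owner[read_id], scaffold_id,
                )
                emap.cross_listed.append((read_id, owner[read_id], scaffold_id))
            continue
        owner[read_id] = scaffold_id
        bucket.append(read_id)
    return emap


def write_evidence_tsv(emap: EvidenceMap, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for scaffold_id, reads in emap.entries.items():
            for rid in reads:
                fh.write(f"{scaffold_id}\t{rid}\n")
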