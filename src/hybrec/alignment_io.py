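"""Sequence/alignment input and per-long-read pileup construction.

Long reads are the alignment *targets*; short reads are queries placed on
them by an external aligner (consumed as SAM) or by the oracle aligner in
:mod:`hybrec.synthetic_data`.  A :class:`Pileup` tallies, for every original
long-read position, how often each short-read base covers it, how often a
short read skips it (deletion), and which insertion events are anchored
behind it.  Case encodes strand: uppercase counts come from forward-strand
alignments, lowercase from reverse-strand ones.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO

BASES_UPPER = "ATGC"
BASES_LOWER = "atgc"
BASE_KEYS = BASES_UPPER + BASES_LOWER

# CIGAR ops we can place on the target; pysam op codes 0..8 = MIDNSHP=X
_OP_CODE_TO_CHAR = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S", 5: "H", 7: "=", 8: "X"}
_SUPPORTED_OPS = frozenset("MIDNSH=X")
_QUERY_CONSUMING = frozenset("MIS=X")


class ParseError(ValueError):
    """Malformed input file."""


@dataclass
class ReadRecord:
    """A sequencing read: id, uppercase sequence, optional qualities."""

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: qualities/sequence length mismatch")


@dataclass
class AlignmentRecord:
    """One short read placed on a long read.

    ``query_sequence`` is stored exactly as the alignment record stores it,
    i.e. already reverse-complemented for reverse-strand placements (SAM
    convention).  ``cigar`` is a list of ``(op, length)`` with op one of
    M, =, X, I, D, S, H, N.
    """

    query_id: str
    target_id: str
    target_start: int
    strand: str  # "forward" | "reverse"
    cigar: list[tuple[str, int]]
    query_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.target_start < 0:
            raise ValueError(f"{self.query_id}: negative target_start")
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"{self.query_id}: bad strand {self.strand!r}")
        for op, length in self.cigar:
            if op not in _SUPPORTED_OPS:
                raise ValueError(f"{self.query_id}: unsupported CIGAR op {op!r}")
            if length < 1:
                raise ValueError(f"{self.query_id}: CIGAR length < 1")
        if self.query_sequence is not None:
            consumed = sum(n for op, n in self.cigar if op in _QUERY_CONSUMING)
            if consumed != len(self.query_sequence):
                raise ValueError(
                    f"{self.query_id}: CIGAR consumes {consumed} query bases, "
                    f"sequence has {len(self.query_sequence)}"
                )


@dataclass
class PileupColumn:
    """Counts at one original long-read position.

    Invariant: sum(base_counts) + deletion_count + n_count == coverage.
    ``n_count`` holds query N bases, which support coverage but no base field
    and do not raise the deletion flag.
    """

    base_counts: dict[str, int] = field(default_factory=lambda: {b: 0 for b in BASE_KEYS})
    deletion_count: int = 0
    n_count: int = 0
    coverage: int = 0


@dataclass
class InsertionEvent:
    """Query bases inserted behind original target position ``anchor``."""

    anchor: int
    inserted: str

    def __post_init__(self) -> None:
        if not self.inserted:
            raise ValueError("empty insertion")


@dataclass
class Pileup:
    """Columnar pileup of one long read.

    ``insertion_sites`` maps anchor -> list of per-offset base counters
    (case-sensitive keys as in PileupColumn.base_counts).  The number of
    alignments inserting at least k+1 bases at an anchor equals the total
    count at offset k.
    """

    target_id: str
    target_length: int
    columns: list[PileupColumn]
    insertion_sites: dict[int, list[dict[str, int]]] = field(default_factory=dict)

    def insertion_support(self, anchor: int, offset: int) -> int:
        """Number of alignments that insert >= offset+1 bases at this anchor."""
        site = self.insertion_sites[anchor]
        return sum(site[offset].values())

    def anchor_coverage(self, anchor: int) -> int:
        """Alignments covering an insertion anchor (virtual anchor -1 uses the
        insertion events themselves as support)."""
        if anchor < 0:
            return self.insertion_support(anchor, 0) if anchor in self.insertion_sites else 0
        return self.columns[anchor].coverage


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[ReadRecord]:
    """Read FASTA or FASTQ (plain or gzip), auto-detected by first character.

    Ids are taken up to the first whitespace and sequences are uppercased:
    input case is not meaningful here (strand is encoded later, from SAM
    flags, not from read files).
    """
    with _open_text(path) as handle:
        first = handle.read(1)
        if first == "":
            return []
        handle.seek(0)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise ParseError(f"{path}: not FASTA/FASTQ (starts with {first!r})")
        records = []
        try:
            for rec in SeqIO.parse(handle, fmt):
                quals = rec.letter_annotations.get("phred_quality")
                records.append(
                    ReadRecord(
                        id=rec.id,
                        sequence=str(rec.seq).upper(),
                        qualities=list(quals) if quals is not None else None,
                    )
                )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(path: str | Path, reads: Iterable[ReadRecord]) -> None:
    with open(path, "w") as out:
        for read in reads:
            out.write(f">{read.id}\n{read.sequence}\n")


def read_sam(
    path: str | Path,
    target_ids: Iterable[str],
    *,
    include_secondary: bool = False,
) -> list[AlignmentRecord]:
    """Load SAM/BAM records targeting the given long reads.

    Unmapped records, records whose target is not in ``target_ids`` and (by
    default) secondary/supplementary records are dropped.
    """
    wanted = set(target_ids)
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name not in wanted:
                continue
            if not include_secondary and (rec.is_secondary or rec.is_supplementary):
                continue
            cigar = []
            for code, length in rec.cigartuples or []:
                if code not in _OP_CODE_TO_CHAR:
                    raise ParseError(
                        f"{path}: record {rec.query_name}: unsupported CIGAR op code {code}"
                    )
                cigar.append((_OP_CODE_TO_CHAR[code], length))
            records.append(
                AlignmentRecord(
                    query_id=rec.query_name,
                    target_id=rec.reference_name,
                    target_start=rec.reference_start,
                    strand="reverse" if rec.is_reverse else "forward",
                    cigar=cigar,
                    query_sequence=rec.query_sequence,
                )
            )
    return records


def build_pileup(long_read: ReadRecord, alignments: Sequence[AlignmentRecord]) -> Pileup:
    """Walk each alignment's CIGAR and accumulate per-position counts.

    M/=/X place a query base on the target column (lowercased for
    reverse-strand alignments); D spans increment deletion_count and
    coverage; I records inserted bases behind the previous target position;
    S/H consume no target; N skips target without contributing coverage.
    """
    L = len(long_read.sequence)
    columns = [PileupColumn() for _ in range(L)]
    sites: dict[int, list[dict[str, int]]] = {}

    for aln in alignments:
        if aln.target_id != long_read.id:
            raise ValueError(
                f"alignment {aln.query_id} targets {aln.target_id}, not {long_read.id}"
            )
        lower = aln.strand == "reverse"
        query = aln.query_sequence
        qpos = 0
        tpos = aln.target_start
        for op, n in aln.cigar:
            if op in "M=X":
                if tpos + n > L:
                    raise ValueError(
                        f"alignment {aln.query_id} runs past end of {long_read.id}"
                    )
                for i in range(n):
                    col = columns[tpos + i]
                    col.coverage += 1
                    base = query[qpos + i].upper() if query else "N"
                    if base == "N":
                        col.n_count += 1
                    else:
                        col.base_counts[base.lower() if lower else base] += 1
                qpos += n
                tpos += n
            elif op == "D":
                if tpos + n > L:
                    raise ValueError(
                        f"alignment {aln.query_id} runs past end of {long_read.id}"
                    )
                for i in range(n):
                    columns[tpos + i].deletion_count += 1
                    columns[tpos + i].coverage += 1
                tpos += n
            elif op == "I":
                anchor = tpos - 1
                inserted = query[qpos : qpos + n] if query else "N" * n
                site = sites.setdefault(anchor, [])
                while len(site) < n:
                    site.append({b: 0 for b in BASE_KEYS})
                for k, base in enumerate(inserted):
                    b = base.upper()
                    if b == "N":
                        continue
                    site[k][b.lower() if lower else b] += 1
                qpos += n
            elif op == "S":
                qpos += n
            elif op == "N":
                tpos += n
            # H: consumes nothing

    return Pileup(
        target_id=long_read.id,
        target_length=L,
        columns=columns,
        insertion_sites=sites,
    )


def coverage_fraction(pileups: Sequence[Pileup]) -> float:
    """Fraction of original long-read positions covered by >= 1 short read."""
    total = sum(p.target_length for p in pileups)
    if total == 0:
        raise ValueError("no pileup columns")
    covered = sum(1 for p in pileups for col in p.columns if col.coverage > 0)
    return covered / total
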