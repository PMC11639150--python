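"""Synthetic genomes, reads, oracle alignments and the worked-example fixture.

The simulator provides everything the pipeline needs to run without an
external aligner: a uniform random genome, long reads with mixed
substitution/insertion/deletion errors at third-generation rates (~13%
PacBio-like, ~15% nanopore-like), accurate short reads at configurable
coverage, and *oracle* alignments whose CIGARs are derived exactly from the
recorded edit scripts rather than from heuristic alignment.  Error
placement is positionally independent and base composition uniform — the
minimum structure the correction method assumes; platform artefacts
(homopolymer bias, chimeras, quality correlation) are deliberately absent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignment_io import AlignmentRecord, ReadRecord

_ALPHABET = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ErrorProfile:
    """Per-base error probabilities (independent across positions)."""

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0

    def __post_init__(self) -> None:
        rates = (self.substitution_rate, self.insertion_rate, self.deletion_rate)
        if any(not 0 <= r < 1 for r in rates) or sum(rates) >= 1:
            raise ValueError("rates must lie in [0,1) and sum below 1")

    @property
    def total(self) -> float:
        return self.substitution_rate + self.insertion_rate + self.deletion_rate


# nanopore-like ~15% and PacBio-like ~13% totals; Illumina-like short reads
LONG_ONT = ErrorProfile(0.06, 0.05, 0.04)
LONG_PACBIO = ErrorProfile(0.05, 0.04, 0.04)
SHORT_DEFAULT = ErrorProfile(0.005, 0.0, 0.0)


@dataclass
class LongReadTruth:
    """Source interval and exact edit script of one simulated long read.

    ``ops`` replays the read from the reference byte-exactly:
    ("=", n) copy n bases, ("X", base) substitute one base,
    ("I", bases) insert bases, ("D", n) skip n reference bases.
    """

    start: int
    end: int
    ops: list[tuple[str, object]]


@dataclass
class ShortReadTruth:
    start: int
    end: int
    strand: str  # "forward" | "reverse"


@dataclass
class SimTruth:
    genome_length: int
    long: dict[str, LongReadTruth] = field(default_factory=dict)
    short: dict[str, ShortReadTruth] = field(default_factory=dict)


def replay(genome: str, truth: LongReadTruth) -> str:
    """Regenerate a read from its edit script (used as a self-check)."""
    out = []
    pos = truth.start
    for op, arg in truth.ops:
        if op == "=":
            out.append(genome[pos : pos + arg])
            pos += arg
        elif op == "X":
            out.append(arg)
            pos += 1
        elif op == "I":
            out.append(arg)
        elif op == "D":
            pos += arg
        else:
            raise ValueError(f"bad op {op}")
    assert pos == truth.end
    return "".join(out)


def simulate_genome(length: int, seed: int = 0) -> str:
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join(_ALPHABET[rng.integers(0, 4, size=length)])


def _mutate(
    genome: str, start: int, end: int, profile: ErrorProfile, rng: np.random.Generator
) -> tuple[str, list[tuple[str, object]]]:
    """Apply per-base errors over genome[start:end], recording the script."""
    ops: list[tuple[str, object]] = []
    seq: list[str] = []
    run = 0  # length of the current "=" run

    def flush() -> None:
        nonlocal run
        if run:
            ops.append(("=", run))
            run = 0

    for pos in range(start, end):
        if profile.insertion_rate and rng.random() < profile.insertion_rate:
            ins = "".join(_ALPHABET[rng.integers(0, 4, size=rng.geometric(0.7))])
            flush()
            ops.append(("I", ins))
            seq.append(ins)
        u = rng.random()
        if u < profile.deletion_rate:
            flush()
            if ops and ops[-1][0] == "D":
                ops[-1] = ("D", ops[-1][1] + 1)
            else:
                ops.append(("D", 1))
        elif u < profile.deletion_rate + profile.substitution_rate:
            orig = genome[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != orig]))
            flush()
            ops.append(("X", alt))
            seq.append(alt)
        else:
            run += 1
            seq.append(genome[pos])
    flush()
    return "".join(seq), ops


def simulate_long_reads(
    genome: str,
    n: int,
    mean_len: int,
    profile: ErrorProfile = LONG_ONT,
    seed: int = 0,
) -> tuple[list[ReadRecord], SimTruth]:
    """Long reads from uniform source intervals with per-base errors."""
    if mean_len > len(genome):
        raise ValueError("mean_len exceeds genome length")
    rng = np.random.default_rng(seed)
    truth = SimTruth(genome_length=len(genome))
    reads = []
    for i in range(n):
        length = int(np.clip(rng.normal(mean_len, 0.1 * mean_len), 50, len(genome)))
        start = int(rng.integers(0, len(genome) - length + 1))
        end = start + length
        seq, ops = _mutate(genome, start, end, profile, rng)
        rid = f"long_{i:05d}"
        if not seq:  # fully deleted (possible only at extreme rates)
            seq = genome[start:end]
            ops = [("=", length)]
        reads.append(ReadRecord(id=rid, sequence=seq))
        truth.long[rid] = LongReadTruth(start=start, end=end, ops=ops)
    return reads, truth


def simulate_short_reads(
    genome: str,
    coverage: float,
    read_len: int,
    profile: ErrorProfile = SHORT_DEFAULT,
    seed: int = 0,
) -> tuple[list[ReadRecord], SimTruth]:
    """Substitution-only short reads; about half reverse-complemented."""
    if read_len > len(genome):
        raise ValueError("read_len exceeds genome length")
    if profile.insertion_rate or profile.deletion_rate:
        raise ValueError("short-read profile must be substitution-only")
    rng = np.random.default_rng(seed)
    n = math.ceil(coverage * len(genome) / read_len)
    truth = SimTruth(genome_length=len(genome))
    reads = []
    for i in range(n):
        start = int(rng.integers(0, len(genome) - read_len + 1))
        end = start + read_len
        frag = list(genome[start:end])
        if profile.substitution_rate:
            hits = np.nonzero(rng.random(read_len) < profile.substitution_rate)[0]
            for j in hits:
                frag[j] = str(rng.choice([b for b in "ACGT" if b != frag[j]]))
        frag = "".join(frag)
        strand = "reverse" if rng.random() < 0.5 else "forward"
        seq = revcomp(frag) if strand == "reverse" else frag
        rid = f"short_{i:06d}"
        reads.append(ReadRecord(id=rid, sequence=seq))
        truth.short[rid] = ShortReadTruth(start=start, end=end, strand=strand)
    return reads, truth


def _long_coordinate_maps(truth: LongReadTruth):
    """Per-reference-position placement of one long read.

    Returns (ref_to_long, ins_before): ref_to_long[i] is the long-read
    coordinate carrying reference position i (None if deleted from the long
    read); ins_before[i] is the number of long-read bases inserted between
    reference positions i-1 and i.
    """
    ref_to_long: dict[int, int | None] = {}
    ins_before: dict[int, int] = {}
    lp = 0
    rp = truth.start
    for op, arg in truth.ops:
        if op == "=":
            for k in range(arg):
                ref_to_long[rp + k] = lp + k
            lp += arg
            rp += arg
        elif op == "X":
            ref_to_long[rp] = lp
            lp += 1
            rp += 1
        elif op == "I":
            ins_before[rp] = ins_before.get(rp, 0) + len(arg)
            lp += len(arg)
        elif op == "D":
            for k in range(arg):
                ref_to_long[rp + k] = None
            rp += arg
    return ref_to_long, ins_before


def oracle_alignments(
    long_reads: Sequence[ReadRecord],
    long_truth: SimTruth,
    short_reads: Sequence[ReadRecord],
    short_truth: SimTruth,
) -> list[AlignmentRecord]:
    """Exact short-to-long alignments composed from the two edit scripts.

    A short read is placed on every long read whose true source interval
    contains the short read's.  Since short reads carry substitutions only,
    reference position i holds short-read base i - start (on the aligned
    strand), and the CIGAR follows directly from the long read's own edit
    script: kept reference positions give M, long-read deletions give I
    (short-read base with no target base), long-read insertions between
    kept positions give D.
    """
    out: list[AlignmentRecord] = []
    shorts = [(sr, short_truth.short[sr.id]) for sr in short_reads]
    for lr in long_reads:
        lt = long_truth.long[lr.id]
        ref_to_long, ins_before = _long_coordinate_maps(lt)
        for sr, st in shorts:
            if st.start < lt.start or st.end > lt.end:
                continue
            aligned_query = revcomp(sr.sequence) if st.strand == "reverse" else sr.sequence
            cigar: list[tuple[str, int]] = []

            def emit(op: str, n: int = 1) -> None:
                if cigar and cigar[-1][0] == op:
                    cigar[-1] = (op, cigar[-1][1] + n)
                else:
                    cigar.append((op, n))

            target_start = None
            for i in range(st.start, st.end):
                if i > st.start and ins_before.get(i, 0) and target_start is not None:
                    emit("D", ins_before[i])
                if ref_to_long[i] is None:
                    emit("I")
                else:
                    if target_start is None:
                        target_start = ref_to_long[i]
                    emit("M")
            if target_start is None:
                continue  # span entirely deleted from the long read
            # trailing target-side bases beyond the last M are not part of
            # the alignment: drop a trailing D if the span ends inside one
            if cigar and cigar[-1][0] == "D":
                cigar.pop()
            out.append(
                AlignmentRecord(
                    query_id=sr.id,
                    target_id=lr.id,
                    target_start=target_start,
                    strand=st.strand,
                    cigar=cigar,
                    query_sequence=aligned_query,
                )
            )
    return out


# ---------------------------------------------------------------------------
# the worked-example fixture


def figure_fixture() -> tuple[ReadRecord, list[AlignmentRecord]]:
    """A 43-base long read with five fully concordant short-read alignments.

    Events (1-based original coordinates):
      * position 1 is C, matched by all five reads;
      * "T" inserted behind position 3 by all five (one reserved slot);
      * "GC" inserted behind position 10 by all five (two slots);
      * "GCC" inserted twice and "GC" three times behind position 15
        (three slots: G x5, C x5, then C x2 against 3 no-base rows);
      * the long read's "AA" at positions 28-29 is absent from all five
        reads (deletion evidence);
      * alignments span positions 1-31; position 43 (base A) is uncovered.
    """
    seq = (
        "CGA"  # 1-3   (pos 1 = C)
        "TGCATCG"  # 4-10
        "ATCGA"  # 11-15
        "TTGCGATCGTGC"  # 16-27
        "AA"  # 28-29 (deleted in all short reads)
        "GT"  # 30-31
        "CGATCGATCGT"  # 32-42
        "A"  # 43 (uncovered)
    )
    assert len(seq) == 43 and seq[0] == "C" and seq[27:29] == "AA" and seq[42] == "A"

    long_read = ReadRecord(id="fig_long", sequence=seq)
    alignments = []
    for i in range(5):
        ins3 = "GCC" if i < 2 else "GC"
        query = (
            seq[0:3] + "T" + seq[3:10] + "GC" + seq[10:15] + ins3 + seq[15:27] + seq[29:31]
        )
        cigar = [
            ("M", 3), ("I", 1), ("M", 7), ("I", 2), ("M", 5),
            ("I", len(ins3)), ("M", 12), ("D", 2), ("M", 2),
        ]
        alignments.append(
            AlignmentRecord(
                query_id=f"fig_short_{i}",
                target_id="fig_long",
                target_start=0,
                strand="forward",
                cigar=cigar,
                query_sequence=query,
            )
        )
    return long_read, alignments


# ---------------------------------------------------------------------------
# artifact writers (used by the CLI)


def write_fastq(path: str | Path, reads: Sequence[ReadRecord]) -> None:
    with open(path, "w") as out:
        for r in reads:
            out.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_oracle_sam(
    path: str | Path, long_reads: Sequence[ReadRecord], alignments: Sequence[AlignmentRecord]
) -> None:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r.id, "LN": len(r.sequence)} for r in long_reads],
    }
    tid = {r.id: i for i, r in enumerate(long_reads)}
    op_code = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "=": 7, "X": 8}
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for aln in alignments:
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = aln.query_id
            rec.query_sequence = aln.query_sequence
            rec.reference_id = tid[aln.target_id]
            rec.reference_start = aln.target_start
            rec.flag = 16 if aln.strand == "reverse" else 0
            rec.mapping_quality = 60
            rec.cigartuples = [(op_code[op], n) for op, n in aln.cigar]
            sam.write(rec)


def save_truth(path: str | Path, truth: SimTruth) -> None:
    data = {
        "genome_length": truth.genome_length,
        "long": {
            rid: {"start": t.start, "end": t.end, "ops": [[op, arg] for op, arg in t.ops]}
            for rid, t in truth.long.items()
        },
        "short": {
            rid: {"start": t.start, "end": t.end, "strand": t.strand}
            for rid, t in truth.short.items()
        },
    }
    Path(path).write_text(json.dumps(data))


def load_truth(path: str | Path) -> SimTruth:
    data = json.loads(Path(path).read_text())
    truth = SimTruth(genome_length=data["genome_length"])
    for rid, t in data["long"].items():
        truth.long[rid] = LongReadTruth(
            start=t["start"], end=t["end"], ops=[(op, arg) for op, arg in t["ops"]]
        )
    for rid, t in data["short"].items():
        truth.short[rid] = ShortReadTruth(start=t["start"], end=t["end"], strand=t["strand"])
    return truth
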