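"""Correction-quality metrics: identity, N50, genome fraction, min-max scaling.

At desk scale the reference interval of every simulated read is known, so
identity is computed from a global (Needleman-Wunsch, unit-cost) alignment
of each read against its true reference substring instead of whole-genome
mapping; the semantics — aligned bases over total bases — are the same.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np

from .alignment_io import ReadRecord
from .synthetic_data import SimTruth


@dataclass
class MetricReport:
    total_bases: int
    aligned_bases: int
    alignment_identity: float
    max_aligned_length: int
    mean_aligned_length: float
    n50: int
    genome_fraction: float


def n50(lengths: Sequence[int]) -> int:
    """Length of the read containing the midpoint of the sorted concatenation.

    Reads are sorted in descending length order (the assembly convention);
    the midpoint base is ceil(total/2).
    """
    if not lengths:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    midpoint = math.ceil(sum(ordered) / 2)
    running = 0
    for l in ordered:
        running += l
        if running >= midpoint:
            return l
    raise AssertionError("unreachable")


def identity_vs_truth(read_seq: str, true_seq: str) -> float:
    """1 - edit_distance / max(len) between a read and its true interval."""
    if not read_seq or not true_seq:
        raise ValueError("sequences must be non-empty")
    dist = edlib.align(read_seq, true_seq, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(read_seq), len(true_seq))


def genome_fraction(covered_intervals: Sequence[tuple[int, int]], genome_length: int) -> float:
    """Union length of [start, end) intervals over the genome length."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if not covered_intervals:
        return 0.0
    covered = 0
    cur_s = cur_e = None
    for s, e in sorted(covered_intervals):
        if not 0 <= s <= e <= genome_length:
            raise ValueError(f"interval ({s}, {e}) outside genome")
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / genome_length


def minmax_normalize(values: Sequence[float]) -> list[float]:
    """(x - min) / (max - min); undefined (error) when all values equal."""
    if len(values) < 2:
        raise ValueError("need at least two values")
    lo, hi = min(values), max(values)
    if hi == lo:
        raise ValueError("all values equal; min-max normalization undefined")
    return [(x - lo) / (hi - lo) for x in values]


def _report(reads: Sequence[ReadRecord], genome: str, truth: SimTruth) -> MetricReport:
    total = 0
    aligned = 0
    aligned_lengths = []
    intervals = []
    for read in reads:
        t = truth.long[read.id]
        ref = genome[t.start : t.end]
        total += len(read.sequence)
        ident = identity_vs_truth(read.sequence, ref)
        a = int(round(ident * len(read.sequence)))
        aligned += a
        aligned_lengths.append(a)
        intervals.append((t.start, t.end))
    return MetricReport(
        total_bases=total,
        aligned_bases=aligned,
        alignment_identity=aligned / total if total else 0.0,
        max_aligned_length=max(aligned_lengths) if aligned_lengths else 0,
        mean_aligned_length=float(np.mean(aligned_lengths)) if aligned_lengths else 0.0,
        n50=n50([len(r.sequence) for r in reads]),
        genome_fraction=genome_fraction(intervals, len(genome)),
    )


def evaluate_run(
    raw_reads: Sequence[ReadRecord],
    corrected_reads: Sequence[ReadRecord],
    genome: str,
    truth: SimTruth,
) -> dict:
    """Metric reports for raw and corrected reads plus per-metric deltas."""
    if [r.id for r in raw_reads] != [r.id for r in corrected_reads]:
        raise ValueError("raw and corrected read sets disagree")
    raw = _report(raw_reads, genome, truth)
    corrected = _report(corrected_reads, genome, truth)
    deltas = {
        key: getattr(corrected, key) - getattr(raw, key)
        for key in ("total_bases", "aligned_bases", "alignment_identity", "n50", "genome_fraction")
    }
    return {"raw": raw, "corrected": corrected, "deltas": deltas}
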