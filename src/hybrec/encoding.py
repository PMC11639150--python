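"""11-field feature vectors and majority-vote labels per absolute position.

Field order: counts of A, T, G, C (forward strand), a, t, g, c (reverse
strand), then three binary flags — "#" (a short read skips this position:
deletion evidence), "*" (ambiguous: more alignments show no base here than
show one), "SR" (short-read coverage present).  Labels live in
{A:0, T:1, G:2, C:3, *:4}; -1 is the PAD sentinel used only by windowing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .alignment_io import Pileup, ReadRecord
from .position_map import (
    INSERTED,
    ORIGINAL,
    AbsoluteColumn,
    AbsolutePositionMap,
    absolute_columns,
    build_absolute_map,
)

N_FIELDS = 11
FIELD_BASES = ("A", "T", "G", "C", "a", "t", "g", "c")
LABEL_OF_BASE = {"A": 0, "T": 1, "G": 2, "C": 3}
BASE_OF_LABEL = {0: "A", 1: "T", 2: "G", 3: "C"}
STAR = 4
PAD = -1

# tie-break precedence for majority vote (deterministic)
_PRECEDENCE = ("A", "T", "G", "C")


@dataclass
class EncodedRead:
    """Features, labels and the coordinate map for one long read."""

    read_id: str
    features: np.ndarray  # (absolute_length, 11) int32
    labels: np.ndarray  # (absolute_length,) int8
    map: AbsolutePositionMap
    original_sequence: str

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise AssertionError("feature/label length mismatch")
        if len(self.features) != self.map.absolute_length:
            raise AssertionError("encoding does not cover the absolute axis")

    @property
    def absolute_length(self) -> int:
        return len(self.labels)


def encode_position(column: AbsoluteColumn, original_base: str | None = None) -> np.ndarray:
    """Encode one absolute slot into the 11-field vector.

    Covered slots carry raw per-strand base counts; the "*" flag is raised
    when no-base evidence outweighs base evidence at the slot.  Uncovered
    original slots fall back to a one-hot of the long read's own base with
    SR=0 and "*"=1 (no correction signal, position flagged for the network).
    """
    vec = np.zeros(N_FIELDS, dtype=np.int32)
    covered = column.coverage > 0
    if not covered:
        if column.kind == ORIGINAL and original_base is None:
            raise ValueError("original slot requires the long-read base")
        if original_base is not None and original_base in LABEL_OF_BASE:
            vec[FIELD_BASES.index(original_base)] = 1
        vec[9] = 1  # ambiguous: no alignment information at all
        return vec
    base_support = 0
    for i, b in enumerate(FIELD_BASES):
        c = column.base_counts.get(b, 0)
        vec[i] = c
        base_support += c
    vec[8] = 1 if column.deletion_count > 0 else 0
    vec[9] = 1 if column.no_base > base_support else 0
    vec[10] = 1
    return vec


def _pooled_counts(column: AbsoluteColumn) -> dict[str, int]:
    return {
        b: column.base_counts.get(b, 0) + column.base_counts.get(b.lower(), 0)
        for b in _PRECEDENCE
    }


def label_position(column: AbsoluteColumn, original_base: str | None = None) -> int:
    """Majority-vote ground-truth label for one absolute slot.

    Strand case is pooled (labels are strand-free).  Ambiguous slots and
    slots where deletion evidence beats every base map to "*" so that the
    corrector can remove spurious long-read bases.  Uncovered slots keep the
    long read's own base.
    """
    if column.coverage == 0:
        if column.kind == ORIGINAL and original_base is None:
            raise ValueError("original slot requires the long-read base")
        return LABEL_OF_BASE.get(original_base, STAR) if original_base else STAR
    pooled = _pooled_counts(column)
    best = max(_PRECEDENCE, key=lambda b: (pooled[b], -_PRECEDENCE.index(b)))
    base_support = sum(pooled.values())
    if column.no_base > base_support:
        return STAR
    if column.deletion_count > pooled[best]:
        return STAR
    if pooled[best] == 0:
        return STAR
    return LABEL_OF_BASE[best]


def encode_read(
    pileup: Pileup,
    amap: AbsolutePositionMap | None,
    long_read: ReadRecord,
) -> EncodedRead:
    """Encode a whole long read: one (vector, label) pair per absolute slot."""
    if amap is None:
        amap = build_absolute_map(pileup)
    cols = absolute_columns(pileup, amap)
    features = np.zeros((len(cols), N_FIELDS), dtype=np.int32)
    labels = np.zeros(len(cols), dtype=np.int8)
    seq = long_read.sequence
    for i, col in enumerate(cols):
        base = seq[col.orig_index] if col.kind == ORIGINAL else None
        features[i] = encode_position(col, base)
        labels[i] = label_position(col, base)
    return EncodedRead(
        read_id=long_read.id,
        features=features,
        labels=labels,
        map=amap,
        original_sequence=seq,
    )


# ---------------------------------------------------------------------------
# chunked on-disk dataset (one HDF5 group per read)


def save_dataset(path: str | Path, encoded: Sequence[EncodedRead]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["n_reads"] = len(encoded)
        for i, er in enumerate(encoded):
            g = f.create_group(f"read_{i:06d}")
            g.attrs["read_id"] = er.read_id
            g.attrs["original_length"] = er.map.original_length
            g.attrs["original_sequence"] = er.original_sequence
            g.create_dataset("features", data=er.features, chunks=True)
            g.create_dataset("labels", data=er.labels, chunks=True)
            anchors = np.array(sorted(er.map.reserved), dtype=np.int64)
            g.create_dataset("anchors", data=anchors)
            g.create_dataset(
                "reserved", data=np.array([er.map.reserved[a] for a in anchors], dtype=np.int64)
            )


def _map_from_tables(
    target_id: str, original_length: int, anchors: np.ndarray, reserved: np.ndarray
) -> AbsolutePositionMap:
    from .position_map import build_absolute_map  # reuse the splicing logic

    fake = Pileup(
        target_id=target_id,
        target_length=original_length,
        columns=[],
        insertion_sites={
            int(a): [{} for _ in range(int(r))] for a, r in zip(anchors, reserved)
        },
    )
    return build_absolute_map(fake)


def load_dataset(path: str | Path) -> list[EncodedRead]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(k for k in f.keys() if k.startswith("read_")):
            g = f[key]
            amap = _map_from_tables(
                g.attrs["read_id"],
                int(g.attrs["original_length"]),
                g["anchors"][()],
                g["reserved"][()],
            )
            out.append(
                EncodedRead(
                    read_id=g.attrs["read_id"],
                    features=g["features"][()].astype(np.int32),
                    labels=g["labels"][()].astype(np.int8),
                    map=amap,
                    original_sequence=g.attrs["original_sequence"],
                )
            )
    return out
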