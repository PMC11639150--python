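"""Insertion-aware coordinate expansion.

A recurrent classifier needs one label per input vector, but short-read
insertions have no long-read coordinate of their own.  The fix is an
expanded "absolute" axis: for every insertion anchor, as many extra slots
are reserved as the longest insertion observed there, placed immediately
after the anchor's own slot.  Deletions do not move anything.  The map is
invertible, which is what lets corrected sequences be restored untrimmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment_io import BASE_KEYS, Pileup, PileupColumn

ORIGINAL = 0
INSERTED = 1


@dataclass
class AbsolutePositionMap:
    """Monotone map original index -> absolute index, plus slot bookkeeping.

    ``reserved`` maps an anchor (0-based original position, or -1 for
    insertions before the first base) to the number of slots reserved behind
    it.  ``slots`` tags every absolute index with ``(kind, index_or_anchor,
    offset)``: original slots carry their original index, inserted slots the
    anchor and 0-based offset within the reserved run.
    """

    target_id: str
    original_length: int
    reserved: dict[int, int]
    orig_to_abs: np.ndarray  # int64, len == original_length
    slots: list[tuple[int, int, int]]  # (kind, orig_index | anchor, offset)

    @property
    def absolute_length(self) -> int:
        return len(self.slots)


def build_absolute_map(pileup: Pileup) -> AbsolutePositionMap:
    """Reserve max-insertion-length slots behind every insertion anchor."""
    reserved = {anchor: len(site) for anchor, site in pileup.insertion_sites.items()}
    L = pileup.target_length
    slots: list[tuple[int, int, int]] = []
    orig_to_abs = np.empty(L, dtype=np.int64)
    if -1 in reserved:
        slots.extend((INSERTED, -1, k) for k in range(reserved[-1]))
    for p in range(L):
        orig_to_abs[p] = len(slots)
        slots.append((ORIGINAL, p, 0))
        if p in reserved:
            slots.extend((INSERTED, p, k) for k in range(reserved[p]))
    return AbsolutePositionMap(
        target_id=pileup.target_id,
        original_length=L,
        reserved=reserved,
        orig_to_abs=orig_to_abs,
        slots=slots,
    )


@dataclass
class AbsoluteColumn:
    """Counts attached to one absolute slot, ready for feature encoding.

    For inserted slots ``no_base`` counts alignments that cover the anchor
    but insert fewer bases than this slot's offset + 1 (the "N" rows of a
    padded insertion column); for original slots it is deletions + query-N.
    """

    kind: int
    base_counts: dict[str, int]
    deletion_count: int
    no_base: int
    coverage: int
    orig_index: int | None = None


def absolute_columns(pileup: Pileup, amap: AbsolutePositionMap) -> list[AbsoluteColumn]:
    """Materialize one column per absolute slot."""
    out: list[AbsoluteColumn] = []
    for kind, idx, offset in amap.slots:
        if kind == ORIGINAL:
            col: PileupColumn = pileup.columns[idx]
            out.append(
                AbsoluteColumn(
                    kind=ORIGINAL,
                    base_counts=dict(col.base_counts),
                    deletion_count=col.deletion_count,
                    no_base=col.deletion_count + col.n_count,
                    coverage=col.coverage,
                    orig_index=idx,
                )
            )
        else:
            counts = dict(pileup.insertion_sites[idx][offset])
            support = sum(counts.values())
            cov = pileup.anchor_coverage(idx)
            out.append(
                AbsoluteColumn(
                    kind=INSERTED,
                    base_counts=counts,
                    deletion_count=0,
                    no_base=max(cov - support, 0),
                    coverage=cov,
                    orig_index=None,
                )
            )
    return out
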