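"""Turn per-position class predictions back into untrimmed corrected reads.

The model predicts one of {A, T, G, C, *} for every absolute slot.  Base
predictions at original slots keep or substitute the long-read base; base
predictions at inserted slots add the base the short reads vouch for; "*"
omits the slot — deleting a spurious long-read base or suppressing a
candidate insertion.  Reads without any short-read coverage are emitted
unchanged: no read is ever trimmed, split or dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .alignment_io import Pileup, ReadRecord
from .encoding import BASE_OF_LABEL, PAD, STAR, EncodedRead, encode_read
from .model import predict_probs
from .position_map import ORIGINAL, AbsolutePositionMap
from .windowing import SplitConfig, segment

logger = logging.getLogger(__name__)


@dataclass
class Provenance:
    kept: int = 0
    substituted: int = 0
    inserted: int = 0
    removed: int = 0  # "*" at original slots (base deleted)
    suppressed: int = 0  # "*" at inserted slots (insertion not made)

    @property
    def total(self) -> int:
        return self.kept + self.substituted + self.inserted + self.removed + self.suppressed


@dataclass
class CorrectedRead:
    id: str
    sequence: str
    corrected: bool
    provenance: Provenance | None = None


def predict_labels(
    params: Mapping[str, np.ndarray],
    encoded: EncodedRead,
    cfg: SplitConfig | None = None,
    batch_size: int = 16,
) -> np.ndarray:
    """Predict a label for every absolute position of one read.

    Windows are predicted independently; each non-first window's leading
    seam (the overlap re-predicted by its predecessor) and all PAD tails
    are discarded, so the stitched result has exactly absolute_length
    labels.
    """
    cfg = cfg or SplitConfig()
    if encoded.features.shape[1] != params["f_Wxz"].shape[0]:
        raise ValueError("model input width does not match feature width")
    windows = segment(encoded, cfg)
    parts: list[np.ndarray] = []
    for lo in range(0, len(windows), batch_size):
        chunk = windows[lo : lo + batch_size]
        X = np.stack([w.features.astype(np.float64) for w in chunk])
        preds = predict_probs(params, X).argmax(axis=-1)
        for w, row in zip(chunk, preds):
            start = 0 if w.is_first else cfg.overlap
            end = cfg.window - w.pad_len
            parts.append(row[start:end])
    out = np.concatenate(parts)
    assert len(out) == encoded.absolute_length
    return out.astype(np.int8)


def restore_sequence(labels: Sequence[int], amap: AbsolutePositionMap) -> str:
    """Concatenate predicted bases; "*" slots contribute nothing."""
    labels = np.asarray(labels)
    if len(labels) != amap.absolute_length:
        raise ValueError("label sequence does not cover the absolute axis")
    bases = [BASE_OF_LABEL[int(l)] for l in labels if int(l) in BASE_OF_LABEL]
    if not bases:
        logger.warning("%s: every position predicted '*'; empty corrected sequence", amap.target_id)
    return "".join(bases)


def tally_provenance(
    labels: Sequence[int], amap: AbsolutePositionMap, original_sequence: str
) -> Provenance:
    prov = Provenance()
    for label, (kind, idx, _) in zip(labels, amap.slots):
        label = int(label)
        if kind == ORIGINAL:
            if label == STAR:
                prov.removed += 1
            elif BASE_OF_LABEL[label] == original_sequence[idx]:
                prov.kept += 1
            else:
                prov.substituted += 1
        else:
            if label == STAR:
                prov.suppressed += 1
            else:
                prov.inserted += 1
    return prov


def correct_reads(
    params: Mapping[str, np.ndarray],
    long_reads: Sequence[ReadRecord],
    pileups: Mapping[str, Pileup],
    cfg: SplitConfig | None = None,
) -> list[CorrectedRead]:
    """Correct every read; zero-coverage reads pass through unchanged."""
    cfg = cfg or SplitConfig()
    out: list[CorrectedRead] = []
    for read in long_reads:
        if read.id not in pileups:
            raise KeyError(f"no pileup for read {read.id}")
        pileup = pileups[read.id]
        if all(col.coverage == 0 for col in pileup.columns):
            out.append(CorrectedRead(id=read.id, sequence=read.sequence, corrected=False))
            continue
        encoded = encode_read(pileup, None, read)
        labels = predict_labels(params, encoded, cfg)
        seq = restore_sequence(labels, encoded.map)
        prov = tally_provenance(labels, encoded.map, read.sequence)
        logger.info(
            "%s: kept=%d substituted=%d inserted=%d removed=%d suppressed=%d",
            read.id, prov.kept, prov.substituted, prov.inserted, prov.removed, prov.suppressed,
        )
        out.append(CorrectedRead(id=read.id, sequence=seq, corrected=True, provenance=prov))
    return out


def write_corrected_fasta(path, corrected: Sequence[CorrectedRead]) -> None:
    """FASTA output; headers tag corrected vs. passed-through reads."""
    with open(path, "w") as out:
        for rec in corrected:
            tag = "corrected" if rec.corrected else "uncorrected"
            seq = rec.sequence if rec.sequence else "N"
            out.write(f">{rec.id} {tag}\n{seq}\n")
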