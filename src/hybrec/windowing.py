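"""Overlapping fixed-length windows and streamed batches.

Encoded reads are cut into 1,000-position windows that share a 200-position
seam with their predecessor, so the recurrent model never sees a cold cut
except at read boundaries.  Within every window the first 80% of positions
are training positions, the next 10% validation and the last 10% test —
the split is positional, not per-window, to keep local sequence context in
every role.  Batches are streamed from the on-disk dataset; the full
feature matrix of a run is never resident in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np

from .encoding import N_FIELDS, PAD, EncodedRead

ROLES = ("train", "val", "test")


@dataclass
class SplitConfig:
    window: int = 1000
    overlap: int = 200
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.window:
            raise ValueError("overlap must be < window")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def stride(self) -> int:
        return self.window - self.overlap

    def role_bounds(self, role: str) -> tuple[int, int]:
        """Positional [start, end) range of a role inside a window."""
        edges = np.cumsum((0.0,) + self.fractions) * self.window
        idx = ROLES.index(role)
        return int(round(edges[idx])), int(round(edges[idx + 1]))


@dataclass
class Window:
    read_id: str
    start_abs: int
    features: np.ndarray  # (window, 11)
    labels: np.ndarray  # (window,), PAD = -1 on the padded tail
    is_first: bool
    pad_len: int


def window_starts(absolute_length: int, cfg: SplitConfig) -> list[int]:
    """Start offsets of the windows covering [0, absolute_length).

    Window k starts at k*stride; windows are added until one ends at or past
    the sequence end, so every position lands in exactly one kept region.
    """
    starts = [0]
    while starts[-1] + cfg.window < absolute_length:
        starts.append(starts[-1] + cfg.stride)
    return starts


def segment(encoded: EncodedRead, cfg: SplitConfig | None = None) -> list[Window]:
    """Cut one encoded read into overlapping, zero/PAD-padded windows."""
    cfg = cfg or SplitConfig()
    L = encoded.absolute_length
    windows = []
    for k, start in enumerate(window_starts(L, cfg)):
        feats = np.zeros((cfg.window, N_FIELDS), dtype=encoded.features.dtype)
        labels = np.full(cfg.window, PAD, dtype=np.int8)
        n = min(cfg.window, L - start)
        feats[:n] = encoded.features[start : start + n]
        labels[:n] = encoded.labels[start : start + n]
        windows.append(
            Window(
                read_id=encoded.read_id,
                start_abs=start,
                features=feats,
                labels=labels,
                is_first=(k == 0),
                pad_len=cfg.window - n,
            )
        )
    return windows


def stitch(windows: Sequence[Window], cfg: SplitConfig | None = None) -> np.ndarray:
    """Invert :func:`segment` for any per-position array shaped like labels.

    Drops each non-first window's leading seam and every window's PAD tail;
    the concatenation reproduces the encoded read's axis exactly.
    """
    cfg = cfg or SplitConfig()
    parts = []
    for w in windows:
        lo = 0 if w.is_first else cfg.overlap
        hi = cfg.window - w.pad_len
        parts.append(w.labels[lo:hi])
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.int8)


def split_window(
    w: Window, cfg: SplitConfig | None = None
) -> tuple[tuple[np.ndarray, np.ndarray], ...]:
    """(train, validation, test) slices of one window, PAD excluded."""
    cfg = cfg or SplitConfig()
    out = []
    valid_end = cfg.window - w.pad_len
    for role in ROLES:
        lo, hi = cfg.role_bounds(role)
        hi = min(hi, valid_end)
        lo = min(lo, valid_end)
        out.append((w.features[lo:hi], w.labels[lo:hi]))
    return tuple(out)


def mask_labels_for_role(labels: np.ndarray, role: str, cfg: SplitConfig) -> np.ndarray:
    """PAD-mask every position outside the role's positional range."""
    lo, hi = cfg.role_bounds(role)
    masked = np.full_like(labels, PAD)
    masked[lo:hi] = labels[lo:hi]
    return masked


def _window_index(path: str | Path, cfg: SplitConfig) -> list[tuple[str, int]]:
    index = []
    with h5py.File(path, "r") as f:
        for key in sorted(k for k in f.keys() if k.startswith("read_")):
            L = f[key]["labels"].shape[0]
            index.extend((key, s) for s in window_starts(L, cfg))
    return index


def batch_stream(
    dataset_path: str | Path,
    role: str,
    batch_size: int,
    seed: int = 0,
    cfg: SplitConfig | None = None,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (batch, window, 11) features and (batch, window) labels.

    Labels outside the role's positional range (and PAD tails) are -1 and
    must be excluded from loss/metrics.  Train order is shuffled with the
    seed; val/test preserve on-disk order.  Only one batch plus one read's
    encoding are held in memory at a time.
    """
    if role not in ROLES:
        raise ValueError(f"role must be one of {ROLES}")
    cfg = cfg or SplitConfig()
    path = Path(dataset_path)
    if not path.exists():
        raise FileNotFoundError(path)
    index = _window_index(path, cfg)
    order = np.arange(len(index))
    if role == "train":
        np.random.default_rng(seed).shuffle(order)

    with h5py.File(path, "r") as f:
        cached_key: str | None = None
        cached: tuple[np.ndarray, np.ndarray] | None = None

        def load_window(i: int) -> tuple[np.ndarray, np.ndarray]:
            nonlocal cached_key, cached
            key, start = index[i]
            if key != cached_key:
                cached = (f[key]["features"][()], f[key]["labels"][()])
                cached_key = key
            feats_all, labels_all = cached
            L = labels_all.shape[0]
            n = min(cfg.window, L - start)
            feats = np.zeros((cfg.window, N_FIELDS), dtype=np.float64)
            labels = np.full(cfg.window, PAD, dtype=np.int64)
            feats[:n] = feats_all[start : start + n]
            labels[:n] = labels_all[start : start + n]
            return feats, mask_labels_for_role(labels, role, cfg)

        for lo in range(0, len(order), batch_size):
            chunk = order[lo : lo + batch_size]
            pairs = [load_window(int(i)) for i in chunk]
            yield (
                np.stack([p[0] for p in pairs]),
                np.stack([p[1] for p in pairs]),
            )
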