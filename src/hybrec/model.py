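"""Bidirectional GRU sequence classifier, written directly in NumPy.

Per direction and time step, with input x_t and previous hidden state h:

    Z_t = sigmoid(x_t W_xz + h W_hz + b_z)          (update gate)
    R_t = sigmoid(x_t W_xr + h W_hr + b_r)          (reset gate)
    Hc_t = tanh(x_t W_xh + (R_t * h) W_hh + b_h)    (candidate state)
    H_t = Z_t * h + (1 - Z_t) * Hc_t

The forward and backward hidden states are concatenated per position and
fed through a dense softmax layer with 5 outputs (A, T, G, C, *).  Training
is cross-entropy + Adam with hand-derived backpropagation through time;
PAD labels (-1) are excluded from loss and metrics.  Gradients are verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .encoding import PAD
from .windowing import SplitConfig, batch_stream

N_CLASSES = 5
N_FEATURES = 11

_DIR_KEYS = ("Wxz", "Wxr", "Wxh", "Whz", "Whr", "Whh", "bz", "br", "bh")


@dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults follow the method's published settings: Adam at learning rate
    1e-3, at most 200 epochs, early stopping when the training loss has not
    improved for 5 consecutive epochs, 128 hidden units per direction.
    """

    hidden: int = 128
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 5
    batch_size: int = 32
    seed: int = 0
    monitor: str = "train_loss"  # or "val_loss"

    def __post_init__(self) -> None:
        if self.patience < 1 or self.max_epochs < 1:
            raise ValueError("patience and max_epochs must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    @property
    def epochs(self) -> int:
        return len(self.train_loss)


def init_params(d: int = N_FEATURES, h: int = 128, v: int = N_CLASSES, seed: int = 0) -> dict[str, np.ndarray]:
    """Glorot-uniform weights, zero biases, deterministic given the seed."""
    if min(d, h, v) < 1:
        raise ValueError("d, h, v must be >= 1")
    rng = np.random.default_rng(seed)

    def glorot(n_in: int, n_out: int) -> np.ndarray:
        lim = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-lim, lim, size=(n_in, n_out))

    params: dict[str, np.ndarray] = {}
    for prefix in ("f", "b"):
        params[f"{prefix}_Wxz"] = glorot(d, h)
        params[f"{prefix}_Wxr"] = glorot(d, h)
        params[f"{prefix}_Wxh"] = glorot(d, h)
        params[f"{prefix}_Whz"] = glorot(h, h)
        params[f"{prefix}_Whr"] = glorot(h, h)
        params[f"{prefix}_Whh"] = glorot(h, h)
        params[f"{prefix}_bz"] = np.zeros(h)
        params[f"{prefix}_br"] = np.zeros(h)
        params[f"{prefix}_bh"] = np.zeros(h)
    params["Wyh"] = glorot(2 * h, v)
    params["by"] = np.zeros(v)
    return params


def direction_view(params: Mapping[str, np.ndarray], direction: str) -> dict[str, np.ndarray]:
    """Unprefixed view of one direction's tensors ('f' or 'b')."""
    return {k: params[f"{direction}_{k}"] for k in _DIR_KEYS}


def hidden_size(params: Mapping[str, np.ndarray]) -> int:
    return params["f_Whz"].shape[0]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def gru_step(
    p: Mapping[str, np.ndarray], x_t: np.ndarray, h_prev: np.ndarray
) -> np.ndarray:
    """One GRU update; accepts a single direction's unprefixed parameters."""
    if x_t.shape[-1] != p["Wxz"].shape[0] or h_prev.shape[-1] != p["Whz"].shape[0]:
        raise ValueError("gru_step: input/state dimension mismatch")
    z = _sigmoid(x_t @ p["Wxz"] + h_prev @ p["Whz"] + p["bz"])
    r = _sigmoid(x_t @ p["Wxr"] + h_prev @ p["Whr"] + p["br"])
    hc = np.tanh(x_t @ p["Wxh"] + (r * h_prev) @ p["Whh"] + p["bh"])
    return z * h_prev + (1.0 - z) * hc


def _gru_pass(
    p: Mapping[str, np.ndarray], X: np.ndarray, reverse: bool, want_cache: bool
):
    """Run one direction over X (B, T, d) from a zero initial state."""
    B, T, _ = X.shape
    H = p["Whz"].shape[0]
    hidden = np.zeros((B, T, H))
    cache = [] if want_cache else None
    h_prev = np.zeros((B, H))
    steps = range(T - 1, -1, -1) if reverse else range(T)
    for t in steps:
        x_t = X[:, t, :]
        z = _sigmoid(x_t @ p["Wxz"] + h_prev @ p["Whz"] + p["bz"])
        r = _sigmoid(x_t @ p["Wxr"] + h_prev @ p["Whr"] + p["br"])
        hc = np.tanh(x_t @ p["Wxh"] + (r * h_prev) @ p["Whh"] + p["bh"])
        h_t = z * h_prev + (1.0 - z) * hc
        hidden[:, t, :] = h_t
        if want_cache:
            cache.append((t, x_t, h_prev, z, r, hc))
        h_prev = h_t
    return hidden, cache


def bigru_forward(params: Mapping[str, np.ndarray], X: np.ndarray) -> np.ndarray:
    """Hidden states of both directions, concatenated per position.

    Accepts (T, d) or (B, T, d); returns (T, 2h) or (B, T, 2h).
    """
    squeeze = X.ndim == 2
    if squeeze:
        X = X[None]
    hf, _ = _gru_pass(direction_view(params, "f"), X, reverse=False, want_cache=False)
    hb, _ = _gru_pass(direction_view(params, "b"), X, reverse=True, want_cache=False)
    out = np.concatenate([hf, hb], axis=-1)
    return out[0] if squeeze else out


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def predict_probs(params: Mapping[str, np.ndarray], X: np.ndarray) -> np.ndarray:
    """Per-position class probabilities; rows sum to 1."""
    hidden = bigru_forward(params, X)
    return softmax(hidden @ params["Wyh"] + params["by"])


def loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy over non-PAD positions."""
    labels = np.asarray(labels)
    mask = labels != PAD
    n = int(mask.sum())
    if n == 0:
        raise ValueError("all positions are PAD")
    p = probs[mask, labels[mask]]
    return float(-np.log(np.clip(p, 1e-300, None)).mean())


def accuracy(probs: np.ndarray, labels: np.ndarray) -> float:
    labels = np.asarray(labels)
    mask = labels != PAD
    if not mask.any():
        return float("nan")
    return float((probs.argmax(axis=-1)[mask] == labels[mask]).mean())


def loss_and_grads(
    params: Mapping[str, np.ndarray],
    X: np.ndarray,
    labels: np.ndarray,
    return_probs: bool = False,
):
    """Cross-entropy loss and analytic gradients (BPTT, both directions).

    X is (B, T, d), labels (B, T) with PAD = -1 masked out of the loss.
    """
    if X.ndim == 2:
        X = X[None]
        labels = np.asarray(labels)[None]
    B, T, d = X.shape
    H = hidden_size(params)

    pf = direction_view(params, "f")
    pb = direction_view(params, "b")
    hf, cache_f = _gru_pass(pf, X, reverse=False, want_cache=True)
    hb, cache_b = _gru_pass(pb, X, reverse=True, want_cache=True)
    hidden = np.concatenate([hf, hb], axis=-1)  # (B, T, 2H)

    logits = hidden @ params["Wyh"] + params["by"]
    probs = softmax(logits)

    labels = np.asarray(labels)
    mask = labels != PAD
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise ValueError("all positions are PAD")
    idx = np.where(mask)
    loss_val = float(-np.log(np.clip(probs[idx[0], idx[1], labels[mask]], 1e-300, None)).mean())

    dlogits = probs.copy()
    dlogits[idx[0], idx[1], labels[mask]] -= 1.0
    dlogits[~mask] = 0.0
    dlogits /= n_valid

    grads: dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in params.items()}
    flat_hidden = hidden.reshape(-1, 2 * H)
    flat_dlogits = dlogits.reshape(-1, params["by"].shape[0])
    grads["Wyh"] = flat_hidden.T @ flat_dlogits
    grads["by"] = flat_dlogits.sum(axis=0)
    dhidden = dlogits @ params["Wyh"].T  # (B, T, 2H)

    _bptt(pf, cache_f, dhidden[:, :, :H], grads, "f")
    _bptt(pb, cache_b, dhidden[:, :, H:], grads, "b")
    if return_probs:
        return loss_val, grads, probs
    return loss_val, grads


def _bptt(
    p: Mapping[str, np.ndarray],
    cache: list,
    dhidden: np.ndarray,
    grads: dict[str, np.ndarray],
    prefix: str,
) -> None:
    """Backpropagate one direction; cache is in processing order."""
    H = p["Whz"].shape[0]
    B = dhidden.shape[0]
    dh_next = np.zeros((B, H))  # gradient flowing into h_t from later steps
    for t, x_t, h_prev, z, r, hc in reversed(cache):
        dh = dhidden[:, t, :] + dh_next
        dz = dh * (h_prev - hc)
        dhc = dh * (1.0 - z)
        dh_prev = dh * z

        da_h = dhc * (1.0 - hc * hc)
        grads[f"{prefix}_Wxh"] += x_t.T @ da_h
        grads[f"{prefix}_bh"] += da_h.sum(axis=0)
        grads[f"{prefix}_Whh"] += (r * h_prev).T @ da_h
        drh = da_h @ p["Whh"].T
        dr = drh * h_prev
        dh_prev += drh * r

        da_z = dz * z * (1.0 - z)
        grads[f"{prefix}_Wxz"] += x_t.T @ da_z
        grads[f"{prefix}_Whz"] += h_prev.T @ da_z
        grads[f"{prefix}_bz"] += da_z.sum(axis=0)
        dh_prev += da_z @ p["Whz"].T

        da_r = dr * r * (1.0 - r)
        grads[f"{prefix}_Wxr"] += x_t.T @ da_r
        grads[f"{prefix}_Whr"] += h_prev.T @ da_r
        grads[f"{prefix}_br"] += da_r.sum(axis=0)
        dh_prev += da_r @ p["Whr"].T

        dh_next = dh_prev


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: Mapping[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _iter_batches(dataset, role: str, cfg: TrainConfig, split: SplitConfig, epoch_seed: int):
    """Dataset may be an HDF5 path or an in-memory Window sequence."""
    if isinstance(dataset, (str, Path)):
        yield from batch_stream(dataset, role, cfg.batch_size, seed=epoch_seed, cfg=split)
        return
    # in-memory windows
    from .windowing import mask_labels_for_role

    windows = list(dataset)
    order = np.arange(len(windows))
    if role == "train":
        np.random.default_rng(epoch_seed).shuffle(order)
    for lo in range(0, len(order), cfg.batch_size):
        chunk = [windows[i] for i in order[lo : lo + cfg.batch_size]]
        yield (
            np.stack([w.features.astype(np.float64) for w in chunk]),
            np.stack([mask_labels_for_role(w.labels.astype(np.int64), role, split) for w in chunk]),
        )


def train(
    dataset,
    cfg: TrainConfig | None = None,
    split: SplitConfig | None = None,
) -> tuple[dict[str, np.ndarray], TrainHistory]:
    """Train on the dataset's train positions with early stopping.

    ``dataset`` is either a path to an HDF5 dataset or a sequence of
    in-memory windows.  Returns the parameters from the best monitored
    epoch and the per-epoch history.
    """
    cfg = cfg or TrainConfig()
    split = split or SplitConfig()
    params = init_params(N_FEATURES, cfg.hidden, N_CLASSES, seed=cfg.seed)
    opt = Adam(params, lr=cfg.learning_rate)
    history = TrainHistory()

    best = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    stale = 0

    for epoch in range(cfg.max_epochs):
        tot_loss = tot_n = tot_correct = 0
        saw_batch = False
        for Xb, yb in _iter_batches(dataset, "train", cfg, split, cfg.seed + epoch):
            saw_batch = True
            mask = yb != PAD
            if not mask.any():
                continue
            lval, grads, probs = loss_and_grads(params, Xb, yb, return_probs=True)
            if not np.isfinite(lval):
                raise FloatingPointError(f"training loss diverged at epoch {epoch + 1}")
            opt.step(params, grads)
            n = int(mask.sum())
            tot_loss += lval * n
            tot_n += n
            tot_correct += int((probs.argmax(-1)[mask] == yb[mask]).sum())
        if not saw_batch or tot_n == 0:
            raise ValueError("dataset contains no train windows")
        history.train_loss.append(tot_loss / tot_n)
        history.train_acc.append(tot_correct / tot_n)

        v_loss = v_n = v_correct = 0
        for Xb, yb in _iter_batches(dataset, "val", cfg, split, 0):
            mask = yb != PAD
            if not mask.any():
                continue
            probs = predict_probs(params, Xb)
            v_loss += loss(probs, yb) * int(mask.sum())
            v_correct += int((probs.argmax(-1)[mask] == yb[mask]).sum())
            v_n += int(mask.sum())
        history.val_loss.append(v_loss / v_n if v_n else float("nan"))
        history.val_acc.append(v_correct / v_n if v_n else float("nan"))

        monitored = history.train_loss[-1] if cfg.monitor == "train_loss" else history.val_loss[-1]
        if monitored < best:
            best = monitored
            best_params = {k: v.copy() for k, v in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    return best_params, history


def save_checkpoint(path: str | Path, params: Mapping[str, np.ndarray], cfg: TrainConfig) -> None:
    meta = json.dumps(
        {"hidden": cfg.hidden, "learning_rate": cfg.learning_rate, "seed": cfg.seed,
         "batch_size": cfg.batch_size, "max_epochs": cfg.max_epochs, "patience": cfg.patience}
    )
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **params)


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], TrainConfig]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        params = {k: data[k] for k in data.files if k != "__config__"}
    return params, TrainConfig(**{k: meta[k] for k in
                                  ("hidden", "learning_rate", "seed", "batch_size",
                                   "max_epochs", "patience")})
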