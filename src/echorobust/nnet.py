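"""A small from-scratch convolutional classifier (pure numpy).

Desk-scale stand-in for a fine-tuned deep backbone: three 3x3 conv blocks
(conv -> ReLU -> 2x2 max-pool), a dropout head and a linear output layer,
trained with the full study recipe — AdamW with decoupled weight decay and
two learning-rate groups (convolutional "backbone" vs classification head),
class-weighted label-smoothed cross-entropy, weighted sampling, cosine
learning-rate annealing, and early stopping on validation loss with the best
weights retained.

Everything is deterministic given the training seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 same-padding convolution. x: (N,Cin,H,W), w: (Cout,Cin,3,3)."""
    N, Cin, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((N, w.shape[0], H, W), dtype=x.dtype)
    for di in range(3):
        for dj in range(3):
            patch = xp[:, :, di:di + H, dj:dj + W]
            out += np.tensordot(patch, w[:, :, di, dj], axes=([1], [1])).transpose(0, 3, 1, 2)
    return out + b[None, :, None, None], xp


def _conv_backward(dout: np.ndarray, xp: np.ndarray, w: np.ndarray):
    N, Cout, H, W = dout.shape
    dw = np.zeros_like(w)
    db = dout.sum(axis=(0, 2, 3))
    dxp = np.zeros_like(xp)
    for di in range(3):
        for dj in range(3):
            patch = xp[:, :, di:di + H, dj:dj + W]
            dw[:, :, di, dj] = np.tensordot(dout, patch, axes=([0, 2, 3], [0, 2, 3]))
            dxp[:, :, di:di + H, dj:dj + W] += np.tensordot(
                dout, w[:, :, di, dj], axes=([1], [0])
            ).transpose(0, 3, 1, 2)
    return dxp[:, :, 1:-1, 1:-1], dw, db


def _pool_forward(x: np.ndarray):
    """2x2 max pool (stride 2); input H, W assumed even."""
    N, C, H, W = x.shape
    xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(N, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _pool_backward(dout: np.ndarray, cache):
    idx, shape = cache
    N, C, H, W = shape
    dxr = np.zeros((N, C, H // 2, W // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dxr = dxr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dxr.reshape(N, C, H, W)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class AdamWState:
    m: np.ndarray
    v: np.ndarray
    t: int = 0


class SmallCnn:
    """conv(1->c1) -> pool -> conv(c1->c2) -> pool -> conv(c2->c3) -> pool
    -> flatten -> dropout -> linear(K)."""

    def __init__(
        self,
        input_size: int,
        n_classes: int,
        channels: tuple[int, int, int] = (8, 16, 32),
        dropout: float = 0.3,
        seed: int = 0,
    ):
        if input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8")
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.n_classes = n_classes
        self.channels = channels
        self.dropout = dropout
        c_prev = 1
        self.params: dict[str, np.ndarray] = {}
        for i, c in enumerate(channels):
            fan_in = c_prev * 9
            self.params[f"w{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(c, c_prev, 3, 3)
            )
            self.params[f"b{i}"] = np.zeros(c)
            c_prev = c
        feat = channels[-1] * (input_size // 8) ** 2
        self.params["w_fc"] = rng.normal(0.0, np.sqrt(2.0 / feat), size=(n_classes, feat))
        self.params["b_fc"] = np.zeros(n_classes)
        self._opt: dict[str, AdamWState] = {}

    # ---- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None):
        cache: dict = {"relu": [], "pool": [], "xp": []}
        h = x
        for i in range(len(self.channels)):
            h, xp = _conv_forward(h, self.params[f"w{i}"], self.params[f"b{i}"])
            cache["xp"].append(xp)
            mask = h > 0
            cache["relu"].append(mask)
            h = h * mask
            h, pc = _pool_forward(h)
            cache["pool"].append(pc)
        N = h.shape[0]
        flat = h.reshape(N, -1)
        if train and self.dropout > 0:
            drop = (rng.uniform(size=flat.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            drop = np.ones_like(flat)
        cache["drop"] = drop
        cache["flat"] = flat * drop
        logits = cache["flat"] @ self.params["w_fc"].T + self.params["b_fc"]
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        grads["w_fc"] = dlogits.T @ cache["flat"]
        grads["b_fc"] = dlogits.sum(axis=0)
        dflat = (dlogits @ self.params["w_fc"]) * cache["drop"]
        n_blocks = len(self.channels)
        size = self.input_size // 8
        dh = dflat.reshape(-1, self.channels[-1], size, size)
        for i in reversed(range(n_blocks)):
            dh = _pool_backward(dh, cache["pool"][i])
            dh = dh * cache["relu"][i]
            dh, dw, db = _conv_backward(dh, cache["xp"][i], self.params[f"w{i}"])
            grads[f"w{i}"] = dw
            grads[f"b{i}"] = db
        return grads

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for start in range(0, x.shape[0], batch_size):
            logits, _ = self.forward(x[start:start + batch_size], train=False)
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)

    # ---- optimization -------------------------------------------------------

    def _lr_of(self, name: str, lr_backbone: float, lr_head: float) -> float:
        return lr_head if name.endswith("_fc") else lr_backbone

    def adamw_step(
        self,
        grads: dict[str, np.ndarray],
        lr_backbone: float,
        lr_head: float,
        weight_decay: float,
        schedule: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        for name, g in grads.items():
            p = self.params[name]
            state = self._opt.get(name)
            if state is None:
                state = self._opt[name] = AdamWState(np.zeros_like(p), np.zeros_like(p))
            state.t += 1
            state.m = beta1 * state.m + (1 - beta1) * g
            state.v = beta2 * state.v + (1 - beta2) * g * g
            mhat = state.m / (1 - beta1**state.t)
            vhat = state.v / (1 - beta2**state.t)
            lr = schedule * self._lr_of(name, lr_backbone, lr_head)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
            if name.startswith("w") and weight_decay > 0:  # decoupled, weights only
                p -= lr * weight_decay * p

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        for k, v in snap.items():
            self.params[k] = v.copy()


def smoothed_weighted_loss(
    logits: np.ndarray,
    y: np.ndarray,
    class_weights: np.ndarray,
    label_smoothing: float,
):
    """Class-weighted label-smoothed cross-entropy; returns (loss, dlogits)."""
    N, K = logits.shape
    p = softmax(logits)
    q = np.full((N, K), label_smoothing / K)
    q[np.arange(N), y] += 1.0 - label_smoothing
    w = class_weights[y]
    logp = np.log(np.clip(p, 1e-12, None))
    loss = float(-(w[:, None] * q * logp).sum() / w.sum())
    dlogits = (w[:, None] * (p - q)) / w.sum()
    return loss, dlogits


@dataclass
class FitHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def fit_small_cnn(
    net: SmallCnn,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    *,
    lr_backbone: float = 1e-4,
    lr_head: float = 5e-4,
    weight_decay: float = 1e-4,
    label_smoothing: float = 0.05,
    batch_size: int = 32,
    max_epochs: int = 30,
    patience: int = 5,
    seed: int = 0,
) -> FitHistory:
    """Train with weighted sampling + cosine schedule + early stopping.

    Class weights are inverse-frequency ``N / (K * n_k)``; the per-epoch
    sampler draws frames with probability proportional to their class weight
    (so every class is equally represented in expectation).  The weights at
    the validation-loss minimum are restored before returning.
    """
    if x_val.shape[0] == 0:
        raise ValueError("validation set must be non-empty")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y_train, return_counts=True)
    K = net.n_classes
    class_weights = np.ones(K)
    for c, n in zip(classes, counts):
        class_weights[c] = y_train.size / (len(classes) * n)
    sample_p = class_weights[y_train]
    sample_p = sample_p / sample_p.sum()

    history = FitHistory()
    best_val = np.inf
    best_snap = net.snapshot()
    since_best = 0
    n = x_train.shape[0]
    steps = max(1, n // batch_size)
    for epoch in range(max_epochs):
        schedule = 0.5 * (1.0 + np.cos(np.pi * epoch / max_epochs))
        epoch_loss = 0.0
        for _ in range(steps):
            idx = rng.choice(n, size=min(batch_size, n), replace=True, p=sample_p)
            logits, cache = net.forward(x_train[idx], train=True, rng=rng)
            loss, dlogits = smoothed_weighted_loss(
                logits, y_train[idx], class_weights, label_smoothing
            )
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch} (loss={loss})")
            grads = net.backward(dlogits, cache)
            net.adamw_step(grads, lr_backbone, lr_head, weight_decay, schedule)
            epoch_loss += loss
        history.train_loss.append(epoch_loss / steps)

        val_logits, _ = net.forward(x_val, train=False)
        val_loss, _ = smoothed_weighted_loss(
            val_logits, y_val, class_weights, label_smoothing
        )
        history.val_loss.append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_snap = net.snapshot()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if patience > 0 and since_best >= patience:
                history.stopped_epoch = epoch
                break
    else:
        history.stopped_epoch = max_epochs - 1
    net.restore(best_snap)
    return history
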