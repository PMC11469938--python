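"""Minimal convolutional network on numpy for tile grading.

A compact, fully deterministic CNN (three 3x3 conv blocks with 2x2 max
pooling, global average pooling, one dense layer, softmax) trained with
the Adam optimizer on cross-entropy.  Roughly 25k parameters — small
enough to train on a single CPU in minutes while easily separating the
synthetic texture scale.  Everything is seeded: weight init, batch
shuffling and augmentation draw from one generator, so two runs with the
same data and seed produce bit-identical weights and predictions.

Inputs are float32 tensors of shape (N, S, S, 3) scaled to [0, 1].
"""

from __future__ import annotations

from typing import Callable, List, Optional, Tuple

import numpy as np

Array = np.ndarray


def _conv_forward(x: Array, w: Array, b: Array) -> Array:
    """3x3 same-padding convolution, stride 1; x (N,H,W,C), w (3,3,C,F)."""
    n, h, wd, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.broadcast_to(b, (n, h, wd, b.shape[0])).copy()
    for dy in range(3):
        for dx in range(3):
            out += np.tensordot(xp[:, dy : dy + h, dx : dx + wd, :], w[dy, dx], axes=([3], [0]))
    return out


def _conv_backward(x: Array, w: Array, dout: Array) -> Tuple[Array, Array, Array]:
    n, h, wd, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    dxp = np.zeros_like(xp)
    dw = np.empty_like(w)
    for dy in range(3):
        for dx in range(3):
            patch = xp[:, dy : dy + h, dx : dx + wd, :]
            dw[dy, dx] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, dy : dy + h, dx : dx + wd, :] += np.tensordot(
                dout, w[dy, dx], axes=([3], [1])
            )
    db = dout.sum(axis=(0, 1, 2))
    return dxp[:, 1:-1, 1:-1, :], dw, db


def _pool_forward(x: Array) -> Tuple[Array, Array]:
    """2x2 max pooling; assumes even spatial dims."""
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = xr.max(axis=(2, 4))
    mask = xr == out[:, :, None, :, None, :]
    return out, mask


def _pool_backward(dout: Array, mask: Array) -> Array:
    n, h2, _, w2, _, c = mask.shape
    dxr = mask * dout[:, :, None, :, None, :]
    return dxr.reshape(n, h2 * 2, w2 * 2, c)


def _softmax(z: Array) -> Array:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """Three-conv-block classifier with per-epoch validation tracking."""

    def __init__(
        self,
        n_classes: int = 10,
        input_size: int = 32,
        channels: Tuple[int, int, int] = (16, 32, 64),
        seed: int = 0,
    ) -> None:
        self.n_classes = n_classes
        self.input_size = input_size
        self.channels = channels
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed & 0x7FFFFFFF)
        cins = (3,) + channels[:2]
        self.params: List[Array] = []
        for cin, cout in zip(cins, channels):
            fan_in = 9 * cin
            self.params.append(
                (rng.standard_normal((3, 3, cin, cout)) * np.sqrt(2.0 / fan_in)).astype(
                    np.float32
                )
            )
            self.params.append(np.zeros(cout, dtype=np.float32))
        self.params.append(
            (rng.standard_normal((channels[2], n_classes)) * np.sqrt(1.0 / channels[2])).astype(
                np.float32
            )
        )
        self.params.append(np.zeros(n_classes, dtype=np.float32))
        self._rng = rng
        self.epoch_trace: List[dict] = []

    # ----- forward / backward -------------------------------------------------

    def _forward(self, x: Array, need_cache: bool) -> Tuple[Array, Optional[list]]:
        cache = [] if need_cache else None
        h = x
        for i in range(3):
            w, b = self.params[2 * i], self.params[2 * i + 1]
            z = _conv_forward(h, w, b)
            a = np.maximum(z, 0.0)
            p, mask = _pool_forward(a)
            if need_cache:
                cache.append((h, z, mask))
            h = p
        feat = h.mean(axis=(1, 2))
        logits = feat @ self.params[6] + self.params[7]
        if need_cache:
            cache.append((h.shape, feat))
        return logits, cache

    def _backward(self, cache: list, dlogits: Array) -> List[Array]:
        grads: List[Array] = [None] * len(self.params)
        pshape, feat = cache[3]
        grads[6] = feat.T @ dlogits
        grads[7] = dlogits.sum(axis=0)
        dfeat = dlogits @ self.params[6].T
        n, ph, pw, c = pshape
        dh = np.broadcast_to(dfeat[:, None, None, :] / (ph * pw), pshape).astype(np.float32)
        for i in reversed(range(3)):
            x_in, z, mask = cache[i]
            da = _pool_backward(dh, mask)
            dz = da * (z > 0)
            dh, dw, db = _conv_backward(x_in, self.params[2 * i], dz)
            grads[2 * i], grads[2 * i + 1] = dw, db
        return grads

    # ----- public API ---------------------------------------------------------

    def predict_proba(self, x: Array, batch_size: int = 128) -> Array:
        """Class probabilities over the fixed class order; rows sum to 1."""
        x = np.asarray(x, dtype=np.float32)
        out = np.empty((x.shape[0], self.n_classes), dtype=np.float64)
        for i in range(0, x.shape[0], batch_size):
            logits, _ = self._forward(x[i : i + batch_size], need_cache=False)
            out[i : i + batch_size] = _softmax(logits.astype(np.float64))
        return out

    def fit(
        self,
        x_train: Array,
        y_train: Array,
        x_val: Array,
        y_val: Array,
        epochs: int = 25,
        lr: float = 1e-3,
        batch_size: int = 32,
        augment_fn: Optional[Callable[[Array, np.random.Generator], Array]] = None,
    ) -> List[dict]:
        """Train for exactly ``epochs`` epochs with Adam; keep the best-validation weights.

        Records training loss and validation accuracy per epoch in
        ``epoch_trace``.  ``augment_fn`` (if given) is applied to each
        epoch's training tensor with the model's own RNG.
        """
        x_train = np.asarray(x_train, dtype=np.float32)
        x_val = np.asarray(x_val, dtype=np.float32)
        y_train = np.asarray(y_train, dtype=np.int64)
        y_val = np.asarray(y_val, dtype=np.int64)
        if x_train.shape[0] == 0:
            raise ValueError("training set is empty")

        rng = self._rng
        m = [np.zeros_like(p) for p in self.params]
        v = [np.zeros_like(p) for p in self.params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_acc = -1.0
        best_params = [p.copy() for p in self.params]
        self.epoch_trace = []

        for epoch in range(int(epochs)):
            order = rng.permutation(x_train.shape[0])
            xs = x_train[order]
            ys = y_train[order]
            if augment_fn is not None:
                xs = augment_fn(xs, rng)
            losses = []
            for i in range(0, xs.shape[0], batch_size):
                xb, yb = xs[i : i + batch_size], ys[i : i + batch_size]
                logits, cache = self._forward(xb, need_cache=True)
                probs = _softmax(logits.astype(np.float64))
                n = xb.shape[0]
                losses.append(-np.log(probs[np.arange(n), yb] + 1e-12).mean())
                dlogits = probs.copy()
                dlogits[np.arange(n), yb] -= 1.0
                dlogits = (dlogits / n).astype(np.float32)
                grads = self._backward(cache, dlogits)
                step += 1
                for j, g in enumerate(grads):
                    m[j] = beta1 * m[j] + (1 - beta1) * g
                    v[j] = beta2 * v[j] + (1 - beta2) * g * g
                    mhat = m[j] / (1 - beta1**step)
                    vhat = v[j] / (1 - beta2**step)
                    self.params[j] = (self.params[j] - lr * mhat / (np.sqrt(vhat) + eps)).astype(
                        np.float32
                    )
            if x_val.shape[0] > 0:
                val_acc = float(
                    (self.predict_proba(x_val).argmax(axis=1) == y_val).mean()
                )
            else:
                val_acc = float("nan")
            self.epoch_trace.append(
                {"epoch": epoch + 1, "train_loss": float(np.mean(losses)), "val_accuracy": val_acc}
            )
            if x_val.shape[0] > 0 and val_acc > best_acc:
                best_acc = val_acc
                best_params = [p.copy() for p in self.params]

        if x_val.shape[0] > 0:
            self.params = best_params
        return self.epoch_trace
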