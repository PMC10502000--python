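"""Desk-scale training harness: Adam, validation split, best-model selection.

Mirrors the full-scale protocol at CPU size: Adam with learning rate 1e-3,
100 epochs by default, 10% of the samples held out for validation, and the
parameters from the epoch with the lowest validation loss returned.  All
randomness (split, shuffling, dropout) flows from the seed, so a
single-threaded run is bit-reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .losses import composite_loss_and_grads
from .unet import N_CLASSES, UNet

__all__ = ["train", "TrainingHistory", "stack_samples"]


@dataclass
class TrainingHistory:
    frame: pd.DataFrame  # columns: epoch, train_loss, val_loss
    best_epoch: int
    lam: float

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def stack_samples(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """TrainingSamples -> batched tensors (x, t_onehot, d_t, w)."""
    x = np.stack([s.image for s in samples])[:, None]
    labels = np.stack([s.labels3 for s in samples]).astype(int)
    t = np.moveaxis(np.eye(N_CLASSES)[labels], -1, 1)
    d = np.stack([s.diam_vox for s in samples]).astype(float)
    w = np.stack([s.weights for s in samples]).astype(float)
    return x, t, d, w


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _epoch_loss(net: UNet, x, t, d, w, lam: float, batch_size: int) -> float:
    """Mean loss in eval mode (no dropout, running BN stats)."""
    total, n = 0.0, 0
    for i in range(0, x.shape[0], batch_size):
        sl = slice(i, i + batch_size)
        logits, diam = net.forward(x[sl], training=False)
        loss, _, _ = composite_loss_and_grads(
            logits, t[sl], diam[:, 0], d[sl], w[sl], lam
        )
        nb = min(i + batch_size, x.shape[0]) - i
        total += loss * nb
        n += nb
    return total / n


def train(
    net: UNet,
    samples,
    epochs: int = 100,
    lr: float = 1e-3,
    val_fraction: float = 0.1,
    seed: int = 0,
    lam: float | str = 0.01,
    batch_size: int = 4,
) -> tuple[UNet, TrainingHistory]:
    """Train a U-net on TrainingSamples; returns the best-validation model.

    ``val_fraction`` of the samples (at least one, split deterministically by
    seed) is held out; the returned network carries the weights from the
    epoch with the lowest validation loss.  ``val_fraction=0`` is an explicit
    no-validation mode (used when deliberately overfitting); selection then
    uses the training loss.  ``lam="auto"`` estimates the diameter weight on
    the first batch so the squared-error term lands at the order of magnitude
    of the cross-entropy terms.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    if val_fraction < 0 or val_fraction >= 1:
        raise ValueError("val_fraction must be in [0, 1)")
    n_val = int(round(val_fraction * len(samples)))
    if val_fraction > 0:
        n_val = max(1, n_val)
        if n_val >= len(samples):
            raise ValueError("val_fraction leaves no training samples")
    val_idx, train_idx = order[:n_val], order[n_val:]
    xt, tt, dt, wt = stack_samples([samples[i] for i in train_idx])
    if n_val:
        xv, tv, dv, wv = stack_samples([samples[i] for i in val_idx])

    if lam == "auto":
        logits, diam = net.forward(xt[:batch_size], training=False)
        from .losses import softmax, _per_voxel_terms

        p = softmax(logits)
        ce, bce, se = _per_voxel_terms(p, tt[:batch_size], diam[:, 0], dt[:batch_size])
        mean_se = float(se.mean())
        lam = float((ce + bce).mean() / mean_se) if mean_se > 0 else 0.01
    lam = float(lam)

    opt = _Adam(net.parameters(), lr=lr)
    rows = []
    best = (np.inf, -1, None)
    n_train = xt.shape[0]
    for epoch in range(epochs):
        perm = rng.permutation(n_train)
        train_loss, seen = 0.0, 0
        for i in range(0, n_train, batch_size):
            idx = perm[i : i + batch_size]
            net.zero_grad()
            logits, diam = net.forward(xt[idx], training=True)
            loss, dlogits, ddiam = composite_loss_and_grads(
                logits, tt[idx], diam[:, 0], dt[idx], wt[idx], lam
            )
            net.backward(dlogits, ddiam[:, None])
            opt.step()
            train_loss += loss * len(idx)
            seen += len(idx)
        train_loss /= seen
        val_loss = (
            _epoch_loss(net, xv, tv, dv, wv, lam, batch_size) if n_val else train_loss
        )
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best[0]:
            best = (val_loss, epoch, net.state())
    if best[2] is not None:
        net.load_state(best[2])
    history = TrainingHistory(pd.DataFrame(rows), best_epoch=best[1], lam=lam)
    return net, history
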