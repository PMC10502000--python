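"""The composite training loss.

Per voxel, with one-hot truth t over the 4 classes (k = 0 is background),
predicted probabilities p, and true/predicted diameters d_t, d_p in voxels:

    L_CE  = -sum_k t_k log p_k            (4-class cross-entropy)
    L_BCE = -t_0 log p_0 - (1 - t_0) log(1 - p_0)
    L_SE  = (d_t - d_p)^2

    L = mean over voxels of  w * (L_CE + L_BCE + lambda * L_SE)

The binary term dichotomizes bowel vs background, favouring detection of the
gut even when the part is ambiguous; w is the per-voxel sample weight that
up-weights non-background voxels; lambda scales the squared diameter error
to roughly the magnitude of the cross-entropy terms (0.01 by default for
diameters of tens of voxels, or estimated from data with ``lam="auto"`` in
the trainer).
"""

from __future__ import annotations

import numpy as np

__all__ = ["composite_loss", "composite_loss_and_grads", "softmax"]

_EPS = 1e-7


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


def _per_voxel_terms(p, t_onehot, d_p, d_t):
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    ce = -(t_onehot * np.log(pc)).sum(axis=1)
    t0 = t_onehot[:, 0]
    p0 = pc[:, 0]
    bce = -(t0 * np.log(p0) + (1.0 - t0) * np.log(1.0 - p0))
    se = (d_t - d_p) ** 2
    return ce, bce, se


def composite_loss(
    p: np.ndarray,
    t_onehot: np.ndarray,
    d_p: np.ndarray,
    d_t: np.ndarray,
    weights: np.ndarray | None = None,
    lam: float = 0.01,
) -> float:
    """Scalar composite loss from predicted probabilities and diameters.

    Shapes: p and t_onehot (N, 4, *spatial); d_p, d_t and weights
    (N, *spatial).  The result is the sample-weighted mean over all voxels.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    p = np.asarray(p, dtype=float)
    t_onehot = np.asarray(t_onehot, dtype=float)
    d_p = np.asarray(d_p, dtype=float)
    d_t = np.asarray(d_t, dtype=float)
    if p.shape != t_onehot.shape or d_p.shape != d_t.shape:
        raise ValueError("prediction/truth shapes disagree")
    ce, bce, se = _per_voxel_terms(p, t_onehot, d_p, d_t)
    w = np.ones_like(ce) if weights is None else np.asarray(weights, dtype=float)
    return float((w * (ce + bce + lam * se)).mean())


def composite_loss_and_grads(
    logits: np.ndarray,
    t_onehot: np.ndarray,
    d_p: np.ndarray,
    d_t: np.ndarray,
    weights: np.ndarray | None = None,
    lam: float = 0.01,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss plus gradients w.r.t. the segmentation logits and the diameter output.

    ``d_p`` is the post-activation diameter (the softplus layer handles its
    own chain rule in ``UNet.backward``).  With lam = 0 the diameter gradient
    is identically zero: the regression head is fully decoupled.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    p = softmax(logits)
    ce, bce, se = _per_voxel_terms(p, t_onehot, d_p, d_t)
    w = np.ones_like(ce) if weights is None else np.asarray(weights, dtype=float)
    n_vox = ce.size
    loss = float((w * (ce + bce + lam * se)).mean())

    wn = (w / n_vox)[:, None]
    # CE through softmax: p - t
    dlogits = p - t_onehot
    # BCE on p0 through softmax: dz_k = p_k * (g_k - sum_j g_j p_j), g only on k=0
    pc0 = np.clip(p[:, 0], _EPS, 1.0 - _EPS)
    t0 = t_onehot[:, 0]
    g0 = -t0 / pc0 + (1.0 - t0) / (1.0 - pc0)
    gdotp = g0 * p[:, 0]
    dlogits[:, 0] += p[:, 0] * (g0 - gdotp)
    for k in range(1, p.shape[1]):
        dlogits[:, k] += p[:, k] * (-gdotp)
    dlogits *= wn
    ddiam = (w / n_vox) * (2.0 * lam * (d_p - d_t))
    return loss, dlogits, ddiam
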