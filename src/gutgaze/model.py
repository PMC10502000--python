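"""Model surface: U-net construction, composite loss, training, prediction.

Thin facade over :mod:`gutgaze.nn` that speaks in volumes: ``predict`` takes
a raw HU volume on its grid, normalizes and resizes it for the network, and
returns a 3-part label volume and a voxel-unit diameter map resized back to
the scan's original matrix.
"""

from __future__ import annotations

import numpy as np

from .nn import UNet, UNetConfig, build_unet, composite_loss, train  # noqa: F401
from .preprocessing import _zoom, pad_slices, window_normalize
from .reconstruction import DiameterMap, LabelVolume, VolumeGrid

__all__ = [
    "UNet",
    "UNetConfig",
    "build_unet",
    "composite_loss",
    "train",
    "predict",
]


def _predict_batched(net: UNet, x: np.ndarray, batch_size: int = 8):
    probs, diams = [], []
    for i in range(0, x.shape[0], batch_size):
        p, d = net.predict_proba(x[i : i + batch_size])
        probs.append(p)
        diams.append(d)
    return np.concatenate(probs), np.concatenate(diams)


def predict(
    net: UNet,
    ct: np.ndarray,
    grid: VolumeGrid,
    window: float = 400.0,
    level: float = 40.0,
    batch_size: int = 8,
) -> tuple[LabelVolume, DiameterMap]:
    """Run the network over a scan and resize predictions to the original matrix.

    2d networks run slice by slice; 3d networks see the whole (padded,
    resized) volume.  Labels come from the softmax argmax (codes 0..3) and
    the diameter map from the softplus head (>= 0 everywhere, units of
    original-scan in-plane voxels); both are mapped back with nearest-
    neighbour resampling.
    """
    if tuple(ct.shape) != grid.shape:
        raise ValueError(f"ct shape {ct.shape} != grid shape {grid.shape}")
    img = window_normalize(ct, window, level)
    target = tuple(net.config.input_shape)
    nx, ny, nz = grid.shape

    if net.config.dims == 2:
        x = np.stack([_zoom(img[:, :, k], target, order=1, cval=-1.0) for k in range(nz)])
        probs, diams = _predict_batched(net, x[:, None], batch_size)
        lab_small = probs.argmax(axis=1)  # (nz, *target)
        labels = np.stack(
            [
                np.rint(_zoom(lab_small[k].astype(float), (nx, ny), 0, 0.0))
                for k in range(nz)
            ],
            axis=-1,
        ).astype(np.uint8)
        diam = np.stack(
            [_zoom(diams[k, 0], (nx, ny), 0, 0.0) for k in range(nz)], axis=-1
        )
    else:
        padded_nz = pad_slices(nz, target[2])
        pad = padded_nz - nz
        padded = np.pad(img, ((0, 0), (0, 0), (0, pad)), constant_values=-1.0)
        k = padded_nz // target[2]
        decimated = padded[:, :, k // 2 :: k]
        x = np.stack(
            [_zoom(decimated[:, :, j], target[:2], 1, -1.0) for j in range(target[2])],
            axis=-1,
        )
        probs, diams = _predict_batched(net, x[None, None], batch_size)
        lab_small = probs[0].argmax(axis=0)  # (*target,)
        # back to original matrix: nearest in-plane, slice repetition along z
        lab_planes = np.stack(
            [
                np.rint(_zoom(lab_small[:, :, j].astype(float), (nx, ny), 0, 0.0))
                for j in range(target[2])
            ],
            axis=-1,
        )
        labels = np.repeat(lab_planes, k, axis=2)[:, :, :nz].astype(np.uint8)
        diam_planes = np.stack(
            [_zoom(diams[0, 0][:, :, j], (nx, ny), 0, 0.0) for j in range(target[2])],
            axis=-1,
        )
        diam = np.repeat(diam_planes, k, axis=2)[:, :, :nz]

    diam = np.maximum(diam, 0.0)
    return (
        LabelVolume(grid, labels, scheme="3"),
        DiameterMap(grid, diam, units="voxels", masked=False),
    )
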