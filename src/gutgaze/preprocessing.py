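"""Normalization, unit conversion, resizing and geometric augmentation.

Turns (CT, 13-part labels, mm diameter map) into model-ready samples:
soft-tissue window/level normalization to [-1, 1], reduction to the 3-part
foregut/midgut/hindgut scheme, diameters expressed in in-plane voxels (so
the regression target is independent of field of view and patient size),
resizing to the network input matrix, and affine augmentation composed in
physical mm so geometry is preserved despite anisotropic voxels.  Diameter
values are multiplied by the magnification factor during augmentation so
voxel-unit diameters stay consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .annotation import reduce_label
from .reconstruction import DiameterMap, LabelVolume, VolumeGrid

__all__ = [
    "TrainingSample",
    "AugmentParams",
    "window_normalize",
    "reduce_label_volume",
    "diameter_to_voxels",
    "voxels_to_mm",
    "resize_for_model",
    "augment",
    "make_weights",
    "make_training_sample",
    "DEFAULT_WINDOW_HU",
    "DEFAULT_LEVEL_HU",
    "DEFAULT_FOREGROUND_WEIGHT",
]

DEFAULT_WINDOW_HU = 400.0
DEFAULT_LEVEL_HU = 40.0
DEFAULT_FOREGROUND_WEIGHT = 10.0

# lookup table: 13-part code -> 3-part code (index = 13-part code)
_REDUCE_LUT = np.array([reduce_label(c) for c in range(14)], dtype=np.uint8)


@dataclass(frozen=True)
class TrainingSample:
    """One model-ready sample: image in [-1,1], 3-part labels, voxel diameters,
    per-voxel loss weights — all on the same grid."""

    image: np.ndarray
    labels3: np.ndarray
    diam_vox: np.ndarray
    weights: np.ndarray
    grid: VolumeGrid | None = None

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.image, self.labels3, self.diam_vox, self.weights)}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.image.size:
            if self.image.min() < -1 - 1e-9 or self.image.max() > 1 + 1e-9:
                raise ValueError("image must lie in [-1, 1]")
            if self.diam_vox.min() < 0:
                raise ValueError("diam_vox must be >= 0")
            if self.weights.min() <= 0:
                raise ValueError("weights must be > 0")
        if not np.isin(np.unique(self.labels3), [0, 1, 2, 3]).all():
            raise ValueError("labels3 must hold 3-part codes 0..3")


@dataclass(frozen=True)
class AugmentParams:
    """One draw of the augmentation transform.

    Translation is in-plane only (+-30 mm along x and y), rotation +-30
    degrees about each axis, magnification in [0.7, 1.3]; applied as
    translate o rotate o scale about the volume center in physical mm.
    """

    translation: tuple[float, float] = (0.0, 0.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    magnification: float = 1.0

    def __post_init__(self) -> None:
        if any(abs(t) > 30.0 for t in self.translation):
            raise ValueError("translation must be within +-30 mm")
        if any(abs(r) > 30.0 for r in self.rotation):
            raise ValueError("rotation must be within +-30 degrees")
        if not (0.7 <= self.magnification <= 1.3):
            raise ValueError("magnification must be within [0.7, 1.3]")

    @classmethod
    def random(cls, seed_or_rng: int | np.random.Generator) -> "AugmentParams":
        rng = (
            seed_or_rng
            if isinstance(seed_or_rng, np.random.Generator)
            else np.random.default_rng(seed_or_rng)
        )
        return cls(
            translation=tuple(rng.uniform(-30.0, 30.0, 2)),
            rotation=tuple(rng.uniform(-30.0, 30.0, 3)),
            magnification=float(rng.uniform(0.7, 1.3)),
        )

    @property
    def is_identity(self) -> bool:
        return (
            self.translation == (0.0, 0.0)
            and self.rotation == (0.0, 0.0, 0.0)
            and self.magnification == 1.0
        )


def window_normalize(
    ct: np.ndarray, window: float = DEFAULT_WINDOW_HU, level: float = DEFAULT_LEVEL_HU
) -> np.ndarray:
    """Window/level a HU volume to [-1, 1]: clip(2*(v - level)/window, -1, 1)."""
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    return np.clip(2.0 * (np.asarray(ct, dtype=float) - level) / window, -1.0, 1.0)


def reduce_label_volume(labels: LabelVolume) -> LabelVolume:
    """Collapse a 13-part label volume to the 3-part scheme."""
    if labels.scheme != "13":
        raise ValueError("expected a 13-part label volume")
    return LabelVolume(labels.grid, _REDUCE_LUT[labels.values], scheme="3")


def _check_inplane_isotropic(grid: VolumeGrid) -> float:
    sx, sy = grid.spacing[0], grid.spacing[1]
    if abs(sx - sy) > 1e-6:
        raise ValueError(f"in-plane spacing must be isotropic, got ({sx}, {sy})")
    return sx


def diameter_to_voxels(diam: DiameterMap) -> DiameterMap:
    """Express a mm diameter map in units of in-plane voxels.

    Diameters are measured in the axial plane, so the in-plane voxel size is
    the natural unit; slice thickness plays no role.
    """
    if diam.units != "mm":
        raise ValueError(f"expected units 'mm', got {diam.units!r}")
    s = _check_inplane_isotropic(diam.grid)
    return DiameterMap(diam.grid, diam.values / s, units="voxels", masked=diam.masked)


def voxels_to_mm(diam: DiameterMap) -> DiameterMap:
    """Inverse of :func:`diameter_to_voxels`."""
    if diam.units != "voxels":
        raise ValueError(f"expected units 'voxels', got {diam.units!r}")
    s = _check_inplane_isotropic(diam.grid)
    return DiameterMap(diam.grid, diam.values * s, units="mm", masked=diam.masked)


def _zoom(values: np.ndarray, target: Sequence[int], order: int, cval: float) -> np.ndarray:
    factors = [t / s for t, s in zip(target, values.shape)]
    out = ndimage.zoom(
        values.astype(float), factors, order=order, mode="grid-constant", cval=cval,
        grid_mode=True,
    )
    assert out.shape == tuple(target)
    return out


def pad_slices(n_slices: int, multiple: int) -> int:
    """Number of slices after zero padding to the next multiple."""
    return int(-(-n_slices // multiple) * multiple)


def resize_for_model(
    sample: TrainingSample,
    target: Sequence[int],
    image_pad_value: float = -1.0,
) -> TrainingSample:
    """Resize a sample to the network input matrix.

    A 2-length target resizes in-plane only (per-slice / 2d model path).  A
    3-length target first pads the slice axis to the next multiple of the
    target slice count — so the longitudinal reduction is a pure integer
    decimation, no interpolation along z — then resizes in-plane.  Images are
    linearly interpolated; labels, diameters and weights use nearest
    neighbour.  Diameter *values* are untouched: they count voxels of the
    original scan.
    """
    target = tuple(int(t) for t in target)
    arrs = {
        "image": (sample.image, 1, image_pad_value),
        "labels3": (sample.labels3, 0, 0.0),
        "diam_vox": (sample.diam_vox, 0, 0.0),
        "weights": (sample.weights, 0, 1.0),
    }
    if len(target) not in (2, 3):
        raise ValueError("target must have 2 (in-plane) or 3 entries")
    out = {}
    for name, (values, order, cval) in arrs.items():
        if len(target) == 2:
            inplane = target
            if values.ndim == 2:
                resized = _zoom(values, inplane, order, cval)
            else:
                resized = np.stack(
                    [_zoom(values[..., k], inplane, order, cval) for k in range(values.shape[2])],
                    axis=-1,
                )
        else:
            if values.ndim != 3:
                raise ValueError("3-length target needs volumetric samples")
            nz = values.shape[2]
            padded_nz = pad_slices(nz, target[2])
            if padded_nz < target[2]:
                raise ValueError("padded volume shorter than target along z")
            pad = padded_nz - nz
            padded = np.pad(
                values, ((0, 0), (0, 0), (0, pad)), mode="constant", constant_values=cval
            )
            k = padded_nz // target[2]
            decimated = padded[:, :, k // 2 :: k]  # integer decimation: no z interpolation
            resized = np.stack(
                [
                    _zoom(decimated[..., j], target[:2], order, cval)
                    for j in range(decimated.shape[2])
                ],
                axis=-1,
            )
        out[name] = resized
    labels = np.rint(out["labels3"]).astype(np.uint8)
    return TrainingSample(
        np.clip(out["image"], -1.0, 1.0), labels, out["diam_vox"], out["weights"], grid=None
    )


def _rotation_matrix(rotation_deg: Sequence[float]) -> np.ndarray:
    rx, ry, rz = np.radians(rotation_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def affine_resample(
    values: np.ndarray,
    grid: VolumeGrid,
    params: AugmentParams,
    order: int,
    cval: float,
) -> np.ndarray:
    """Resample one channel under the augmentation transform.

    The forward map is x_out = C + t + R (m (x_in - C)) with C the volume
    center in mm; resampling evaluates the inverse at every output voxel
    center, composed in physical coordinates so anisotropic voxels do not
    shear the geometry.
    """
    S = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    center = origin + S * (np.asarray(grid.shape) - 1) / 2.0
    R = _rotation_matrix(params.rotation)
    Rinv = R.T
    m = params.magnification
    t = np.array([params.translation[0], params.translation[1], 0.0])
    # in_idx = M @ out_idx + off  (voxel-index coordinates)
    M = (Rinv * S[None, :] / S[:, None]) / m
    off = ((center - origin) + Rinv @ (origin - center - t) / m) / S
    return ndimage.affine_transform(
        values.astype(float), M, offset=off, order=order, mode="constant", cval=cval
    )


def augment(sample: TrainingSample, params: AugmentParams, grid: VolumeGrid) -> TrainingSample:
    """Apply one affine augmentation to a volumetric sample.

    Image is linearly interpolated (out-of-field -1), labels/diameters/
    weights nearest neighbour (out-of-field 0 / 0 / 1).  Diameter values are
    multiplied by the magnification factor so voxel-unit diameters remain
    consistent with the rescaled geometry.  Identity parameters are a
    bit-exact no-op.
    """
    if params.is_identity:
        return replace(sample, grid=grid)
    image = np.clip(affine_resample(sample.image, grid, params, order=1, cval=-1.0), -1.0, 1.0)
    labels = np.rint(affine_resample(sample.labels3, grid, params, order=0, cval=0.0)).astype(
        np.uint8
    )
    diam = affine_resample(sample.diam_vox, grid, params, order=0, cval=0.0)
    diam = diam * params.magnification
    weights = affine_resample(sample.weights, grid, params, order=0, cval=1.0)
    return TrainingSample(image, labels, diam, weights, grid=grid)


def make_weights(
    labels3: np.ndarray, foreground_weight: float = DEFAULT_FOREGROUND_WEIGHT
) -> np.ndarray:
    """Per-voxel loss weights: ``foreground_weight`` on non-background voxels, 1 elsewhere."""
    if foreground_weight < 1:
        raise ValueError("foreground_weight must be >= 1")
    return np.where(np.asarray(labels3) != 0, float(foreground_weight), 1.0)


def make_training_sample(
    ct: np.ndarray,
    labels13: LabelVolume,
    diam_mm: DiameterMap,
    window: float = DEFAULT_WINDOW_HU,
    level: float = DEFAULT_LEVEL_HU,
    foreground_weight: float = DEFAULT_FOREGROUND_WEIGHT,
) -> TrainingSample:
    """Full normalization path: HU window, 3-part reduction, voxel diameters, weights."""
    labels3 = reduce_label_volume(labels13)
    diam_vox = diameter_to_voxels(diam_mm)
    return TrainingSample(
        window_normalize(ct, window, level),
        labels3.values,
        diam_vox.values,
        make_weights(labels3.values, foreground_weight),
        grid=labels13.grid,
    )
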