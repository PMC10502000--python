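"""Readers and writers for volumes, samples, and phantom bundles.

Volumes travel as NIfTI (.nii/.nii.gz, via nibabel) or NRRD (via SimpleITK)
with the affine restricted to axis-aligned scaling plus translation — world
coordinates are plain ``origin + index * spacing`` in mm, matching the
reconstruction geometry exactly.  Anything with a rotated or sheared
orientation matrix is rejected rather than silently reinterpreted.  Files
are written atomically (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import yaml

from .phantom import PhantomVolume, TubeSpec
from .preprocessing import TrainingSample
from .reconstruction import DiameterMap, LabelVolume, VolumeGrid

__all__ = [
    "read_volume",
    "write_volume",
    "write_label_volume",
    "write_diameter_map",
    "read_label_volume",
    "read_diameter_map",
    "save_phantom",
    "load_phantom",
    "save_sample",
    "load_sample",
]

_ORIENT_TOL = 1e-6


def _check_affine(affine: np.ndarray, path) -> tuple[np.ndarray, np.ndarray]:
    lin = affine[:3, :3]
    off = np.abs(lin - np.diag(np.diag(lin))).max()
    if off > _ORIENT_TOL:
        raise ValueError(
            f"{path}: unsupported orientation matrix (only axis-aligned scaling "
            f"+ translation is supported); off-diagonal magnitude {off:.3g}"
        )
    spacing = np.diag(lin)
    if (spacing <= 0).any():
        raise ValueError(f"{path}: non-positive or flipped voxel spacing {spacing}")
    return spacing, affine[:3, 3]


def _atomic_write(path: Path, writer) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix="".join(path.suffixes))
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_volume(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    """Read a NIfTI or NRRD volume as ((nx, ny, nz) values, VolumeGrid)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        if img.header.get("dim", None) is None:
            raise ValueError(f"{path}: corrupt NIfTI header (missing 'dim' field)")
        spacing, origin = _check_affine(np.asarray(img.affine), path)
        values = np.asanyarray(img.dataobj)
        if values.ndim != 3:
            raise ValueError(f"{path}: expected a 3-D volume, got shape {values.shape}")
        return np.asarray(values), VolumeGrid(values.shape, tuple(spacing), tuple(origin))
    if name.endswith(".nrrd"):
        img = sitk.ReadImage(str(path))
        direction = np.asarray(img.GetDirection()).reshape(3, 3)
        if np.abs(direction - np.eye(3)).max() > _ORIENT_TOL:
            raise ValueError(f"{path}: unsupported orientation (direction must be identity)")
        values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return values, VolumeGrid(values.shape, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    raise ValueError(f"{path}: unsupported volume format (use .nii, .nii.gz or .nrrd)")


def write_volume(
    values: np.ndarray, grid: VolumeGrid, path: str | Path, dtype=None
) -> None:
    """Write an (nx, ny, nz) volume with its grid to NIfTI or NRRD."""
    path = Path(path)
    values = np.asarray(values)
    if tuple(values.shape) != grid.shape:
        raise ValueError(f"values shape {values.shape} != grid shape {grid.shape}")
    if dtype is not None:
        values = values.astype(dtype)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        affine = np.eye(4)
        affine[:3, :3] = np.diag(grid.spacing)
        affine[:3, 3] = grid.origin
        img = nib.Nifti1Image(values, affine)
        _atomic_write(path, lambda tmp: nib.save(img, tmp))
    elif name.endswith(".nrrd"):
        img = sitk.GetImageFromArray(values.transpose(2, 1, 0))
        img.SetSpacing(tuple(float(s) for s in grid.spacing))
        img.SetOrigin(tuple(float(o) for o in grid.origin))
        _atomic_write(path, lambda tmp: sitk.WriteImage(img, tmp))
    else:
        raise ValueError(f"{path}: unsupported volume format (use .nii, .nii.gz or .nrrd)")


def write_label_volume(labels: LabelVolume, path: str | Path) -> None:
    write_volume(labels.values, labels.grid, path, dtype=np.uint8)


def write_diameter_map(diam: DiameterMap, path: str | Path) -> None:
    write_volume(diam.values, diam.grid, path, dtype=np.float32)


def read_label_volume(path: str | Path, scheme: str = "13") -> LabelVolume:
    values, grid = read_volume(path)
    return LabelVolume(grid, values.astype(np.uint8), scheme=scheme)


def read_diameter_map(
    path: str | Path, units: str = "mm", masked: bool = True
) -> DiameterMap:
    values, grid = read_volume(path)
    return DiameterMap(grid, values.astype(float), units=units, masked=masked)


# ---------------------------------------------------------------------------
# Phantom bundles: ct.nii.gz + labels.nii.gz + diam.nii.gz + tubes.json + meta.yaml

def save_phantom(phantom: PhantomVolume, directory: str | Path, meta: dict | None = None) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_volume(phantom.ct, phantom.grid, d / "ct.nii.gz", dtype=np.float32)
    write_label_volume(phantom.truth_labels, d / "labels.nii.gz")
    write_diameter_map(phantom.truth_diameters, d / "diam.nii.gz")
    tubes = [
        {
            "control_points": t.control_points.tolist(),
            "diameter_profile": t.diameter_profile.tolist(),
            "label": t.label,
            "lumen_hu": t.lumen_hu,
            "wall_hu": t.wall_hu,
        }
        for t in phantom.tubes
    ]
    (d / "tubes.json").write_text(json.dumps(tubes))
    (d / "meta.yaml").write_text(
        yaml.safe_dump({"scan_id": phantom.scan_id, **(meta or {})})
    )


def load_phantom(directory: str | Path) -> PhantomVolume:
    d = Path(directory)
    ct, grid = read_volume(d / "ct.nii.gz")
    labels = read_label_volume(d / "labels.nii.gz")
    diam = read_diameter_map(d / "diam.nii.gz")
    tubes = tuple(
        TubeSpec(
            np.asarray(t["control_points"]),
            np.asarray(t["diameter_profile"]),
            t["label"],
            t["lumen_hu"],
            t["wall_hu"],
        )
        for t in json.loads((d / "tubes.json").read_text())
    )
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    return PhantomVolume(ct, grid, labels, diam, tubes, scan_id=meta["scan_id"])


# ---------------------------------------------------------------------------
# Training samples as .npz

def save_sample(sample: TrainingSample, path: str | Path) -> None:
    path = Path(path)
    arrays = {
        "image": sample.image,
        "labels3": sample.labels3,
        "diam_vox": sample.diam_vox,
        "weights": sample.weights,
    }
    if sample.grid is not None:
        arrays["spacing"] = np.asarray(sample.grid.spacing)
        arrays["origin"] = np.asarray(sample.grid.origin)
    _atomic_write(path, lambda tmp: np.savez_compressed(_force_npz(tmp), **arrays))


def _force_npz(tmp: str) -> str:
    # np.savez appends .npz unless present; the temp name must keep it
    return tmp if tmp.endswith(".npz") else tmp + ".npz"


def load_sample(path: str | Path) -> TrainingSample:
    data = np.load(Path(path))
    grid = None
    if "spacing" in data:
        grid = VolumeGrid(
            data["image"].shape, tuple(data["spacing"]), tuple(data["origin"])
        )
    return TrainingSample(
        data["image"], data["labels3"], data["diam_vox"], data["weights"], grid=grid
    )
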