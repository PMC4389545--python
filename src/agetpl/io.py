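"""NIfTI-1 and plain-text I/O for volumes, PVE maps, transforms and tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .volume import CLASSES, GeometryError, PVEMap, Volume


def read_volume(path) -> Volume:
    """Read a 3D NIfTI-1 volume.

    Raises :class:`GeometryError` for non-3D data or a non-invertible affine.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return Volume(np.asarray(data, dtype=np.float64), np.asarray(img.affine))


def write_volume(volume: Volume, path) -> None:
    """Write a Volume as float32 NIfTI-1 (affine preserved exactly)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.asarray(affine))
    nib.save(img, str(path))


def read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj) > 0, np.asarray(img.affine)


def write_pve(pve: PVEMap, out_dir, prefix: str = "pve") -> None:
    """Write per-class PVE files named ``{prefix}_{om,gm,wm}.nii.gz``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k in CLASSES:
        write_volume(Volume(pve.maps[k], pve.affine), out / f"{prefix}_{k}.nii.gz")
    write_mask(pve.mask, pve.affine, out / f"{prefix}_mask.nii.gz")


def read_pve(in_dir, prefix: str = "pve") -> PVEMap:
    in_dir = Path(in_dir)
    maps = {}
    affine = None
    for k in CLASSES:
        v = read_volume(in_dir / f"{prefix}_{k}.nii.gz")
        maps[k] = v.data
        affine = v.affine
    mask, _ = read_mask(in_dir / f"{prefix}_mask.nii.gz")
    return PVEMap(maps, mask, affine)


def write_labels(labels: np.ndarray, affine: np.ndarray, path) -> None:
    """Hard label volume as uint8 (0 bg, 1 OM, 2 GM, 3 WM)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(labels.astype(np.uint8), np.asarray(affine)), str(path))


def write_affine_matrix(matrix: np.ndarray, path) -> None:
    """4x4 affine as a plain-text matrix file."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(str(path), np.asarray(matrix), fmt="%.12g")


def read_affine_matrix(path) -> np.ndarray:
    m = np.loadtxt(str(path))
    if m.shape != (4, 4):
        raise GeometryError(f"{path}: expected a 4x4 matrix, got {m.shape}")
    return m


def write_displacement(field: np.ndarray, affine: np.ndarray, path) -> None:
    """(3, X, Y, Z) displacement (mm) as a 4D NIfTI with 3 components."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    arr = np.moveaxis(np.asarray(field, dtype=np.float32), 0, -1)
    nib.save(nib.Nifti1Image(arr, np.asarray(affine)), str(path))


def read_displacement(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise GeometryError(f"{path}: expected a 4D displacement with 3 components")
    return np.moveaxis(arr, -1, 0).astype(np.float64), np.asarray(img.affine)
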