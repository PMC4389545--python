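"""Core carrier types: scalar volumes with world geometry and partial-volume maps.

A :class:`Volume` is a 3D scalar grid plus a 4x4 voxel-index -> world-mm
affine (RAS, 0-based indices).  A :class:`PVEMap` holds one partial volume
estimate (PVE) volume per tissue class, constrained to sum to one inside its
brain mask.  The tissue class order is fixed everywhere in this package as
OM < GM < WM (labels 1, 2, 3; background 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed tissue class order used for files, label volumes and tie-breaking.
CLASSES: tuple[str, str, str] = ("om", "gm", "wm")

#: Hard labels: background 0, then 1-based in CLASSES order.
LABELS: dict[str, int] = {"om": 1, "gm": 2, "wm": 3}

PVE_SUM_TOL = 1e-6


class GeometryError(ValueError):
    """Raised for incompatible or degenerate grid geometry."""


@dataclass
class Volume:
    """3D scalar grid with a voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise GeometryError(f"expected 3D data, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise GeometryError("volume contains non-finite values")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm, per axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coordinates(self) -> np.ndarray:
        """World-mm coordinates of every voxel centre, shape (3, *grid)."""
        idx = np.indices(self.shape, dtype=np.float64)
        flat = idx.reshape(3, -1)
        world = self.affine[:3, :3] @ flat + self.affine[:3, 3:4]
        return world.reshape((3,) + self.shape)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (3, N) to continuous voxel indices (3, N)."""
        inv = np.linalg.inv(self.affine)
        return inv[:3, :3] @ points + inv[:3, 3:4]

    def same_grid(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())


def center_affine(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    """Isotropic RAS affine placing the world origin at the grid centre."""
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size
    aff[:3, 3] = -voxel_size * (np.asarray(shape) - 1) / 2.0
    return aff


@dataclass
class PVEMap:
    """Per-class partial volume estimates on one grid.

    ``maps`` is keyed by :data:`CLASSES`; each map is in [0, 1], the per-voxel
    class sum is 1 within ``mask`` and 0 outside.
    """

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if set(self.maps) != set(CLASSES):
            raise ValueError(f"PVEMap requires classes {CLASSES}, got {set(self.maps)}")
        for k in CLASSES:
            self.maps[k] = np.asarray(self.maps[k], dtype=np.float64)
            if self.maps[k].shape != self.mask.shape:
                raise GeometryError("PVE map and mask shapes differ")

    def stacked(self) -> np.ndarray:
        """(3, *grid) array in class order."""
        return np.stack([self.maps[k] for k in CLASSES])

    def validate(self, tol: float = PVE_SUM_TOL) -> None:
        s = self.stacked()
        if s.min() < -tol or s.max() > 1 + tol:
            raise ValueError("PVE values outside [0, 1]")
        total = s.sum(axis=0)
        if self.mask.any() and not np.allclose(total[self.mask], 1.0, atol=tol):
            raise ValueError("per-voxel PVE sum differs from 1 inside mask")
        if (~self.mask).any() and np.abs(total[~self.mask]).max() > tol:
            raise ValueError("nonzero PVE outside mask")

    def copy(self) -> "PVEMap":
        return PVEMap(
            {k: v.copy() for k, v in self.maps.items()},
            self.mask.copy(),
            self.affine.copy(),
        )


def normalize_pve(stacked: np.ndarray, mask: np.ndarray, affine: np.ndarray) -> PVEMap:
    """Build a PVEMap from raw per-class weights, renormalizing inside mask."""
    s = np.clip(np.asarray(stacked, dtype=np.float64), 0.0, None)
    total = s.sum(axis=0)
    safe = np.where(total > 0, total, 1.0)
    s = s / safe
    # voxels in-mask with zero total weight: flat assignment
    dead = mask & (total <= 0)
    if dead.any():
        s[:, dead] = 1.0 / len(CLASSES)
    s[:, ~mask] = 0.0
    return PVEMap({k: s[i] for i, k in enumerate(CLASSES)}, mask, affine)
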