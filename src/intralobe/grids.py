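"""Shared image-domain types: grids, count volumes, VOIs, rigid transforms.

All grids are axis-aligned: the world coordinate (mm) of voxel index
``(i, j, k)`` is ``origin + index * spacing``.  Indices are 0-based and
ordered like the value array's axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GridSpec",
    "ImageVolume",
    "VOI",
    "RigidTransform",
    "load_volume",
    "save_volume",
    "load_label_map",
    "save_label_map",
    "voi_from_label_map",
    "voi_to_label_map",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular 3-D voxel grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]  # mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm
    grid_id: str = "grid"

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """World (mm) coordinates of voxel centers for an (N, 3) index array."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def nearest_indices(self, points: np.ndarray) -> np.ndarray:
        """Nearest voxel index for each world point; may be out of bounds."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.rint((pts - np.asarray(self.origin)) / np.asarray(self.spacing)).astype(int)

    def in_bounds(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices))
        return np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass(frozen=True)
class ImageVolume:
    """3-D grid of non-negative counts per voxel."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {vals.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("volume contains non-finite values")
        if np.any(vals < 0):
            raise ValueError("volume contains negative counts")
        object.__setattr__(self, "values", vals)

    def scaled(self, k: float) -> "ImageVolume":
        if k <= 0:
            raise ValueError("scale factor must be positive")
        return ImageVolume(self.values * k, self.grid)


def _canonical_indices(indices: np.ndarray) -> np.ndarray:
    """Unique (N, 3) int indices in lexicographic (axis0, axis1, axis2) order."""
    idx = np.atleast_2d(np.asarray(indices, dtype=int))
    if idx.ndim != 2 or idx.shape[1] != 3:
        raise ValueError("voxel indices must form an (N, 3) array")
    return np.unique(idx, axis=0)


@dataclass(frozen=True)
class VOI:
    """A volume of interest: a set of voxel indices on a named grid."""

    indices: np.ndarray  # (N, 3) int, unique, lexicographically sorted
    grid: GridSpec
    label: str = "voi"

    def __post_init__(self) -> None:
        idx = _canonical_indices(self.indices)
        if idx.shape[0] == 0:
            raise ValueError(f"VOI {self.label!r} is empty")
        if not np.all(self.grid.in_bounds(idx)):
            raise ValueError(f"VOI {self.label!r} has indices outside grid {self.grid.grid_id!r}")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.shape[0])

    @property
    def volume_ml(self) -> float:
        """VOI volume in mL (voxel count x voxel volume / 1000)."""
        return len(self) * self.grid.voxel_volume_mm3 / 1000.0

    def values_in(self, volume: ImageVolume) -> np.ndarray:
        g, h = self.grid, volume.grid
        if g.shape != h.shape or g.spacing != h.spacing or g.origin != h.origin:
            raise ValueError(
                f"VOI on grid {g.grid_id!r} applied to geometrically different "
                f"grid {h.grid_id!r}"
            )
        i, j, k = self.indices.T
        return volume.values[i, j, k]

    def as_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid.shape, dtype=bool)
        i, j, k = self.indices.T
        mask[i, j, k] = True
        return mask

    @classmethod
    def from_mask(cls, mask: np.ndarray, grid: GridSpec, label: str = "voi") -> "VOI":
        return cls(np.argwhere(np.asarray(mask, dtype=bool)), grid, label)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map of world coordinates: x -> R x + t."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must have determinant +1 (no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rotation, np.eye(3)) and np.allclose(self.translation, 0.0)


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_volume(volume: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), volume.grid.affine)
    nib.save(img, str(path))


def load_volume(path: str | Path, grid_id: str | None = None) -> ImageVolume:
    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise ValueError(f"{path}: only axis-aligned (diagonal-affine) grids are supported")
    data = np.asarray(img.dataobj, dtype=float)
    grid = GridSpec(
        shape=tuple(int(s) for s in data.shape),
        spacing=tuple(float(s) for s in np.diag(aff[:3, :3])),
        origin=tuple(float(o) for o in aff[:3, 3]),
        grid_id=grid_id or Path(path).stem.replace(".nii", ""),
    )
    return ImageVolume(data, grid)


def save_label_map(labels: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), grid.affine)
    nib.save(img, str(path))


def load_label_map(path: str | Path, grid_id: str | None = None) -> tuple[np.ndarray, GridSpec]:
    vol = load_volume(path, grid_id=grid_id)
    return vol.values.astype(int), vol.grid


def voi_from_label_map(labels: np.ndarray, grid: GridSpec, value: int, label: str) -> VOI:
    return VOI.from_mask(np.asarray(labels) == value, grid, label)


def voi_to_label_map(vois: dict[int, VOI], grid: GridSpec) -> np.ndarray:
    out = np.zeros(grid.shape, dtype=np.int16)
    for value, voi in vois.items():
        i, j, k = voi.indices.T
        out[i, j, k] = value
    return out
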