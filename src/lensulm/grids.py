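"""Voxel grids and scalar volumes.

Conventions: right-handed coordinates, probe face at z = 0, +z into the
medium; lengths in mm, times in seconds.  Voxel (0, 0, 0) sits at ``origin``
and world coordinates are ``origin + index * spacing`` (node-centred).
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "ScalarVolume", "read_nifti", "write_nifti"]


@dataclass(frozen=True)
class VolumeGrid:
    """A regular 3D voxel grid: ``origin`` (mm), ``spacing`` (mm), ``shape``."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.shape) != 3:
            raise ValueError("origin, spacing and shape must be length-3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on every axis")
        if any(n < 1 for n in self.shape):
            raise ValueError("shape must be >= 1 on every axis")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_centers(self) -> np.ndarray:
        """All voxel centres as an (nx*ny*nz, 3) array (C order)."""
        ax = [self.axis_coords(i) for i in range(3)]
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of world points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def contains(self, points: np.ndarray) -> np.ndarray:
        idx = self.world_to_index(points)
        hi = np.asarray(self.shape) - 1
        return np.all((idx >= 0) & (idx <= hi), axis=1)

    @classmethod
    def centered(
        cls,
        extent_mm: tuple[float, float, float],
        spacing: float | tuple[float, float, float],
        z_start: float = 0.0,
    ) -> "VolumeGrid":
        """Grid spanning ``extent_mm`` laterally centred on the z axis,
        starting at depth ``z_start``."""
        sp = (spacing,) * 3 if np.isscalar(spacing) else tuple(spacing)
        shape = tuple(max(1, int(round(extent_mm[i] / sp[i])) + 1) for i in range(3))
        origin = (
            -0.5 * (shape[0] - 1) * sp[0],
            -0.5 * (shape[1] - 1) * sp[1],
            z_start,
        )
        return cls(origin, sp, shape)


@dataclass
class ScalarVolume:
    """A scalar field sampled on a :class:`VolumeGrid` with a unit tag."""

    grid: VolumeGrid
    values: np.ndarray
    unit: str = "a.u."

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if tuple(self.values.shape) != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not self.unit:
            raise ValueError("unit tag must be set")

    def copy_with(self, values: np.ndarray, unit: str | None = None) -> "ScalarVolume":
        return ScalarVolume(self.grid, values, unit or self.unit)

    def to_db(self, reference: float | None = None, floor_db: float = -120.0) -> "ScalarVolume":
        ref = float(np.max(np.abs(self.values))) if reference is None else float(reference)
        if ref <= 0:
            raise ValueError("reference must be positive")
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(np.abs(self.values) / ref)
        return ScalarVolume(self.grid, np.maximum(db, floor_db), "dB")


def write_nifti(volume: ScalarVolume, path: str) -> None:
    """Write a volume as NIfTI; spacing/origin go into the affine (mm, RAS-like)."""
    vals = np.asarray(volume.values)
    if not np.all(np.isfinite(vals)):
        raise ValueError("volume contains non-finite voxels")
    affine = np.diag(list(volume.grid.spacing) + [1.0])
    affine[:3, 3] = volume.grid.origin
    img = nib.Nifti1Image(vals.astype(np.float64), affine)
    img.header.set_xyzt_units("mm")
    img.header["descrip"] = volume.unit[:79].encode()
    nib.save(img, path)


def read_nifti(path: str) -> ScalarVolume:
    img = nib.load(path)
    affine = img.affine
    spacing = tuple(float(v) for v in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(v) for v in affine[:3, 3])
    vals = np.asarray(img.dataobj, dtype=np.float64)
    if vals.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got ndim={vals.ndim}")
    unit = img.header["descrip"].item().decode() or "a.u."
    grid = VolumeGrid(origin, spacing, vals.shape)
    return ScalarVolume(grid, vals, unit)
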