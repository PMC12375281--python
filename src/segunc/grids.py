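"""Spatial data model shared by every stage of the pipeline.

All voxel arrays use ``(slice, row, col)`` axis order — the order in which
DICOM slices stack — and spacing triples are given in the same order, in
millimetres.  ``origin_mm`` and ``direction`` follow the ITK physical-space
convention (LPS, direction row-major with columns giving the physical step
for one increment of the col/row/slice index respectively), so volumes
round-trip losslessly through SimpleITK readers and writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: spacing agreement required for two grids to be interchangeable (mm)
SPACING_ATOL_MM = 1e-6
#: origin agreement required for two grids to be interchangeable (mm)
ORIGIN_ATOL_MM = 1e-3

_IDENTITY_DIRECTION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)


@dataclass(frozen=True)
class ImageGrid:
    """Geometry of a 3D voxel grid.

    Parameters
    ----------
    shape : tuple of int
        ``(slices, rows, cols)``, each >= 1.
    spacing_mm : tuple of float
        Voxel spacing ``(slice, row, col)`` in mm, each > 0.
    origin_mm : tuple of float
        Physical position (LPS, mm) of the voxel with index (0, 0, 0).
    direction : tuple of float
        Row-major 3x3 direction-cosine matrix, ITK convention.
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = _IDENTITY_DIRECTION

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))
        object.__setattr__(self, "direction", tuple(float(d) for d in self.direction))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be a triple of positive ints, got {self.shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing components must be > 0, got {self.spacing_mm}")
        if len(self.direction) != 9:
            raise ValueError("direction must be a row-major 3x3 matrix (9 values)")

    # -- derived geometry -------------------------------------------------

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    def slice_position_mm(self, slice_index: int) -> np.ndarray:
        """Physical position of voxel (slice_index, 0, 0); used for DICOM export."""
        d = self.direction_matrix
        step = d @ np.array([0.0, 0.0, slice_index * self.spacing_mm[0]])
        return np.asarray(self.origin_mm) + step

    def voxel_coordinates_mm(self, indices: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices (slice, row, col) to axis-scaled mm coordinates.

        Distances between voxel centres are invariant under the rigid
        direction/origin transform, so metric code works in this scaled
        index space directly.
        """
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing_mm)

    # -- compatibility ----------------------------------------------------

    def is_compatible(self, other: "ImageGrid") -> bool:
        """True when two grids can be treated as the same voxel lattice."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=SPACING_ATOL_MM, rtol=0)
            and np.allclose(self.origin_mm, other.origin_mm, atol=ORIGIN_ATOL_MM, rtol=0)
            and np.allclose(self.direction, other.direction, atol=1e-6, rtol=0)
        )

    def require_compatible(self, other: "ImageGrid", what: str = "volumes") -> None:
        if not self.is_compatible(other):
            raise ValueError(f"incompatible grids for {what}: {self} vs {other}")


class GridMismatchError(ValueError):
    pass


@dataclass
class LabelVolume:
    """A binary segmentation mask on a spacing-aware grid."""

    grid: ImageGrid
    voxels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.shape != self.grid.shape:
            raise ValueError(f"voxel array shape {arr.shape} != grid shape {self.grid.shape}")
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"label volume must contain only 0/1, found values {vals[:10]}")
        self.voxels = arr.astype(np.uint8)

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return self.voxel_count == 0

    @property
    def volume_cc(self) -> float:
        """Mask volume in cm^3: |A| * voxel volume / 1000."""
        return self.voxel_count * self.grid.voxel_volume_mm3 / 1000.0

    def mask(self) -> np.ndarray:
        return self.voxels.astype(bool)


@dataclass
class ProbVolume:
    """A per-voxel probability (SoftMax) volume in [0, 1]."""

    grid: ImageGrid
    voxels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels, dtype=np.float64)
        if arr.shape != self.grid.shape:
            raise ValueError(f"voxel array shape {arr.shape} != grid shape {self.grid.shape}")
        if not np.isfinite(arr).all():
            raise ValueError("probability volume contains non-finite values")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError(
                f"probabilities must lie in [0, 1], found range [{arr.min()}, {arr.max()}]"
            )
        self.voxels = arr
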