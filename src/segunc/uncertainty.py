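"""Ensemble segmentation and voxel-wise uncertainty map construction.

An ensemble of K cross-validation models yields K SoftMax probability
volumes per structure.  The final segmentation is the mean probability
thresholded at 0.5; the uncertainty map is the per-voxel sample standard
deviation (divisor K-1) across members.  For probabilities bounded in
[0, 1] the sample standard deviation is bounded by sqrt(K / (4(K-1))) —
about 0.527 for K = 10 — so values can exceed the 0.5 display maximum:
storage never clips, export quantization clips with a logged count.

A calibration block of constant value ``display_max`` is inserted at the
bottom of every slice so that all cases share one display colour scale in
the viewing software; the block geometry is recorded on the map so every
downstream analysis can exclude it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .grids import ImageGrid, LabelVolume, ProbVolume
from . import io as _io

DEFAULT_DISPLAY_MAX = 0.5


@dataclass
class SoftMaxEnsemble:
    """K probability volumes for one structure on one shared grid."""

    members: list[ProbVolume]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least 2 members (sample std undefined)")
        g0 = self.members[0].grid
        for m in self.members[1:]:
            g0.require_compatible(m.grid, "ensemble members")

    @property
    def K(self) -> int:
        return len(self.members)

    @property
    def grid(self) -> ImageGrid:
        return self.members[0].grid

    def stack(self) -> np.ndarray:
        return np.stack([m.voxels for m in self.members])


@dataclass(frozen=True)
class CalibrationBlock:
    """A constant-value rectangle repeated on every slice (display-scale anchor)."""

    row_range: tuple[int, int]  # half-open [start, stop)
    col_range: tuple[int, int]

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("row_range", self.row_range), ("col_range", self.col_range)):
            if hi <= lo or lo < 0:
                raise ValueError(f"{name} must be a nonempty nonnegative interval, got {(lo, hi)}")

    def validate_on(self, grid: ImageGrid) -> None:
        if self.row_range[1] > grid.shape[1] or self.col_range[1] > grid.shape[2]:
            raise ValueError(f"calibration block {self} outside grid {grid.shape}")

    def mask(self, grid: ImageGrid) -> np.ndarray:
        """Boolean volume marking the block voxels on every slice."""
        self.validate_on(grid)
        m = np.zeros(grid.shape, dtype=bool)
        m[:, self.row_range[0] : self.row_range[1], self.col_range[0] : self.col_range[1]] = True
        return m


def default_block(grid: ImageGrid, n_rows: int = 10, col_fraction: float = 0.5) -> CalibrationBlock:
    """Bottom ``n_rows`` rows, central ``col_fraction`` of columns, every slice."""
    _, rows, cols = grid.shape
    width = max(1, int(round(cols * col_fraction)))
    start = (cols - width) // 2
    return CalibrationBlock(row_range=(rows - n_rows, rows), col_range=(start, start + width))


@dataclass
class UncertaintyMap:
    """Voxel-wise ensemble standard deviation with a fixed display scale."""

    grid: ImageGrid
    voxels: np.ndarray
    display_max: float = DEFAULT_DISPLAY_MAX
    block: Optional[CalibrationBlock] = None
    #: voxels clipped at the most recent export (storage itself never clips)
    clipped_at_export: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels, dtype=np.float64)
        if arr.shape != self.grid.shape:
            raise ValueError(f"voxel array shape {arr.shape} != grid shape {self.grid.shape}")
        if arr.min() < 0:
            raise ValueError("uncertainty values must be >= 0")
        if self.display_max <= 0:
            raise ValueError(f"display_max must be > 0, got {self.display_max}")
        self.voxels = arr

    def block_mask(self) -> np.ndarray:
        if self.block is None:
            return np.zeros(self.grid.shape, dtype=bool)
        return self.block.mask(self.grid)


def ensemble_mean(ens: SoftMaxEnsemble) -> ProbVolume:
    """Voxel-wise arithmetic mean of the member probabilities."""
    return ProbVolume(grid=ens.grid, voxels=ens.stack().mean(axis=0))


def ensemble_segmentation(ens: SoftMaxEnsemble, threshold: float = 0.5) -> LabelVolume:
    """Threshold the mean probability: voxel = 1 iff mean >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    mean = ens.stack().mean(axis=0)
    return LabelVolume(grid=ens.grid, voxels=(mean >= threshold).astype(np.uint8))


def ensemble_std(ens: SoftMaxEnsemble, display_max: float = DEFAULT_DISPLAY_MAX) -> UncertaintyMap:
    """Per-voxel sample standard deviation (divisor K-1) across members."""
    std = ens.stack().std(axis=0, ddof=1)
    return UncertaintyMap(grid=ens.grid, voxels=std, display_max=display_max)


def sample_std_bound(K: int) -> float:
    """Upper bound on the sample std of K values in [0, 1]: sqrt(K / (4(K-1)))."""
    return float(np.sqrt(K / (4.0 * (K - 1))))


def insert_calibration_block(umap: UncertaintyMap, block: CalibrationBlock) -> UncertaintyMap:
    """Return a copy with block voxels set to ``display_max`` on every slice.

    Idempotent; the block is recorded so histograms and statistics can
    exclude it.
    """
    block.validate_on(umap.grid)
    voxels = umap.voxels.copy()
    voxels[block.mask(umap.grid)] = umap.display_max
    return UncertaintyMap(
        grid=umap.grid, voxels=voxels, display_max=umap.display_max, block=block
    )


def build_uncertainty_product(
    member_paths: Sequence,
    out_dir,
    display_max: float = DEFAULT_DISPLAY_MAX,
    threshold: float = 0.5,
    block_rows: int = 10,
    block_col_fraction: float = 0.5,
    frame_of_reference_uid: Optional[str] = None,
) -> dict:
    """Read member SoftMax volumes, build and write the full uncertainty product.

    Writes ``ensemble_mask.nii.gz``, ``uncertainty.nii.gz`` (raw),
    ``uncertainty_blocked.nii.gz``, a PET DICOM series under ``pet/`` and a
    ``manifest.json`` echoing all settings.  Returns the manifest dict.
    """
    members = [_io.read_prob(p) for p in member_paths]
    ens = SoftMaxEnsemble(members=members)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    seg = ensemble_segmentation(ens, threshold=threshold)
    umap = ensemble_std(ens, display_max=display_max)
    block = default_block(ens.grid, n_rows=block_rows, col_fraction=block_col_fraction)
    blocked = insert_calibration_block(umap, block)

    _io.write_mask(seg, out_dir / "ensemble_mask.nii.gz")
    _io.write_float_volume(umap.voxels, ens.grid, out_dir / "uncertainty.nii.gz")
    _io.write_float_volume(blocked.voxels, ens.grid, out_dir / "uncertainty_blocked.nii.gz")

    if frame_of_reference_uid is None:
        frame_of_reference_uid = str(_io.generate_uid())
    _io.write_pet_series(blocked, ens.grid, frame_of_reference_uid, out_dir / "pet")

    manifest = {
        "K": ens.K,
        "display_max": display_max,
        "threshold": threshold,
        "block": {"row_range": list(block.row_range), "col_range": list(block.col_range)},
        "clipped_voxel_count": int(blocked.clipped_at_export),
        "frame_of_reference_uid": frame_of_reference_uid,
        "members": [str(p) for p in member_paths],
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
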