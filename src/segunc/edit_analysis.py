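"""Edited-voxel maps and uncertainty-binned edit histograms.

The edit map codes each voxel as +1 (added by the observer), -1
(removed) or 0 (untouched) relative to the reference (DL) segmentation.
Edited voxels are histogrammed by the uncertainty-map value at the voxel
in 0.1-wide bins spanning the display range; bins are half-open with the
last bin closed, calibration-block voxels are excluded, and values above
the display maximum go to an explicit overflow bucket (possible because
a sample standard deviation of [0,1]-bounded values can exceed 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grids import ImageGrid, LabelVolume
from .uncertainty import UncertaintyMap


@dataclass
class EditMap:
    """Voxel-wise +1/0/-1 coding of an observer's edits against a reference."""

    grid: ImageGrid
    voxels: np.ndarray  # int8 in {-1, 0, +1}

    @property
    def n_edited(self) -> int:
        return int((self.voxels != 0).sum())

    @property
    def n_added(self) -> int:
        return int((self.voxels == 1).sum())

    @property
    def n_removed(self) -> int:
        return int((self.voxels == -1).sum())


def edit_map(reference: LabelVolume, edited: LabelVolume) -> EditMap:
    """+1 where the observer added a voxel, -1 where one was removed."""
    reference.grid.require_compatible(edited.grid, "edit map")
    delta = edited.voxels.astype(np.int8) - reference.voxels.astype(np.int8)
    return EditMap(grid=reference.grid, voxels=delta)


@dataclass
class UncertaintyHistogram:
    """Edited-voxel counts per uncertainty bin (added and removed pooled)."""

    bin_edges: np.ndarray  # length n_bins + 1, from 0.0 to display_max
    counts: np.ndarray  # nonnegative ints, length n_bins
    overflow_count: int = 0
    observer_id: str = ""
    case_id: str = ""
    organ: str = ""
    step: Optional[int] = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("counts length must be len(bin_edges) - 1")
        if (self.counts < 0).any() or self.overflow_count < 0:
            raise ValueError("histogram counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.overflow_count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "count": self.counts,
                "observer": self.observer_id,
                "case": self.case_id,
                "organ": self.organ,
                "step": self.step,
            }
        )


def uncertainty_histogram(
    em: EditMap,
    umap: UncertaintyMap,
    bin_width: float = 0.1,
    split_added_removed: bool = False,
    observer_id: str = "",
    case_id: str = "",
    organ: str = "",
    step: Optional[int] = None,
):
    """Histogram edited voxels by their uncertainty value.

    Bins are ``[0, w), [w, 2w), ..., [max-w, max]`` (last bin closed);
    ``bin_width`` must divide ``display_max`` evenly.  Calibration-block
    voxels are excluded; values above ``display_max`` are counted in
    ``overflow_count``.  With ``split_added_removed`` a (added, removed)
    histogram pair is returned instead of the pooled one.
    """
    em.grid.require_compatible(umap.grid, "uncertainty histogram")
    n_bins_f = umap.display_max / bin_width
    n_bins = int(round(n_bins_f))
    if n_bins < 1 or abs(n_bins_f - n_bins) > 1e-9:
        raise ValueError(
            f"bin_width {bin_width} does not divide display_max {umap.display_max}"
        )
    edges = np.linspace(0.0, umap.display_max, n_bins + 1)

    keep = ~umap.block_mask()
    meta = dict(observer_id=observer_id, case_id=case_id, organ=organ, step=step)

    def _one(selector: np.ndarray) -> UncertaintyHistogram:
        u = umap.voxels[selector & keep]
        over = int((u > umap.display_max).sum())
        u_in = u[u <= umap.display_max]
        idx = np.minimum((u_in / bin_width).astype(np.int64), n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        return UncertaintyHistogram(
            bin_edges=edges, counts=counts, overflow_count=over, **meta
        )

    if split_added_removed:
        return _one(em.voxels == 1), _one(em.voxels == -1)
    return _one(em.voxels != 0)


def pool_histograms(hs: Sequence[UncertaintyHistogram]) -> UncertaintyHistogram:
    """Element-wise sum of histograms sharing the same bin edges."""
    if not hs:
        raise ValueError("nothing to pool")
    edges = hs[0].bin_edges
    for h in hs[1:]:
        if not np.allclose(h.bin_edges, edges):
            raise ValueError("histograms have mismatched bin edges")
    meta_vals = {
        "observer_id": {h.observer_id for h in hs},
        "case_id": {h.case_id for h in hs},
        "organ": {h.organ for h in hs},
        "step": {h.step for h in hs},
    }

    def _pooled(values):
        return values.pop() if len(values) == 1 else "pooled"

    return UncertaintyHistogram(
        bin_edges=edges,
        counts=np.sum([h.counts for h in hs], axis=0),
        overflow_count=sum(h.overflow_count for h in hs),
        observer_id=_pooled(meta_vals["observer_id"]),
        case_id=_pooled(meta_vals["case_id"]),
        organ=_pooled(meta_vals["organ"]),
        step=next(iter(meta_vals["step"])) if len(meta_vals["step"]) == 1 else None,
    )


def compare_conditions(
    h_step1: UncertaintyHistogram, h_step2: UncertaintyHistogram
) -> pd.DataFrame:
    """Per-bin step-1 vs step-2 counts with the percent reduction.

    ``percent_change = 100 * (count1 - count2) / count1`` — positive when
    step 2 holds fewer edits (the headline form of the analysis); NaN
    where the step-1 bin is empty.
    """
    if not np.allclose(h_step1.bin_edges, h_step2.bin_edges):
        raise ValueError("histograms have mismatched bin edges")
    c1 = h_step1.counts.astype(float)
    c2 = h_step2.counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(c1 > 0, 100.0 * (c1 - c2) / c1, np.nan)
    return pd.DataFrame(
        {
            "bin_low": h_step1.bin_edges[:-1],
            "bin_high": h_step1.bin_edges[1:],
            "count_step1": h_step1.counts,
            "count_step2": h_step2.counts,
            "percent_change": pct,
        }
    )
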