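"""Readers and writers: NIfTI volumes, PET-encoded DICOM export, ratings CSV.

NIfTI handling goes through SimpleITK so header geometry (spacing, origin,
direction) is preserved exactly.  The uncertainty map is exported as a PET
(modality PT) DICOM series with a caller-supplied FrameOfReferenceUID so a
treatment-planning system can overlay it on the planning MRI; pixel values
are stored as 16-bit unsigned integers with RescaleSlope =
display_max / 65535 and intercept 0, i.e. a linear full-range encoding of
the 0..display_max scale.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pydicom
import SimpleITK as sitk
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .grids import ImageGrid, LabelVolume, ProbVolume

PT_SOP_CLASS_UID = "1.2.840.10008.5.1.4.1.1.128"  # PET Image Storage


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def _grid_from_sitk(img: sitk.Image) -> ImageGrid:
    return ImageGrid(
        shape=tuple(reversed(img.GetSize())),
        spacing_mm=tuple(reversed(img.GetSpacing())),
        origin_mm=tuple(img.GetOrigin()),
        direction=tuple(img.GetDirection()),
    )


def _sitk_from_array(arr: np.ndarray, grid: ImageGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(reversed(grid.spacing_mm)))
    img.SetOrigin(grid.origin_mm)
    img.SetDirection(grid.direction)
    return img


def _read_3d(path) -> tuple[np.ndarray, ImageGrid]:
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {img.GetDimension()}D")
    arr = sitk.GetArrayFromImage(img)
    if not np.isfinite(arr).all():
        raise ValueError(f"{path}: volume contains non-finite values")
    return arr, _grid_from_sitk(img)


def read_mask(path) -> LabelVolume:
    """Read a binary mask from NIfTI; nonzero voxels are mapped to 1.

    Inputs carrying more than one distinct nonzero label are rejected:
    that usually means a multi-structure export was passed where a single
    structure was expected.
    """
    arr, grid = _read_3d(path)
    nonzero = np.unique(arr[arr != 0])
    if nonzero.size > 1:
        raise ValueError(
            f"{path}: mask holds {nonzero.size} distinct nonzero labels {nonzero[:5]}; "
            "expected a single structure"
        )
    return LabelVolume(grid=grid, voxels=(arr != 0).astype(np.uint8))


def write_mask(vol: LabelVolume, path) -> None:
    """Write a binary mask to NIfTI (uint8, geometry from the grid)."""
    img = _sitk_from_array(vol.voxels.astype(np.uint8), vol.grid)
    sitk.WriteImage(img, str(path))


def read_prob(path) -> ProbVolume:
    """Read a SoftMax probability volume from NIfTI."""
    arr, grid = _read_3d(path)
    return ProbVolume(grid=grid, voxels=arr.astype(np.float64))


def write_prob(vol: ProbVolume, path) -> None:
    img = _sitk_from_array(vol.voxels.astype(np.float32), vol.grid)
    sitk.WriteImage(img, str(path))


def write_float_volume(arr: np.ndarray, grid: ImageGrid, path) -> None:
    """Write an arbitrary nonnegative float volume (e.g. an uncertainty map)."""
    img = _sitk_from_array(np.asarray(arr, dtype=np.float32), grid)
    sitk.WriteImage(img, str(path))


def read_float_volume(path) -> tuple[np.ndarray, ImageGrid]:
    return _read_3d(path)


# ---------------------------------------------------------------------------
# PET DICOM export of the uncertainty map
# ---------------------------------------------------------------------------

def write_pet_series(
    umap,
    ref_grid: ImageGrid,
    frame_of_reference_uid: str,
    out_dir,
) -> list[Path]:
    """Export an uncertainty map as a PET-encoded DICOM slice stack.

    One file per slice; modality PT; FrameOfReferenceUID taken from the
    caller so the stack registers with the planning image series.  Values
    above ``display_max`` are clipped at this export step (storage never
    clips); the number of clipped voxels is available as
    ``umap.clipped_at_export`` after the call.

    Returns the written file paths in slice order.
    """
    umap.grid.require_compatible(ref_grid, "PET export")
    if umap.display_max <= 0:
        raise ValueError(f"display_max must be > 0, got {umap.display_max}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    slope = umap.display_max / 65535.0
    values = np.asarray(umap.voxels, dtype=np.float64)
    clipped = int((values > umap.display_max).sum())
    umap.clipped_at_export = clipped
    stored = np.round(np.clip(values, 0.0, umap.display_max) / slope).astype(np.uint16)

    series_uid = generate_uid()
    study_uid = generate_uid()
    d = ref_grid.direction_matrix
    iop = [*d[:, 0].tolist(), *d[:, 1].tolist()]  # row then column cosines

    n_slices, n_rows, n_cols = ref_grid.shape
    paths: list[Path] = []
    for k in range(n_slices):
        ds = Dataset()
        ds.SOPClassUID = PT_SOP_CLASS_UID
        ds.SOPInstanceUID = generate_uid()
        ds.Modality = "PT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_of_reference_uid
        ds.SeriesDescription = "segmentation uncertainty"
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [f"{v:.10g}" for v in iop]
        ds.ImagePositionPatient = [f"{v:.10g}" for v in ref_grid.slice_position_mm(k)]
        ds.PixelSpacing = [f"{ref_grid.spacing_mm[1]:.10g}", f"{ref_grid.spacing_mm[2]:.10g}"]
        ds.SliceThickness = f"{ref_grid.spacing_mm[0]:.10g}"
        ds.Rows = n_rows
        ds.Columns = n_cols
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = f"{slope:.9g}"
        ds.RescaleIntercept = "0"
        ds.Units = "NONE"
        ds.PixelData = stored[k].tobytes()

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = PT_SOP_CLASS_UID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta

        path = out_dir / f"pt_{k:04d}.dcm"
        pydicom.dcmwrite(path, ds, enforce_file_format=True)
        paths.append(path)
    return paths


def read_pet_series(in_dir) -> tuple[np.ndarray, ImageGrid, str]:
    """Read back a PET series written by :func:`write_pet_series`.

    Returns (values, grid, frame_of_reference_uid); values are rescaled
    (stored * slope + intercept).  Slices are ordered by the projection of
    ImagePositionPatient onto the slice direction.
    """
    files = sorted(Path(in_dir).glob("*.dcm"))
    if not files:
        raise ValueError(f"no DICOM files in {in_dir}")
    datasets = [pydicom.dcmread(f) for f in files]
    iop = np.array([float(v) for v in datasets[0].ImageOrientationPatient])
    slice_dir = np.cross(iop[:3], iop[3:])
    positions = [np.array([float(v) for v in ds.ImagePositionPatient]) for ds in datasets]
    order = np.argsort([p @ slice_dir for p in positions])
    datasets = [datasets[i] for i in order]
    positions = [positions[i] for i in order]

    slices = []
    for ds in datasets:
        stored = np.frombuffer(ds.PixelData, dtype=np.uint16).reshape(ds.Rows, ds.Columns)
        slices.append(stored * float(ds.RescaleSlope) + float(ds.RescaleIntercept))
    values = np.stack(slices)

    first = datasets[0]
    if len(datasets) > 1:
        slice_spacing = float(np.linalg.norm(positions[1] - positions[0]))
    else:
        slice_spacing = float(first.SliceThickness)
    direction = np.column_stack([iop[:3], iop[3:], slice_dir]).reshape(-1)
    grid = ImageGrid(
        shape=values.shape,
        spacing_mm=(slice_spacing, float(first.PixelSpacing[0]), float(first.PixelSpacing[1])),
        origin_mm=tuple(positions[0]),
        direction=tuple(direction),
    )
    return values, grid, str(first.FrameOfReferenceUID)


# ---------------------------------------------------------------------------
# Observer rating tables
# ---------------------------------------------------------------------------

#: quality scale for Q1/Q2 (4 points, A best)
QUALITY_LABELS = {"D": 1, "C": 2, "B": 3, "A": 4}
#: confidence scale for Q3 (5 points, a best)
CONFIDENCE_LABELS = {"e": 1, "d": 2, "c": 3, "b": 4, "a": 5}

QUESTION_SCALES = {"Q1": 4, "Q2": 4, "Q3": 5}
ORGANS = ("prostate_ctv", "rectum")

RATINGS_COLUMNS = ["observer", "case", "step", "question", "organ", "rating", "time_min"]


@dataclass(frozen=True)
class RatingRecord:
    """One observer's answer (or timing entry) for one case in one step.

    Rating rows carry a question/organ and an ordinal on that question's
    scale.  Time rows carry the per-case total editing time (recorded once
    per case and step, organ and question blank).
    """

    observer_id: str
    case_id: str
    step: int
    question: Optional[str] = None
    organ: Optional[str] = None
    rating_ordinal: Optional[int] = None
    time_min: Optional[float] = None

    def __post_init__(self) -> None:
        if self.step not in (1, 2):
            raise ValueError(f"step must be 1 or 2, got {self.step}")
        if self.question is not None:
            if self.question not in QUESTION_SCALES:
                raise ValueError(f"unknown question {self.question!r}")
            if self.organ not in ORGANS:
                raise ValueError(f"unknown organ {self.organ!r}")
            scale = QUESTION_SCALES[self.question]
            if not (isinstance(self.rating_ordinal, int) and 1 <= self.rating_ordinal <= scale):
                raise ValueError(
                    f"rating {self.rating_ordinal!r} outside 1..{scale} for {self.question}"
                )
        else:
            if self.time_min is None:
                raise ValueError("a record must carry a rating or a time")
        if self.time_min is not None and self.time_min < 0:
            raise ValueError(f"time_min must be >= 0, got {self.time_min}")

    @property
    def key(self) -> tuple:
        return (self.observer_id, self.case_id, self.step, self.question, self.organ)


def rating_to_ordinal(question: str, label: str) -> int:
    """Map an answer label to its ordinal (Q1/Q2: D..A -> 1..4; Q3: e..a -> 1..5)."""
    label = label.strip()
    table = QUALITY_LABELS if question in ("Q1", "Q2") else CONFIDENCE_LABELS
    if label in table:
        return table[label]
    # already-numeric input is accepted if on-scale
    try:
        ordinal = int(label)
    except ValueError:
        raise ValueError(f"unknown rating label {label!r} for question {question}") from None
    if not 1 <= ordinal <= QUESTION_SCALES[question]:
        raise ValueError(f"rating {ordinal} outside the {question} scale")
    return ordinal


def ordinal_to_label(question: str, ordinal: int) -> str:
    table = QUALITY_LABELS if question in ("Q1", "Q2") else CONFIDENCE_LABELS
    for label, value in table.items():
        if value == ordinal:
            return label
    raise ValueError(f"ordinal {ordinal} outside the {question} scale")


def read_ratings(path) -> list[RatingRecord]:
    """Read an observer-study ratings CSV into validated records.

    Expected header: ``observer,case,step,question,organ,rating,time_min``.
    Duplicate (observer, case, step, question, organ) keys are rejected.
    """
    records: list[RatingRecord] = []
    seen: set = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(RATINGS_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            step = int(row["step"])
            question = row["question"].strip() or None
            organ = row["organ"].strip() or None
            rating = row["rating"].strip()
            time_raw = row["time_min"].strip()
            time_min = float(time_raw) if time_raw else None
            if question is not None:
                rec = RatingRecord(
                    observer_id=row["observer"].strip(),
                    case_id=row["case"].strip(),
                    step=step,
                    question=question,
                    organ=organ,
                    rating_ordinal=rating_to_ordinal(question, rating),
                    time_min=time_min,
                )
            else:
                rec = RatingRecord(
                    observer_id=row["observer"].strip(),
                    case_id=row["case"].strip(),
                    step=step,
                    time_min=time_min,
                )
            if rec.key in seen:
                raise ValueError(f"{path}:{i}: duplicate record key {rec.key}")
            seen.add(rec.key)
            records.append(rec)
    return records


def write_ratings(records: Iterable[RatingRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RATINGS_COLUMNS)
        for rec in records:
            label = (
                ordinal_to_label(rec.question, rec.rating_ordinal) if rec.question else ""
            )
            writer.writerow(
                [
                    rec.observer_id,
                    rec.case_id,
                    rec.step,
                    rec.question or "",
                    rec.organ or "",
                    label,
                    "" if rec.time_min is None else f"{rec.time_min:.4f}",
                ]
            )
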