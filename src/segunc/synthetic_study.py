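"""Synthetic observer study with known ground truth.

Generates everything the analysis pipeline consumes — phantom organs, a
K-member ensemble of boundary-perturbed SoftMax volumes, the resulting DL
segmentation and uncertainty map, observer edits under two conditions,
ordinal Likert ratings and per-case editing times — with every effect
parameter recorded, so each pipeline stage can be checked for parameter
recovery.

Ensemble model.  Member k's probability volume is
``sigmoid((d(x) + eta(x) + s(x) * xi_k(x)) / w)`` where ``d`` is the
signed Euclidean distance (mm, positive inside) to the ground-truth
boundary, ``w`` the boundary softness, ``eta`` a smooth bias field shared
by all members (systematic model error, invisible to the ensemble spread),
``xi_k`` independent smooth zero-mean member fields, and ``s`` a smooth
agreement factor in (0, 1) that modulates how much the members disagree
from place to place.  The shared bias makes the ensemble confidently wrong
in some regions; the agreement factor spreads the boundary uncertainty
values over the whole display range — together they reproduce the
empirically central situation of edits occurring at every uncertainty
level, including near-zero.

Edit model.  Observers edit only near the DL boundary (within a candidate
band) and only correctively (toward the ground truth).  In step 1 each
wrong candidate voxel is fixed with probability ``p0``; in step 2 with
``p0 * m_b`` where ``b`` is the voxel's uncertainty bin — so the per-bin
step2/step1 edit-count ratio recovers ``m_b`` directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import expit, ndtr

from .grids import ImageGrid, LabelVolume, ProbVolume
from . import io as _io
from .edit_analysis import UncertaintyHistogram, edit_map, pool_histograms, uncertainty_histogram
from .io import RatingRecord
from .seg_metrics import metric_panel
from .uncertainty import (
    CalibrationBlock,
    SoftMaxEnsemble,
    UncertaintyMap,
    default_block,
    ensemble_segmentation,
    ensemble_std,
    insert_calibration_block,
)

ORGANS = ("prostate_ctv", "rectum")


@dataclass
class StudyConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    n_cases: int = 35
    K: int = 10
    shape: tuple[int, int, int] = (64, 96, 96)
    spacing_mm: tuple[float, float, float] = (2.5, 0.9, 0.9)

    # phantom anatomy (mm)
    prostate_radii_mm: tuple[tuple[float, float], ...] = ((18.0, 22.0), (16.0, 20.0), (20.0, 24.0))
    prostate_modulation: float = 0.1  # relative radial modulation amplitude (<= 0.15)
    rectum_radius_mm: float = 9.0
    rectum_sway_mm: float = 4.0
    rectum_sway_period_mm: float = 120.0

    # ensemble / uncertainty map
    boundary_softness_mm: float = 1.5  # w
    field_sd_mm: float = 6.0  # maximum member-spread sigma_f (scaled by agreement)
    field_corr_mm: float = 8.0  # L
    bias_sd_mm: float = 2.5  # shared systematic boundary error
    bias_corr_mm: float = 16.0
    agreement_corr_mm: float = 16.0
    agreement_sharpness: float = 2.0  # >1 pushes agreement toward 0/1
    display_max: float = 0.5
    seg_threshold: float = 0.5
    block_rows: int = 10
    block_col_fraction: float = 0.5

    # edit model
    edit_band_mm: float = 3.0  # candidate band r around the DL boundary
    base_edit_prob: float = 0.05  # p0
    step2_multipliers: tuple[float, ...] = (0.5, 0.8, 1.0, 1.0, 1.0)  # m_b per bin
    bin_width: float = 0.1

    # observers
    observers: tuple[str, ...] = ("obsB", "obsC", "obsD", "obsE")

    # rating model
    rating_noise_sd: float = 0.5  # sigma_o
    rating_shift: dict = field(default_factory=lambda: {"Q1": 0.0, "Q2": 0.0, "Q3": 0.0})
    cutpoints_4: tuple[float, ...] = (-2.0, -1.0, 0.3)
    cutpoints_5: tuple[float, ...] = (-2.4, -1.5, -0.7, 0.4)

    # time model (per observer, aligned with `observers`)
    time_median_min: tuple[float, ...] = (7.0, 4.5, 7.0, 6.0)
    time_step2_multiplier: tuple[float, ...] = (1.0, 0.85, 0.86, 0.67)
    time_log_sd: float = 0.25

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.base_edit_prob < 1.0:
            raise ValueError("base_edit_prob must lie in (0, 1)")
        if any(not 0.0 <= m <= 2.0 for m in self.step2_multipliers):
            raise ValueError("step-2 multipliers must lie in [0, 2]")
        if self.base_edit_prob * max(self.step2_multipliers) > 1.0:
            raise ValueError("p0 * max(m) exceeds 1; not a probability")
        for name in ("boundary_softness_mm", "field_corr_mm", "bias_corr_mm",
                     "agreement_corr_mm", "edit_band_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.time_median_min) != len(self.observers):
            raise ValueError("one time median per observer required")
        if len(self.time_step2_multiplier) != len(self.observers):
            raise ValueError("one step-2 time multiplier per observer required")
        for cuts in (self.cutpoints_4, self.cutpoints_5):
            if not all(a < b for a, b in zip(cuts, cuts[1:])):
                raise ValueError("cutpoints must be strictly increasing")

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(shape=self.shape, spacing_mm=self.spacing_mm)

    @property
    def case_ids(self) -> list[str]:
        return [f"pat{i + 1:02d}" for i in range(self.n_cases)]

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _smooth_field(
    rng: np.random.Generator, grid: ImageGrid, corr_mm: float, sd: float
) -> np.ndarray:
    """Smooth zero-mean Gaussian random field with unit-sd normalisation.

    Sampled on a coarse lattice (two nodes per correlation length),
    Gaussian-filtered, then trilinearly interpolated to the full grid;
    the result is renormalised to the requested pointwise sd.
    """
    if sd == 0.0:
        return np.zeros(grid.shape)
    spacing = np.asarray(grid.spacing_mm)
    extent = spacing * np.asarray(grid.shape)
    coarse_spacing = corr_mm / 2.0
    sigma = 2.0  # one correlation length in coarse-lattice units
    pad = int(4 * sigma)  # keep the filtered field stationary inside the crop
    cshape = np.maximum(4, np.ceil(extent / coarse_spacing).astype(int) + 3) + 2 * pad
    noise = rng.standard_normal(tuple(cshape))
    f = ndimage.gaussian_filter(noise, sigma=sigma, mode="constant")
    coords = np.meshgrid(
        *[pad + np.arange(n) * sp / coarse_spacing for n, sp in zip(grid.shape, spacing)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        f, [c.ravel() for c in coords], order=1, mode="nearest"
    ).reshape(grid.shape)
    out = (out - out.mean()) / out.std()
    return out * sd


def _signed_distance_mm(mask: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Signed Euclidean distance to the mask boundary, positive inside (mm)."""
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask.astype(bool), sampling=spacing)
    return inside - outside


def _coordinate_grids_mm(grid: ImageGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [np.arange(n) * sp for n, sp in zip(grid.shape, grid.spacing_mm)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def make_phantom(cfg: StudyConfig, case_seed) -> tuple[LabelVolume, LabelVolume]:
    """Prostate-like modulated ellipsoid and rectum-like curved tube.

    The structures are disjoint by construction (the tube is carved away
    from a one-voxel dilation of the prostate).
    """
    rng = np.random.default_rng(case_seed)
    grid = cfg.grid
    zc, yc, xc = _coordinate_grids_mm(grid)
    extent = np.asarray(grid.spacing_mm) * np.asarray(grid.shape)

    radii = np.array([rng.uniform(lo, hi) for lo, hi in cfg.prostate_radii_mm])
    if (radii.min() * (1 - cfg.prostate_modulation) * 2) > min(extent):
        raise ValueError("grid too small for the requested prostate radii")
    centre = np.array([0.5 * extent[0], 0.32 * extent[1], 0.5 * extent[2]])
    centre += rng.uniform(-2.0, 2.0, size=3)
    rho = np.sqrt(
        ((zc - centre[0]) / radii[0]) ** 2
        + ((yc - centre[1]) / radii[1]) ** 2
        + ((xc - centre[2]) / radii[2]) ** 2
    )
    modulation = cfg.prostate_modulation * np.tanh(_smooth_field(rng, grid, 12.0, 1.0))
    prostate = rho <= 1.0 + modulation

    # rectum: tube along the slice axis, posterior to the prostate
    row_centre = 0.68 * extent[1]
    phase = rng.uniform(0, 2 * np.pi)
    sway = cfg.rectum_sway_mm * np.sin(2 * np.pi * zc / cfg.rectum_sway_period_mm + phase)
    col_centre = 0.5 * extent[2] + rng.uniform(-2.0, 2.0)
    in_plane = np.sqrt((yc - (row_centre + sway)) ** 2 + (xc - col_centre) ** 2)
    radius = cfg.rectum_radius_mm * (
        1.0 + 0.1 * np.tanh(_smooth_field(rng, grid, 20.0, 1.0))
    )
    rectum = in_plane <= radius
    rectum &= ~ndimage.binary_dilation(prostate, iterations=1)

    gt_p = LabelVolume(grid=grid, voxels=prostate.astype(np.uint8))
    gt_r = LabelVolume(grid=grid, voxels=rectum.astype(np.uint8))
    assert not np.logical_and(gt_p.mask(), gt_r.mask()).any()
    return gt_p, gt_r


def make_ensemble(gt: LabelVolume, cfg: StudyConfig, case_seed) -> SoftMaxEnsemble:
    """K boundary-perturbed SoftMax volumes around the ground-truth mask."""
    if gt.is_empty:
        raise ValueError("ground-truth mask is empty")
    if cfg.boundary_softness_mm <= 0:
        raise ValueError("boundary softness w must be > 0")
    rng = np.random.default_rng(case_seed)
    grid = gt.grid
    d = _signed_distance_mm(gt.mask(), grid.spacing_mm)
    bias = _smooth_field(rng, grid, cfg.bias_corr_mm, cfg.bias_sd_mm)
    agreement = ndtr(cfg.agreement_sharpness * _smooth_field(rng, grid, cfg.agreement_corr_mm, 1.0))
    members = []
    for _ in range(cfg.K):
        xi = _smooth_field(rng, grid, cfg.field_corr_mm, cfg.field_sd_mm)
        prob = expit((d + bias + agreement * xi) / cfg.boundary_softness_mm)
        members.append(ProbVolume(grid=grid, voxels=prob))
    return SoftMaxEnsemble(members=members)


def edit_candidates(dl_seg: LabelVolume, cfg: StudyConfig) -> np.ndarray:
    """Voxels within ``edit_band_mm`` of the DL boundary (boolean volume)."""
    d = _signed_distance_mm(dl_seg.mask(), dl_seg.grid.spacing_mm)
    return np.abs(d) <= cfg.edit_band_mm


def simulate_edits(
    dl_seg: LabelVolume,
    umap: UncertaintyMap,
    gt: LabelVolume,
    cfg: StudyConfig,
    step: int,
    obs_seed,
    candidates: Optional[np.ndarray] = None,
) -> LabelVolume:
    """One observer's corrective edits of the DL mask in one condition.

    Candidate voxels near the DL boundary that disagree with the ground
    truth are set to the ground-truth label with probability ``p0``
    (step 1) or ``p0 * m_b(u)`` (step 2, uncertainty-binned).
    """
    if step not in (1, 2):
        raise ValueError("step must be 1 or 2")
    dl_seg.grid.require_compatible(gt.grid, "edit simulation")
    dl_seg.grid.require_compatible(umap.grid, "edit simulation")
    rng = np.random.default_rng(obs_seed)
    if candidates is None:
        candidates = edit_candidates(dl_seg, cfg)
    wrong = candidates & (dl_seg.voxels != gt.voxels)
    n_bins = len(cfg.step2_multipliers)
    if step == 1:
        prob = np.full(int(wrong.sum()), cfg.base_edit_prob)
    else:
        u = umap.voxels[wrong]
        bins = np.clip((u / cfg.bin_width).astype(np.int64), 0, n_bins - 1)
        prob = cfg.base_edit_prob * np.asarray(cfg.step2_multipliers)[bins]
    toggled = rng.random(prob.size) < prob
    edited = dl_seg.voxels.copy()
    idx = np.argwhere(wrong)[toggled]
    edited[idx[:, 0], idx[:, 1], idx[:, 2]] = gt.voxels[idx[:, 0], idx[:, 1], idx[:, 2]]
    return LabelVolume(grid=dl_seg.grid, voxels=edited)


def simulate_ratings(cfg: StudyConfig, seed: Optional[int] = None) -> list[RatingRecord]:
    """Likert answers for every observer, case, step, question and organ.

    Latent case quality z_c ~ N(0,1) is shared by both steps (paired
    design); observer noise sd ``rating_noise_sd`` and a per-question
    step-2 shift ``rating_shift`` enter before discretisation through the
    scale's cutpoints.
    """
    base_seed = cfg.seed if seed is None else seed
    records: list[RatingRecord] = []
    question_organs = {"Q1": ("prostate_ctv",), "Q2": ("rectum",), "Q3": ORGANS}
    cuts = {4: np.asarray(cfg.cutpoints_4), 5: np.asarray(cfg.cutpoints_5)}
    for ci, case_id in enumerate(cfg.case_ids):
        z = _rng(base_seed, 1, ci).standard_normal()
        for oi, obs in enumerate(cfg.observers):
            rng = _rng(base_seed, 2, ci, oi)
            for step in (1, 2):
                for question, organs in question_organs.items():
                    shift = cfg.rating_shift.get(question, 0.0) if step == 2 else 0.0
                    scale = _io.QUESTION_SCALES[question]
                    for organ in organs:
                        latent = z + shift + cfg.rating_noise_sd * rng.standard_normal()
                        ordinal = int(1 + (latent > cuts[scale]).sum())
                        records.append(
                            RatingRecord(
                                observer_id=obs,
                                case_id=case_id,
                                step=step,
                                question=question,
                                organ=organ,
                                rating_ordinal=ordinal,
                            )
                        )
    return records


def simulate_times(cfg: StudyConfig, seed: Optional[int] = None) -> list[RatingRecord]:
    """Per-case total editing times (log-normal, per-observer medians)."""
    base_seed = cfg.seed if seed is None else seed
    records: list[RatingRecord] = []
    for ci, case_id in enumerate(cfg.case_ids):
        for oi, obs in enumerate(cfg.observers):
            rng = _rng(base_seed, 3, ci, oi)
            for step in (1, 2):
                median = cfg.time_median_min[oi]
                if step == 2:
                    median *= cfg.time_step2_multiplier[oi]
                t = float(median * np.exp(cfg.time_log_sd * rng.standard_normal()))
                records.append(
                    RatingRecord(observer_id=obs, case_id=case_id, step=step, time_min=t)
                )
    return records


# ---------------------------------------------------------------------------
# Per-case assembly
# ---------------------------------------------------------------------------

@dataclass
class CaseData:
    """Everything generated for one case and one organ."""

    case_id: str
    organ: str
    gt: LabelVolume
    dl: LabelVolume
    umap: UncertaintyMap  # raw (unblocked) values, block geometry recorded
    edits: dict  # (observer_id, step) -> LabelVolume
    ensemble: Optional[SoftMaxEnsemble] = None


def simulate_case(
    cfg: StudyConfig, case_index: int, keep_members: bool = False
) -> list[CaseData]:
    """Generate both organs of one case (deterministic in cfg.seed)."""
    case_id = cfg.case_ids[case_index]
    phantom_seed = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0, case_index))
    gts = make_phantom(cfg, phantom_seed)
    block = default_block(cfg.grid, cfg.block_rows, cfg.block_col_fraction)
    out = []
    for organ_index, (organ, gt) in enumerate(zip(ORGANS, gts)):
        ens_seed = np.random.SeedSequence(
            entropy=cfg.seed, spawn_key=(10 + organ_index, case_index)
        )
        ens = make_ensemble(gt, cfg, ens_seed)
        dl = ensemble_segmentation(ens, threshold=cfg.seg_threshold)
        umap = ensemble_std(ens, display_max=cfg.display_max)
        umap.block = block  # record geometry; stored values stay raw
        candidates = edit_candidates(dl, cfg)
        edits = {}
        for oi, obs in enumerate(cfg.observers):
            for step in (1, 2):
                obs_seed = np.random.SeedSequence(
                    entropy=cfg.seed, spawn_key=(20 + organ_index, case_index, oi, step)
                )
                edits[(obs, step)] = simulate_edits(
                    dl, umap, gt, cfg, step, obs_seed, candidates=candidates
                )
        out.append(
            CaseData(
                case_id=case_id,
                organ=organ,
                gt=gt,
                dl=dl,
                umap=umap,
                edits=edits,
                ensemble=ens if keep_members else None,
            )
        )
    return out


def simulate_study(cfg: StudyConfig, out_dir) -> dict:
    """Write the full study bundle to disk; returns the manifest.

    Layout: per case and organ — member SoftMax volumes, DL mask, raw and
    blocked uncertainty maps, per observer and step edited masks; plus
    ``ratings.csv`` (ratings and times) and ``manifest.json`` holding
    every true parameter.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    block = default_block(cfg.grid, cfg.block_rows, cfg.block_col_fraction)
    for case_index in range(cfg.n_cases):
        for case in simulate_case(cfg, case_index, keep_members=True):
            cdir = out_dir / case.case_id / case.organ
            cdir.mkdir(parents=True, exist_ok=True)
            for k, member in enumerate(case.ensemble.members, start=1):
                _io.write_prob(member, cdir / f"member_{k:02d}.nii.gz")
            _io.write_mask(case.dl, cdir / "dl_mask.nii.gz")
            _io.write_float_volume(case.umap.voxels, cfg.grid, cdir / "uncertainty.nii.gz")
            blocked = insert_calibration_block(case.umap, block)
            _io.write_float_volume(
                blocked.voxels, cfg.grid, cdir / "uncertainty_blocked.nii.gz"
            )
            for (obs, step), mask in case.edits.items():
                _io.write_mask(mask, cdir / f"{obs}_step{step}.nii.gz")
    records = simulate_ratings(cfg) + simulate_times(cfg)
    _io.write_ratings(records, out_dir / "ratings.csv")
    manifest = {"config": cfg.to_dict(), "organs": list(ORGANS), "cases": cfg.case_ids}
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# In-memory study analysis (histograms and metric panels)
# ---------------------------------------------------------------------------

def run_edit_histograms(
    cfg: StudyConfig,
    compute_panels: bool = False,
    panel_organs: Sequence[str] = ORGANS,
) -> dict:
    """Generate the study case by case and accumulate downstream inputs.

    Returns a dict with pooled per-(organ, step) edit histograms
    (``histograms``), and — when ``compute_panels`` — per-step metric
    panel rows against the DL reference (``panels``).
    """
    hists: dict[tuple[str, int], list[UncertaintyHistogram]] = {}
    panels: list = []
    for case_index in range(cfg.n_cases):
        for case in simulate_case(cfg, case_index):
            for (obs, step), edited in case.edits.items():
                em = edit_map(case.dl, edited)
                h = uncertainty_histogram(
                    em,
                    case.umap,
                    bin_width=cfg.bin_width,
                    observer_id=obs,
                    case_id=case.case_id,
                    organ=case.organ,
                    step=step,
                )
                hists.setdefault((case.organ, step), []).append(h)
                if compute_panels and case.organ in panel_organs:
                    panel = metric_panel(
                        case.dl,
                        edited,
                        case_id=case.case_id,
                        organ=case.organ,
                        reference_name="dl",
                        test_name=f"{obs}_step{step}",
                    )
                    row = panel.to_dict()
                    row["observer"] = obs
                    row["step"] = step
                    panels.append(row)
    pooled = {key: pool_histograms(v) for key, v in hists.items()}
    return {"histograms": pooled, "panels": panels}
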