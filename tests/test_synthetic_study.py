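"""Phantom, ensemble, edit/rating/time simulators and the on-disk bundle."""

import json

import numpy as np
import pytest
from scipy.stats import chi2_contingency

import segunc as su
from segunc.grids import ImageGrid, LabelVolume
from segunc.synthetic_study import (
    StudyConfig,
    _signed_distance_mm,
    edit_candidates,
    make_ensemble,
    make_phantom,
    simulate_case,
    simulate_edits,
    simulate_ratings,
    simulate_study,
    simulate_times,
)
from segunc.uncertainty import ensemble_segmentation, ensemble_std
from segunc.vgc import vgc_auc


class TestPhantom:
    def test_default_prostate_volume_in_range(self):
        cfg = StudyConfig(seed=1)
        prostate, rectum = make_phantom(cfg, 1)
        assert 20.0 < prostate.volume_cc < 80.0
        assert not rectum.is_empty

    def test_structures_disjoint(self, tiny_cfg):
        prostate, rectum = make_phantom(tiny_cfg, 3)
        assert not np.logical_and(prostate.mask(), rectum.mask()).any()

    def test_deterministic_given_seed(self, tiny_cfg):
        a = make_phantom(tiny_cfg, 5)
        b = make_phantom(tiny_cfg, 5)
        assert np.array_equal(a[0].voxels, b[0].voxels)
        assert np.array_equal(a[1].voxels, b[1].voxels)


class TestEnsemble:
    def _sphere(self, radius_mm=38.0):
        grid = ImageGrid(shape=(64, 96, 96), spacing_mm=(2.5, 0.9, 0.9))
        axes = [np.arange(n) * sp for n, sp in zip(grid.shape, grid.spacing_mm)]
        zc, yc, xc = np.meshgrid(*axes, indexing="ij", sparse=True)
        centre = [a[-1] / 2 for a in axes]
        r = np.sqrt((zc - centre[0]) ** 2 + (yc - centre[1]) ** 2 + (xc - centre[2]) ** 2)
        return grid, LabelVolume(grid=grid, voxels=(r <= radius_mm).astype(np.uint8))

    def test_no_perturbation_means_no_uncertainty(self, tiny_cfg):
        cfg = StudyConfig(**{**tiny_cfg.to_dict(), "field_sd_mm": 0.0, "bias_sd_mm": 0.0})
        gt, _ = make_phantom(cfg, 0)
        ens = make_ensemble(gt, cfg, 0)
        assert (ensemble_std(ens).voxels == 0).all()
        first = ens.members[0].voxels
        for m in ens.members[1:]:
            assert np.array_equal(m.voxels, first)

    def test_deep_interior_confident(self):
        grid, gt = self._sphere()
        cfg = StudyConfig(seed=2)
        ens = make_ensemble(gt, cfg, 2)
        d = _signed_distance_mm(gt.mask(), grid.spacing_mm)
        total_sd = float(np.hypot(cfg.bias_sd_mm, cfg.field_sd_mm))
        deep = d > cfg.boundary_softness_mm * np.log(99) + 3.5 * total_sd
        assert deep.any()
        for m in ens.members:
            assert m.voxels[deep].min() > 0.99
        assert ensemble_std(ens).voxels[deep].max() < 0.01

    def test_uncertainty_concentrates_at_boundary(self):
        grid, gt = self._sphere()
        cfg = StudyConfig(seed=3)
        ens = make_ensemble(gt, cfg, 3)
        std = ensemble_std(ens).voxels
        d = _signed_distance_mm(gt.mask(), grid.spacing_mm)
        peak = np.unravel_index(np.argmax(std), std.shape)
        assert abs(d[peak]) <= 2 * cfg.bias_sd_mm + cfg.boundary_softness_mm + 2.0
        # far field is certain (margin of several field standard deviations)
        assert std[d < -45].max() < 0.01
        assert np.quantile(std[np.abs(d) > 30], 0.999) < 0.02

    def test_empty_gt_rejected(self, tiny_cfg):
        empty = LabelVolume(grid=tiny_cfg.grid, voxels=np.zeros(tiny_cfg.shape, dtype=np.uint8))
        with pytest.raises(ValueError, match="empty"):
            make_ensemble(empty, tiny_cfg, 0)


class TestEdits:
    def _setup(self, cfg, case_seed=0):
        gt, _ = make_phantom(cfg, case_seed)
        ens = make_ensemble(gt, cfg, case_seed)
        dl = ensemble_segmentation(ens)
        umap = ensemble_std(ens, display_max=cfg.display_max)
        return gt, dl, umap

    def test_zero_probability_no_edits(self, tiny_cfg):
        cfg = StudyConfig(**{**tiny_cfg.to_dict(), "base_edit_prob": 1e-12})
        gt, dl, umap = self._setup(cfg)
        edited = simulate_edits(dl, umap, gt, cfg, step=1, obs_seed=0)
        assert np.array_equal(edited.voxels, dl.voxels)

    def test_edits_are_corrective_and_banded(self, tiny_cfg):
        gt, dl, umap = self._setup(tiny_cfg)
        edited = simulate_edits(dl, umap, gt, tiny_cfg, step=2, obs_seed=1)
        changed = edited.voxels != dl.voxels
        assert changed.any()
        # every edited voxel now matches the ground truth
        assert np.array_equal(edited.voxels[changed], gt.voxels[changed])
        # and lies inside the candidate band
        assert (changed & ~edit_candidates(dl, tiny_cfg)).sum() == 0

    def test_unit_multipliers_match_step1_statistically(self):
        cfg = StudyConfig(
            seed=21, n_cases=4, step2_multipliers=(1.0, 1.0, 1.0, 1.0, 1.0)
        )
        counts = {1: np.zeros(5, dtype=int), 2: np.zeros(5, dtype=int)}
        for i in range(cfg.n_cases):
            for case in simulate_case(cfg, i):
                for (obs, step), edited in case.edits.items():
                    em = su.edit_map(case.dl, edited)
                    h = su.uncertainty_histogram(em, case.umap, bin_width=cfg.bin_width)
                    counts[step] += h.counts
        table = np.array([counts[1], counts[2]])
        table = table[:, table.sum(axis=0) > 0]
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.01

    def test_probability_cap_validated(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            StudyConfig(base_edit_prob=0.6, step2_multipliers=(2.0, 1, 1, 1, 1))


class TestRatingsAndTimes:
    def test_no_noise_no_shift_identical_steps(self):
        cfg = StudyConfig(seed=4, n_cases=20, rating_noise_sd=0.0)
        records = simulate_ratings(cfg)
        r1 = [r for r in records if r.step == 1]
        r2 = {(r.observer_id, r.case_id, r.question, r.organ): r for r in records if r.step == 2}
        ratings1, ratings2 = [], []
        for r in r1:
            mate = r2[(r.observer_id, r.case_id, r.question, r.organ)]
            ratings1.append(r.rating_ordinal)
            ratings2.append(mate.rating_ordinal)
        assert ratings1 == ratings2
        assert vgc_auc(ratings1, ratings2, 5) == pytest.approx(0.5)

    def test_extreme_shift_saturates_top_category(self):
        cfg = StudyConfig(
            seed=5, n_cases=10, rating_shift={"Q1": 50.0, "Q2": 50.0, "Q3": 50.0}
        )
        records = simulate_ratings(cfg)
        step2_q3 = [r.rating_ordinal for r in records if r.step == 2 and r.question == "Q3"]
        assert set(step2_q3) == {5}

    def test_rating_scales_respected(self):
        records = simulate_ratings(StudyConfig(seed=6, n_cases=5))
        for r in records:
            scale = 4 if r.question in ("Q1", "Q2") else 5
            assert 1 <= r.rating_ordinal <= scale

    def test_times_positive_and_reduced_for_obsE(self):
        cfg = StudyConfig(seed=7)
        records = simulate_times(cfg)
        assert all(r.time_min > 0 for r in records)
        frame = su.time_comparison(records).set_index("observer")
        # 33% designed reduction; power at n=35, log-sd 0.25 is essentially 1
        rejections = 0
        for rep in range(10):
            f = su.time_comparison(simulate_times(StudyConfig(seed=100 + rep)))
            rejections += f.set_index("observer").loc["obsE", "p_value"] < 0.05
        assert rejections >= 9
        assert frame.loc["obsC", "median_step1_min"] == pytest.approx(4.5, rel=0.15)


class TestBundle:
    def test_bundle_layout_and_round_trip(self, tiny_cfg, tmp_path):
        simulate_study(tiny_cfg, tmp_path / "study")
        manifest = json.loads((tmp_path / "study" / "manifest.json").read_text())
        assert manifest["config"]["n_cases"] == tiny_cfg.n_cases
        case_dir = tmp_path / "study" / "pat01" / "prostate_ctv"
        members = sorted(case_dir.glob("member_*.nii.gz"))
        assert len(members) == tiny_cfg.K
        # disk artifacts equal the in-memory generation
        cases = simulate_case(tiny_cfg, 0, keep_members=True)
        dl = su.read_mask(case_dir / "dl_mask.nii.gz")
        assert np.array_equal(dl.voxels, cases[0].dl.voxels)
        edited = su.read_mask(case_dir / "obsB_step2.nii.gz")
        assert np.array_equal(edited.voxels, cases[0].edits[("obsB", 2)].voxels)
        raw, _ = su.io.read_float_volume(case_dir / "uncertainty.nii.gz")
        assert np.allclose(raw, cases[0].umap.voxels, atol=1e-6)
        records = su.read_ratings(tmp_path / "study" / "ratings.csv")
        n_rating_rows = tiny_cfg.n_cases * len(tiny_cfg.observers) * 2 * 4  # Q1+Q2+2xQ3
        n_time_rows = tiny_cfg.n_cases * len(tiny_cfg.observers) * 2
        assert len(records) == n_rating_rows + n_time_rows

    def test_bundle_reproducible(self, tiny_cfg, tmp_path):
        simulate_study(tiny_cfg, tmp_path / "a")
        simulate_study(tiny_cfg, tmp_path / "b")
        for f in sorted((tmp_path / "a").rglob("*.nii.gz"))[:6]:
            twin = tmp_path / "b" / f.relative_to(tmp_path / "a")
            assert f.read_bytes() == twin.read_bytes()
        assert (tmp_path / "a" / "ratings.csv").read_text() == (
            tmp_path / "b" / "ratings.csv"
        ).read_text()
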