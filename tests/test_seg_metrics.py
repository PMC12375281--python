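"""Geometric metric panel: examples, degenerate contracts, oracle agreement."""

import numpy as np
import pytest

import segunc as su
from segunc.grids import ImageGrid

from conftest import cube_mask, make_label, random_mask
from oracles import apl_oracle, surface_mask_oracle, surface_metrics_oracle


@pytest.fixture
def iso(unit_grid):
    return unit_grid


def two_voxels_apart(grid, dist_vox):
    a = np.zeros(grid.shape, dtype=np.uint8)
    b = np.zeros(grid.shape, dtype=np.uint8)
    a[8, 8, 8] = 1
    b[8, 8, 8 + dist_vox] = 1
    return make_label(grid, a), make_label(grid, b)


class TestDice:
    def test_identical(self, iso):
        m = make_label(iso, cube_mask(iso.shape, (2, 2, 2), (8, 8, 8)))
        assert su.dice(m, m) == 1.0

    def test_disjoint(self, iso):
        a = make_label(iso, cube_mask(iso.shape, (0, 0, 0), (4, 4, 4)))
        b = make_label(iso, cube_mask(iso.shape, (8, 8, 8), (12, 12, 12)))
        assert su.dice(a, b) == 0.0

    def test_partial_overlap(self, iso):
        # |A| = |B| = 100, |A n B| = 80 -> 160/200
        a = np.zeros(iso.shape, dtype=np.uint8)
        b = np.zeros(iso.shape, dtype=np.uint8)
        a.flat[:100] = 1
        b.flat[20:120] = 1
        assert su.dice(make_label(iso, a), make_label(iso, b)) == pytest.approx(0.8)

    def test_empty_conventions(self, iso):
        empty = make_label(iso, np.zeros(iso.shape))
        full = make_label(iso, cube_mask(iso.shape, (1, 1, 1), (3, 3, 3)))
        assert su.dice(empty, empty) == 1.0
        assert su.dice(empty, full) == 0.0


class TestSurface:
    def test_cube_surface_count(self, iso):
        m = make_label(iso, cube_mask(iso.shape, (4, 4, 4), (7, 7, 7)))
        assert int(su.extract_surface(m).sum()) == 26  # 3^3 minus the centre

    def test_single_voxel(self, iso):
        m = np.zeros(iso.shape)
        m[5, 5, 5] = 1
        assert int(su.extract_surface(make_label(iso, m)).sum()) == 1

    def test_full_volume_gives_outer_shell(self):
        grid = ImageGrid(shape=(4, 4, 4), spacing_mm=(1, 1, 1))
        m = make_label(grid, np.ones(grid.shape))
        surface = su.extract_surface(m)
        assert int(surface.sum()) == 4**3 - 2**3  # all but the interior 2^3

    def test_matches_shift_oracle(self, iso):
        rng = np.random.default_rng(17)
        m = random_mask(iso.shape, 0.4, rng)
        assert np.array_equal(
            su.extract_surface(make_label(iso, m)), surface_mask_oracle(m)
        )


class TestSurfaceDice:
    def test_identical(self, iso):
        m = make_label(iso, cube_mask(iso.shape, (3, 3, 3), (9, 9, 9)))
        assert su.surface_dice(m, m) == 1.0

    def test_two_voxels_2mm_tau1_then_tau2(self, iso):
        a, b = two_voxels_apart(iso, 2)
        assert su.surface_dice(a, b, tau_mm=1.0) == 0.0
        assert su.surface_dice(a, b, tau_mm=2.0) == 1.0

    def test_empty_is_nan(self, iso):
        empty = make_label(iso, np.zeros(iso.shape))
        full = make_label(iso, cube_mask(iso.shape, (1, 1, 1), (3, 3, 3)))
        assert np.isnan(su.surface_dice(empty, full))


class TestHausdorffAsd:
    def test_identical_zero(self, iso):
        m = make_label(iso, cube_mask(iso.shape, (3, 3, 3), (9, 9, 9)))
        assert su.hausdorff(m, m) == 0.0
        assert su.average_surface_distance(m, m) == 0.0

    def test_point_pair_distance(self, iso):
        a, b = two_voxels_apart(iso, 2)
        assert su.hausdorff(a, b) == pytest.approx(2.0)
        assert su.average_surface_distance(a, b) == pytest.approx(2.0)

    def test_nested_cubes_match_oracle(self, iso):
        a = make_label(iso, cube_mask(iso.shape, (6, 6, 6), (9, 9, 9)))  # 3^3
        b = make_label(iso, cube_mask(iso.shape, (5, 5, 5), (10, 10, 10)))  # 5^3
        _, hd, asd = surface_metrics_oracle(a.voxels, b.voxels, iso.spacing_mm, 1.0)
        assert su.hausdorff(a, b) == pytest.approx(hd, abs=1e-9)
        assert su.average_surface_distance(a, b) == pytest.approx(asd, abs=1e-9)


class TestVolumeMetrics:
    def test_halved_volume(self, iso):
        a = np.zeros(iso.shape)
        b = np.zeros(iso.shape)
        a.flat[:1000] = 1
        b.flat[:500] = 1
        v_ref, v_test, diff, ratio = su.volume_metrics(make_label(iso, a), make_label(iso, b))
        assert (v_ref, v_test, diff, ratio) == pytest.approx((1.0, 0.5, -0.5, 0.5))

    def test_identical(self, iso):
        m = make_label(iso, cube_mask(iso.shape, (2, 2, 2), (6, 6, 6)))
        _, _, diff, ratio = su.volume_metrics(m, m)
        assert diff == 0.0 and ratio == 1.0

    def test_empty_reference_ratio_undefined(self, iso):
        empty = make_label(iso, np.zeros(iso.shape))
        full = make_label(iso, cube_mask(iso.shape, (1, 1, 1), (3, 3, 3)))
        assert np.isnan(su.volume_metrics(empty, full)[3])


class TestAddedPathLength:
    def test_identical_zero(self, iso):
        m = make_label(iso, cube_mask(iso.shape, (3, 3, 3), (9, 9, 9)))
        assert su.added_path_length(m, m) == 0.0

    def test_disjoint_square_on_one_slice(self, iso):
        ref = cube_mask(iso.shape, (5, 2, 2), (8, 5, 5))
        edited = ref.copy()
        edited[6, 10:13, 10:13] = 1  # disjoint 3x3 square, all distances > 1
        apl = su.added_path_length(make_label(iso, ref), make_label(iso, edited), tau_mm=1.0)
        assert apl == pytest.approx(8.0)  # 8 boundary pixels x 1 mm

    def test_reference_empty_slice_counts_full_boundary(self, iso):
        ref = np.zeros(iso.shape, dtype=np.uint8)
        edited = np.zeros(iso.shape, dtype=np.uint8)
        edited[4, 5:8, 5:8] = 1
        apl = su.added_path_length(make_label(iso, ref), make_label(iso, edited))
        assert apl == pytest.approx(8.0)

    def test_matches_oracle_random(self, iso):
        rng = np.random.default_rng(23)
        ref = random_mask(iso.shape, 0.3, rng)
        edited = random_mask(iso.shape, 0.3, rng)
        expected = apl_oracle(ref, edited, iso.spacing_mm, 1.0)
        got = su.added_path_length(make_label(iso, ref), make_label(iso, edited), 1.0)
        assert got == pytest.approx(expected, abs=1e-9)


class TestPanelAndProperties:
    def test_identical_masks_panel(self, iso):
        m = make_label(iso, cube_mask(iso.shape, (3, 3, 3), (9, 9, 9)))
        p = su.metric_panel(m, m)
        assert (p.dice, p.surface_dice, p.hausdorff_mm, p.asd_mm) == (1.0, 1.0, 0.0, 0.0)
        assert p.volume_diff_cc == 0.0 and p.apl_mm == 0.0

    def test_empty_test_mask_panel(self, iso):
        ref = make_label(iso, cube_mask(iso.shape, (3, 3, 3), (9, 9, 9)))
        empty = make_label(iso, np.zeros(iso.shape))
        p = su.metric_panel(ref, empty)
        assert p.dice == 0.0
        assert np.isnan(p.surface_dice) and np.isnan(p.hausdorff_mm) and np.isnan(p.asd_mm)
        assert p.volume_ref_cc > 0 and p.volume_test_cc == 0.0

    def test_symmetry(self, iso):
        rng = np.random.default_rng(31)
        a = make_label(iso, random_mask(iso.shape, 0.35, rng))
        b = make_label(iso, random_mask(iso.shape, 0.35, rng))
        assert su.dice(a, b) == su.dice(b, a)
        assert su.surface_dice(a, b) == pytest.approx(su.surface_dice(b, a))
        assert su.hausdorff(a, b) == pytest.approx(su.hausdorff(b, a))
        assert su.average_surface_distance(a, b) == pytest.approx(
            su.average_surface_distance(b, a)
        )

    def test_monotonicity_in_tolerance(self, iso):
        rng = np.random.default_rng(37)
        a = make_label(iso, random_mask(iso.shape, 0.3, rng))
        b = make_label(iso, random_mask(iso.shape, 0.3, rng))
        taus = [0.5, 1.0, 2.0, 4.0]
        sdice = [su.surface_dice(a, b, t) for t in taus]
        apl = [su.added_path_length(a, b, t) for t in taus]
        assert all(x <= y + 1e-12 for x, y in zip(sdice, sdice[1:]))
        assert all(x >= y - 1e-12 for x, y in zip(apl, apl[1:]))

    def test_spacing_scaling(self):
        g1 = ImageGrid(shape=(12, 12, 12), spacing_mm=(1, 1, 1))
        g2 = ImageGrid(shape=(12, 12, 12), spacing_mm=(2, 2, 2))
        rng = np.random.default_rng(41)
        ma = random_mask(g1.shape, 0.3, rng)
        mb = random_mask(g1.shape, 0.3, rng)
        a1, b1 = make_label(g1, ma), make_label(g1, mb)
        a2, b2 = make_label(g2, ma), make_label(g2, mb)
        assert su.hausdorff(a2, b2) == pytest.approx(2 * su.hausdorff(a1, b1))
        assert su.average_surface_distance(a2, b2) == pytest.approx(
            2 * su.average_surface_distance(a1, b1)
        )
        assert su.added_path_length(a2, b2, 2.0) == pytest.approx(
            2 * su.added_path_length(a1, b1, 1.0)
        )
        assert a2.volume_cc == pytest.approx(8 * a1.volume_cc)
        assert su.dice(a2, b2) == su.dice(a1, b1)
        assert su.surface_dice(a2, b2, 2.0) == pytest.approx(su.surface_dice(a1, b1, 1.0))

    def test_grid_mismatch_rejected(self, iso):
        other = ImageGrid(shape=(16, 16, 16), spacing_mm=(2, 1, 1))
        a = make_label(iso, np.zeros(iso.shape))
        b = make_label(other, np.zeros(other.shape))
        with pytest.raises(ValueError, match="incompatible"):
            su.dice(a, b)
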