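import numpy as np
import pytest

from crumbct import (
    GSVHistogram,
    VolumeMeta,
    VoxelVolume,
    balanced_histogram_threshold,
    band_threshold,
    binary_opening,
    compute_histogram,
    fill_holes,
    label_components,
    mask_difference,
)
from crumbct.phantom import PHASE_MATRIX, PHASE_PORE
from crumbct.segmentation import ball_element

from conftest import brute_force_opening, digitized_sphere, make_mask


def make_volume(values):
    values = np.asarray(values, dtype=np.int16)
    return VoxelVolume(meta=VolumeMeta(shape=values.shape), values=values)


class TestHistogram:
    def test_constant_volume_single_bin(self):
        vol = make_volume(np.full((3, 3, 3), -500))
        hist = compute_histogram(vol, bin_width=50)
        occupied = np.flatnonzero(hist.counts)
        assert len(occupied) == 1
        lo = hist.bin_edges[occupied[0]]
        assert lo <= -500 < lo + 50

    def test_bimodal_counts(self):
        values = np.array([-1100, -500] * 4).reshape(2, 2, 2)
        hist = compute_histogram(make_volume(values), bin_width=100)
        assert sorted(hist.counts[hist.counts > 0].tolist()) == [4, 4]

    def test_counts_conserve_voxels(self):
        rng = np.random.default_rng(0)
        vol = make_volume(rng.integers(-2000, 0, size=(4, 5, 6)))
        hist = compute_histogram(vol, bin_width=7)
        assert hist.counts.sum() == 4 * 5 * 6

    def test_empty_region_rejected(self):
        vol = make_volume(np.zeros((2, 2, 2)))
        empty = make_mask(np.zeros((2, 2, 2), dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            compute_histogram(vol, bin_width=10, region=empty)


class TestBalancedThreshold:
    def edges(self, n):
        return np.arange(n + 1)

    def test_symmetric_bimodal_returns_middle_bin(self):
        hist = GSVHistogram(bin_edges=self.edges(5), counts=[5, 0, 0, 0, 5])
        assert balanced_histogram_threshold(hist) == 2

    def test_symmetric_unimodal_returns_center_bin(self):
        hist = GSVHistogram(bin_edges=self.edges(9), counts=[1, 2, 3, 4, 10, 4, 3, 2, 1])
        assert balanced_histogram_threshold(hist) == 4

    def test_asymmetric_hand_executed_oracle(self):
        # hand execution of the balance loop on [9,1,0,0,2]:
        # [0..4] left 10 > right 2 -> drop left; [1..4] left 1 < right 2 ->
        # drop right; [1..3] left 1 > right 0 -> drop left; [2..3] balanced
        # two-bin range -> drop right; collapses to bin 2
        hist = GSVHistogram(bin_edges=self.edges(5), counts=[9, 1, 0, 0, 2])
        assert balanced_histogram_threshold(hist) == 2

    def test_all_zero_rejected(self):
        hist = GSVHistogram(bin_edges=self.edges(3), counts=[0, 0, 0])
        with pytest.raises(ValueError):
            balanced_histogram_threshold(hist)

    def test_threshold_separates_phantom_phases(self, small_phantom):
        _, vol, truth = small_phantom
        hist = compute_histogram(vol, bin_width=25)
        thr = balanced_histogram_threshold(hist)
        assert -1000 < thr < -600  # between the pore and matrix modes


class TestBandThreshold:
    def test_printed_band_on_representative_values(self):
        vol = make_volume(np.array([-800, -500, -100]).reshape(3, 1, 1))
        mask = band_threshold(vol, -750, -250)
        assert mask.grid.ravel().tolist() == [False, True, False]

    def test_full_range_band_is_all_true(self):
        rng = np.random.default_rng(1)
        vol = make_volume(rng.integers(-32768, 32768, size=(3, 3, 3)))
        assert band_threshold(vol, -32768, 32767).grid.all()

    def test_band_endpoints_are_inclusive(self):
        vol = make_volume(np.array([-750, -250]).reshape(2, 1, 1))
        assert band_threshold(vol, -750, -250).grid.all()

    def test_phantom_phase_capture_rates(self, small_phantom):
        _, vol, truth = small_phantom
        pore_mask = band_threshold(vol, -1250, -1000)
        matrix_mask = band_threshold(vol, -750, -250)
        pore = truth.phase_grid == PHASE_PORE
        matrix = truth.phase_grid == PHASE_MATRIX
        assert pore_mask.grid[pore].mean() >= 0.99
        assert pore_mask.grid[matrix].mean() <= 0.005
        assert matrix_mask.grid[matrix].mean() >= 0.997


class TestFillHoles:
    def test_enclosed_cavity_filled(self):
        grid = np.zeros((7, 7, 7), dtype=bool)
        grid[1:6, 1:6, 1:6] = True
        grid[2:5, 2:5, 2:5] = False  # hollow 3^3 interior
        filled = fill_holes(make_mask(grid))
        expected = np.zeros((7, 7, 7), dtype=bool)
        expected[1:6, 1:6, 1:6] = True
        assert np.array_equal(filled.grid, expected)

    def test_vented_cavity_untouched(self):
        grid = np.zeros((7, 7, 7), dtype=bool)
        grid[1:6, 1:6, 1:6] = True
        grid[2:5, 2:5, 2:5] = False
        grid[3, 3, 0:3] = False  # 1-voxel channel from cavity to a face
        filled = fill_holes(make_mask(grid), background_connectivity=6)
        assert np.array_equal(filled.grid, grid)

    def test_all_false_identity(self):
        grid = np.zeros((4, 4, 4), dtype=bool)
        assert not fill_holes(make_mask(grid)).grid.any()

    def test_monotone_and_idempotent(self, small_phantom):
        _, vol, _ = small_phantom
        mask = band_threshold(vol, -750, -250)
        filled = fill_holes(mask)
        assert (filled.grid | mask.grid).sum() == filled.count  # superset
        assert np.array_equal(fill_holes(filled).grid, filled.grid)


class TestMaskDifference:
    def test_single_voxel_pore(self):
        filled = np.ones((3, 3, 3), dtype=bool)
        matrix = filled.copy()
        matrix[1, 1, 1] = False
        diff = mask_difference(make_mask(filled), make_mask(matrix))
        assert diff.count == 1 and diff.grid[1, 1, 1]

    def test_equal_masks_give_empty(self):
        grid = np.ones((3, 3, 3), dtype=bool)
        assert mask_difference(make_mask(grid), make_mask(grid)).count == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            mask_difference(make_mask(np.ones((2, 2, 2), bool)),
                            make_mask(np.ones((3, 3, 3), bool)))


class TestOpening:
    def test_ball_element_radius_convention(self):
        elem = ball_element(3.0)
        assert elem.shape == (7, 7, 7)
        assert elem[3, 3, 0] and elem[3, 3, 6]  # centers at distance 3 included
        assert not elem[0, 0, 0]

    def test_sphere_matches_bruteforce(self):
        grid = digitized_sphere(6)
        opened = binary_opening(make_mask(grid), ball_radius_vox=3.0)
        assert np.array_equal(opened.grid, brute_force_opening(grid, 3.0))

    def test_thin_rod_removed(self):
        grid = np.zeros((9, 9, 20), dtype=bool)
        grid[4, 4, :] = True
        assert binary_opening(make_mask(grid), ball_radius_vox=3.0).count == 0

    def test_dumbbell_neck_cut(self):
        # two radius-5 spheres joined by a radius-1 neck
        grid = np.zeros((13, 13, 36), dtype=bool)
        ax = np.arange(13) - 6
        X, Y, Z = np.meshgrid(ax, ax, np.arange(36), indexing="ij")
        grid |= (X**2 + Y**2 + (Z - 8) ** 2) <= 25
        grid |= (X**2 + Y**2 + (Z - 27) ** 2) <= 25
        grid |= (X**2 + Y**2 <= 1.0) & (Z >= 8) & (Z <= 27)
        opened = binary_opening(make_mask(grid), ball_radius_vox=3.0)
        assert np.array_equal(opened.grid, brute_force_opening(grid, 3.0))
        labels = label_components(opened, connectivity=26)
        assert labels.n_labels == 2

    def test_antiextensive_and_idempotent(self):
        rng = np.random.default_rng(5)
        from scipy import ndimage

        grid = ndimage.gaussian_filter(rng.random((30, 30, 30)), 3) > 0.5
        opened = binary_opening(make_mask(grid), ball_radius_vox=2.0)
        assert not (opened.grid & ~grid).any()
        twice = binary_opening(opened, ball_radius_vox=2.0)
        assert np.array_equal(twice.grid, opened.grid)


class TestLabeling:
    def test_two_disjoint_voxels(self):
        grid = np.zeros((5, 5, 5), dtype=bool)
        grid[0, 0, 0] = grid[4, 4, 4] = True
        assert label_components(make_mask(grid)).n_labels == 2

    def test_corner_touching_connectivity_contract(self):
        grid = np.zeros((4, 4, 4), dtype=bool)
        grid[1, 1, 1] = grid[2, 2, 2] = True
        assert label_components(make_mask(grid), connectivity=26).n_labels == 1
        assert label_components(make_mask(grid), connectivity=6).n_labels == 2

    def test_labels_partition_mask(self, small_phantom):
        _, vol, _ = small_phantom
        mask = band_threshold(vol, -1250, -1000)
        labels = label_components(mask)
        assert (labels.grid > 0).sum() == mask.count
        present = np.unique(labels.grid)
        assert present[0] == 0
        assert np.array_equal(present[1:], np.arange(1, labels.n_labels + 1))

    def test_raster_order_labeling(self):
        grid = np.zeros((6, 3, 3), dtype=bool)
        grid[4, 1, 1] = True  # later in raster order
        grid[1, 1, 1] = True
        labels = label_components(make_mask(grid))
        assert labels.grid[1, 1, 1] == 1
        assert labels.grid[4, 1, 1] == 2

    def test_separated_spheres_count(self):
        # three well-separated spheres -> exactly 3 labels
        grid = np.zeros((40, 14, 14), dtype=bool)
        ax = np.arange(14) - 6.5
        for k, cx in enumerate([6, 19, 32]):
            X = np.arange(40)[:, None, None] - cx
            Y, Z = np.meshgrid(ax, ax, indexing="ij")
            grid |= (X**2 + Y[None] ** 2 + Z[None] ** 2) <= 16
        assert label_components(make_mask(grid)).n_labels == 3
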