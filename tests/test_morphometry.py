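import math

import numpy as np
import pytest

from crumbct import (
    VolumeMeta,
    VoxelVolume,
    eq_diameter,
    extract_cube_roi,
    label_components,
    local_pore_fraction,
    measure_labels,
    porosity,
    size_distribution,
    summarize,
)
from crumbct.morphometry import feret_directions
from crumbct.phantom import PHASE_PORE

from conftest import digitized_sphere, make_mask

SP = 0.16


def measure_grid(grid, spacing=(SP, SP, SP)):
    labels = label_components(make_mask(grid, spacing=spacing))
    return measure_labels(labels)


class TestMeasureLabels:
    def test_single_voxel_closed_form(self):
        grid = np.zeros((5, 5, 5), dtype=bool)
        grid[2, 2, 2] = True
        (s,) = measure_grid(grid)
        assert s.volume_mm3 == pytest.approx(SP**3)  # 0.004096 mm^3
        assert s.eq_diameter_mm == pytest.approx((6 * SP**3 / math.pi) ** (1 / 3))
        # Feret of a cube of side 0.16 over the direction set
        assert SP - 1e-9 <= s.width_mm <= s.length_mm <= SP * math.sqrt(3) + 1e-9
        assert s.centroid_mm == pytest.approx((2.5 * SP,) * 3)
        assert not s.touches_border

    @pytest.mark.parametrize("radius_vox", [5, 8, 12])
    def test_digitized_sphere_calibration(self, radius_vox):
        (s,) = measure_grid(digitized_sphere(radius_vox))
        r_mm = radius_vox * SP
        true_volume = 4 / 3 * math.pi * r_mm**3
        true_area = 4 * math.pi * r_mm**2
        assert abs(s.volume_mm3 - true_volume) / true_volume < 0.05
        assert abs(s.area_mm2 - true_area) / true_area < 0.05
        assert abs(s.eq_diameter_mm - 2 * r_mm) / (2 * r_mm) < 0.03
        diag = SP * math.sqrt(3)
        assert abs(s.length_mm - 2 * r_mm) <= diag
        assert abs(s.width_mm - 2 * r_mm) <= diag

    def test_rod_feret_extents(self):
        grid = np.zeros((7, 7, 11), dtype=bool)
        grid[3, 3, 3:8] = True  # 1x1x5 voxel rod
        (s,) = measure_grid(grid)
        # corner convention: the rod spans 5 voxels = 0.80 mm along z; the
        # largest extent over any direction is at most the box diagonal
        box_diag = SP * math.sqrt(5**2 + 1 + 1)
        assert 5 * SP - 1e-9 <= s.length_mm <= box_diag + 1e-9
        assert SP - 1e-9 <= s.width_mm <= SP * math.sqrt(2) + 1e-9

    def test_feret_invariant_under_axis_rotation(self):
        grid = np.zeros((14, 14, 14), dtype=bool)
        grid[3:11, 5:9, 6:8] = True  # 8x4x2 box
        (s1,) = measure_grid(grid)
        (s2,) = measure_grid(grid.transpose(2, 0, 1))
        assert s1.width_mm <= s1.length_mm
        assert s1.length_mm == pytest.approx(s2.length_mm, rel=0.02)
        assert s1.width_mm == pytest.approx(s2.width_mm, rel=0.02)

    def test_border_touching_flagged(self):
        grid = np.zeros((4, 4, 4), dtype=bool)
        grid[0, 1, 1] = grid[1, 1, 1] = True
        (s,) = measure_grid(grid)
        assert s.touches_border

    def test_empty_label_map(self):
        assert measure_grid(np.zeros((3, 3, 3), dtype=bool)) == []

    def test_direction_set_is_unit_and_fixed(self):
        d1 = feret_directions(128)
        d2 = feret_directions(128)
        assert np.array_equal(d1, d2)
        assert np.allclose(np.linalg.norm(d1, axis=1), 1.0)


class TestPorosity:
    def test_simple_ratio(self):
        sample = np.zeros((10, 10, 10), dtype=bool)
        sample[:, :, :] = True
        pores = np.zeros_like(sample)
        pores.ravel()[:250] = True
        assert porosity(make_mask(pores), make_mask(sample)) == pytest.approx(25.0)

    def test_empty_pores(self):
        sample = np.ones((3, 3, 3), dtype=bool)
        assert porosity(make_mask(np.zeros_like(sample)), make_mask(sample)) == 0.0

    def test_empty_sample_rejected(self):
        empty = make_mask(np.zeros((2, 2, 2), dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            porosity(empty, empty)

    def test_scale_free_under_spacing_change(self):
        rng = np.random.default_rng(2)
        sample = np.ones((6, 6, 6), dtype=bool)
        pores = rng.random((6, 6, 6)) < 0.3
        p1 = porosity(make_mask(pores, spacing=(0.16,) * 3),
                      make_mask(sample, spacing=(0.16,) * 3))
        p2 = porosity(make_mask(pores, spacing=(1.0, 2.0, 0.5)),
                      make_mask(sample, spacing=(1.0, 2.0, 0.5)))
        assert p1 == p2


class TestSummary:
    def test_two_pore_means(self):
        grid = np.zeros((30, 12, 12), dtype=bool)
        ax = np.arange(12) - 5.5
        Y, Z = np.meshgrid(ax, ax, indexing="ij")
        for cx, r in [(7, 3.2), (21, 4.2)]:
            X = np.arange(30)[:, None, None] - cx
            grid |= (X**2 + Y[None] ** 2 + Z[None] ** 2) <= r**2
        labels = label_components(make_mask(grid))
        stats = measure_labels(labels)
        sample = make_mask(np.ones_like(grid))
        summary = summarize(stats, make_mask(grid), sample)
        assert summary.pore_count == 2
        assert summary.mean_volume_mm3 == pytest.approx(
            np.mean([s.volume_mm3 for s in stats])
        )

    def test_sample_volume_unit_conversion(self):
        grid = np.ones((100, 100, 100), dtype=bool)  # 1e6 voxels
        sample = make_mask(grid)
        summary = summarize([], make_mask(np.zeros_like(grid)), sample)
        assert summary.sample_volume_mL == pytest.approx(4.096)
        assert math.isnan(summary.mean_volume_mm3)
        assert summary.porosity_pct == 0.0


class TestSizeDistribution:
    def test_hand_binned_diameters(self):
        class S:
            def __init__(self, d):
                self.eq_diameter_mm = d

        dist = size_distribution([S(1.5), S(3.0), S(7.0)])
        assert dist.counts.tolist() == [1, 1, 0, 1, 0]
        assert dist.percentages == pytest.approx([100 / 3, 100 / 3, 0, 100 / 3, 0])
        assert dist.overflow_count == 0

    def test_empty_input(self):
        dist = size_distribution([])
        assert dist.counts.sum() == 0 and dist.overflow_count == 0

    def test_overflow_reported_and_count_conserved(self):
        class S:
            def __init__(self, d):
                self.eq_diameter_mm = d

        dist = size_distribution([S(0.5), S(11.0), S(10.0)])
        assert dist.counts.sum() + dist.overflow_count == 3
        assert dist.overflow_count == 2

    def test_phantom_small_pores_land_in_first_bin(self):
        # all generated sphere diameters < 2 mm -> everything in the 0-2 bin
        from crumbct import PhantomSpec, generate_bun_phantom

        spec = PhantomSpec(body_semi_axes_mm=(5, 5, 4), pore_count=12,
                           pore_radius_median_mm=0.45, pore_radius_log_sd=0.1, seed=6)
        vol, truth = generate_bun_phantom(spec)
        assert all(2 * r < 2.0 for _, r in truth.pore_spheres)
        mask = make_mask(truth.phase_grid == PHASE_PORE)
        stats = measure_labels(label_components(mask))
        dist = size_distribution(stats)
        # voxelization may nudge a diameter near an edge by one bin
        assert dist.counts[0] >= len(stats) - 1
        assert dist.counts[2:].sum() == 0


class TestCubeRoi:
    def make_volume(self, shape=(60, 60, 60), fill=-500):
        return VoxelVolume(meta=VolumeMeta(shape=shape),
                           values=np.full(shape, fill, dtype=np.int16))

    def test_side_one_single_voxel(self):
        vol = self.make_volume()
        roi = extract_cube_roi(vol, (10, 20, 30), side_vox=1)
        assert roi.meta.shape == (1, 1, 1)
        assert roi.values[0, 0, 0] == vol.values[10, 20, 30]

    def test_default_side_45(self):
        vol = self.make_volume((90, 90, 90))
        roi = extract_cube_roi(vol, (45, 45, 45))
        assert roi.meta.shape == (45, 45, 45)
        assert roi.meta.spacing_mm == vol.meta.spacing_mm

    def test_out_of_bounds_names_axis(self):
        vol = self.make_volume((50, 90, 90))
        with pytest.raises(ValueError, match="axis 0"):
            extract_cube_roi(vol, (10, 45, 45))

    def test_overlapping_cubes_agree_on_intersection(self):
        rng = np.random.default_rng(8)
        values = rng.integers(-2000, 0, size=(60, 60, 60)).astype(np.int16)
        vol = VoxelVolume(meta=VolumeMeta(shape=values.shape), values=values)
        a = extract_cube_roi(vol, (25, 25, 25), side_vox=21)
        b = extract_cube_roi(vol, (30, 25, 25), side_vox=21)
        # a spans x 15..35, b spans x 20..40; overlap is 15 voxels wide
        assert np.array_equal(a.values[5:, :, :], b.values[:16, :, :])


class TestLocalPoreFraction:
    def test_pure_matrix_cube(self):
        vol = VoxelVolume(meta=VolumeMeta(shape=(5, 5, 5)),
                          values=np.full((5, 5, 5), -500, dtype=np.int16))
        assert local_pore_fraction(vol) == 0.0

    def test_pure_pore_cube(self):
        vol = VoxelVolume(meta=VolumeMeta(shape=(5, 5, 5)),
                          values=np.full((5, 5, 5), -1100, dtype=np.int16))
        assert local_pore_fraction(vol) == 100.0

    def test_center_vs_skin_contrast(self):
        # denser center: fewer pore-band voxels in the central cube than in
        # one near the skin
        from crumbct import PhantomSpec, generate_bun_phantom
        from crumbct.morphometry import extract_cube_roi

        spec = PhantomSpec(body_semi_axes_mm=(7, 7, 6), pore_count=0, seed=0)
        vol, truth = generate_bun_phantom(spec)
        rng = np.random.default_rng(13)
        values = vol.values.copy()
        # carve extra pores only outside the central third (a crumb/skin shell)
        nx, ny, nz = vol.meta.shape
        X, Y, Z = np.meshgrid(*(np.arange(n) for n in (nx, ny, nz)), indexing="ij")
        center = tuple(n // 2 for n in (nx, ny, nz))
        rad2 = ((X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2)
        shell = (truth.phase_grid == 1) & (rad2 > 15**2)
        carve = shell & (rng.random(values.shape) < 0.25)
        values[carve] = -1100
        vol2 = VoxelVolume(meta=vol.meta, values=values)
        cube_center = extract_cube_roi(vol2, center, side_vox=15)
        skin_center = (center[0] + 22, center[1], center[2])
        cube_skin = extract_cube_roi(vol2, skin_center, side_vox=15)
        assert local_pore_fraction(cube_center) < local_pore_fraction(cube_skin)


def test_eq_diameter_closed_form():
    assert eq_diameter(math.pi / 6) == pytest.approx(1.0)
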