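"""Windowing, masking, resampling, node filtering, slice choice, augmentation."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from metasurv.preprocessing import (AugmentConfig, ExcludedPatient,
                                    PreprocessConfig, augment, center_on_mask,
                                    filter_small_nodes, mask_with_gtv,
                                    preprocess_record, resample_isotropic,
                                    select_max_tumor_slice, window_rescale)
from metasurv.synthetic import PatientRecord

CFG = PreprocessConfig()


def _sphere(shape, radius, center=None):
    center = center or tuple(s // 2 for s in shape)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return (dist2 <= radius ** 2).astype(np.uint8)


def _record(image, primary, nodes=(), spacing=(1.0, 1.0, 1.0)):
    return PatientRecord(
        patient_id="P0", image=image.astype(np.float32),
        gtv_primary_mask=primary, gtv_node_masks=list(nodes),
        voxel_spacing=spacing, age_years=60.0, sex="M", site="larynx",
        overall_stage="III", t_stage="T2", n_stage="N1",
        gtv_total_volume_cm3=float(primary.sum() * np.prod(spacing) / 1000) or 1.0,
        event=0, time_years=3.0)


class TestWindowRescale:
    @pytest.mark.parametrize("hu,expected", [
        (500.0, 1.0), (-500.0, -1.0), (0.0, 0.0), (700.0, 1.0), (-900.0, -1.0),
    ])
    def test_endpoints_midpoint_clipping(self, hu, expected):
        out = window_rescale(np.array([hu]), CFG)
        assert out[0] == pytest.approx(expected)

    @given(st.lists(st.floats(-2000, 2000), min_size=2, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, values):
        x = np.array(values)
        y = window_rescale(x, CFG)
        assert np.all(y >= -1) and np.all(y <= 1)
        order = np.argsort(x)
        assert np.all(np.diff(y[order]) >= -1e-6)

    def test_idempotent_on_windowed_input(self):
        x = np.linspace(-500, 500, 11)
        once = window_rescale(x, CFG)
        # feeding back rescaled values through an identity window
        unit = replace(CFG, hu_window=(-1.0, 1.0))
        np.testing.assert_allclose(window_rescale(once, unit), once, atol=1e-6)


class TestMaskWithGtv:
    def setup_method(self):
        self.img = np.zeros((8, 8, 8), dtype=np.float32)
        self.mask = np.zeros((8, 8, 8), dtype=np.uint8)
        self.mask[3:6, 3:6, 3:6] = 1
        self.img[4, 4, 4] = 0.3

    def test_binary_mode_inside_above_background_is_plus_one(self):
        cfg = replace(CFG, input_mode="binary")
        out = mask_with_gtv(self.img, [self.mask], cfg)
        assert out[4, 4, 4] == 1.0

    def test_binary_mode_outside_is_minus_one(self):
        cfg = replace(CFG, input_mode="binary")
        out = mask_with_gtv(self.img, [self.mask], cfg)
        assert out[0, 0, 0] == -1.0
        assert set(np.unique(out)) <= {-1.0, 1.0}

    def test_standard_mode_keeps_values_inside_only(self):
        out = mask_with_gtv(self.img, [self.mask], CFG)
        assert out[4, 4, 4] == pytest.approx(0.3)
        assert out[0, 0, 0] == -1.0
        outside = np.ones_like(out, dtype=bool)
        outside[3:6, 3:6, 3:6] = False
        assert np.all(out[outside] == -1.0)

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            mask_with_gtv(self.img, [np.zeros((8, 8, 8), dtype=np.uint8)], CFG)


class TestFilterSmallNodes:
    def _node(self, n_voxels):
        m = np.zeros((30, 30, 30), dtype=np.uint8)
        m.flat[:n_voxels] = 1
        return m

    def test_below_threshold_removed(self):
        assert filter_small_nodes([self._node(1900)], (1, 1, 1)) == []

    def test_exact_threshold_kept(self):
        kept = filter_small_nodes([self._node(2000)], (1, 1, 1))
        assert len(kept) == 1

    def test_mixed_volumes(self):
        nodes = [self._node(1000), self._node(3000), self._node(5000)]
        kept = filter_small_nodes(nodes, (1, 1, 1))
        assert [m.sum() for m in kept] == [3000, 5000]

    def test_spacing_scales_volume(self):
        # 500 voxels at 2 mm spacing = 4 cm^3 -> kept
        kept = filter_small_nodes([self._node(500)], (2, 2, 2))
        assert len(kept) == 1


class TestResampleIsotropic:
    def test_identity_at_target_spacing(self, small_cohort):
        _, records = small_cohort
        cfg = replace(CFG, target_spacing=2.0)
        out = resample_isotropic(records[0], cfg)
        np.testing.assert_array_equal(out.image, records[0].image)

    def test_cube_volume_preserved(self):
        mask = np.zeros((16, 16, 16), dtype=np.uint8)
        mask[3:13, 3:13, 3:13] = 1  # 10-voxel cube at 2 mm spacing
        rec = _record(np.zeros((16, 16, 16)), mask, spacing=(2.0, 2.0, 2.0))
        out = resample_isotropic(rec, CFG)
        vol_before = mask.sum() * 8.0
        vol_after = float(out.gtv_primary_mask.sum())
        assert abs(vol_after - vol_before) / vol_before < 0.15

    def test_sphere_stays_connected(self):
        mask = _sphere((24, 24, 24), radius=8)
        rec = _record(np.zeros((24, 24, 24)), mask, spacing=(2.0, 1.0, 1.5))
        out = resample_isotropic(rec, CFG)
        _, n_components = ndimage.label(out.gtv_primary_mask)
        assert n_components == 1

    def test_vanishing_mask_excluded(self):
        mask = np.zeros((16, 16, 16), dtype=np.uint8)
        mask[8, 8, 8] = 1  # single voxel at 0.3 mm spacing shrinks away
        rec = _record(np.zeros((16, 16, 16)), mask, spacing=(0.3, 0.3, 0.3))
        with pytest.raises(ExcludedPatient):
            resample_isotropic(rec, CFG)


class TestSelectMaxTumorSlice:
    def test_single_slice_mask(self):
        grid = np.random.default_rng(0).normal(size=(6, 6, 6)).astype(np.float32)
        mask = np.zeros((6, 6, 6), dtype=np.uint8)
        mask[4, 1:4, 1:4] = 1
        sel = select_max_tumor_slice(grid, [mask])
        assert sel.index == 4
        np.testing.assert_array_equal(sel.data, grid[4])

    def test_tie_broken_by_lowest_index(self):
        mask = np.zeros((6, 6, 6), dtype=np.uint8)
        mask[1, :2, :2] = 1
        mask[3, :2, :2] = 1
        sel = select_max_tumor_slice(np.zeros((6, 6, 6)), [mask])
        assert sel.index == 1

    def test_ellipsoid_equatorial_slice(self):
        mask = _sphere((20, 20, 20), radius=7)
        counts = [mask[i].sum() for i in range(20)]
        sel = select_max_tumor_slice(np.zeros((20, 20, 20)), [mask])
        assert sel.index == int(np.argmax(counts)) == 10


class TestAugment:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.grid = rng.uniform(-1, 1, (24, 24, 24)).astype(np.float32)
        self.quiet = AugmentConfig(crop_shift_fraction=0.0, mirror_prob=0.0,
                                   rot_elastic_prob=0.0)

    def test_no_randomness_gives_central_crop(self):
        out = augment(self.grid, self.quiet, training=True, crop_extent=16)
        np.testing.assert_array_equal(out, self.grid[4:20, 4:20, 4:20])

    def test_eval_mode_is_central_crop(self):
        out = augment(self.grid, AugmentConfig(), training=False, crop_extent=16)
        np.testing.assert_array_equal(out, self.grid[4:20, 4:20, 4:20])

    def test_fixed_seed_reproducible(self):
        aug = AugmentConfig(seed=5)
        a = augment(self.grid, aug, training=True, crop_extent=16)
        b = augment(self.grid, aug, training=True, crop_extent=16)
        np.testing.assert_array_equal(a, b)

    def test_mirror_is_involution(self):
        crop = augment(self.grid, self.quiet, training=True, crop_extent=16)
        np.testing.assert_array_equal(np.flip(np.flip(crop, -1), -1), crop)

    def test_output_extent_and_range(self):
        aug = AugmentConfig(seed=2, rot_elastic_prob=1.0, mirror_prob=1.0)
        rng = np.random.default_rng(0)
        for _ in range(3):
            out = augment(self.grid, aug, training=True, crop_extent=16, rng=rng)
            assert out.shape == (16, 16, 16)
            assert out.min() >= -1.0 - 1e-5 and out.max() <= 1.0 + 1e-5

    def test_crop_larger_than_grid_rejected(self):
        with pytest.raises(ValueError):
            augment(self.grid, self.quiet, training=False, crop_extent=32)


class TestFullPipeline:
    def test_shapes_and_range(self, small_cohort):
        _, records = small_cohort
        cfg = PreprocessConfig(target_spacing=2.0, input_extent=32, crop_extent=32)
        x3 = preprocess_record(records[0], cfg)
        assert x3.shape == (32, 32, 32)
        assert x3.min() >= -1.0 and x3.max() <= 1.0
        x2 = preprocess_record(records[0], cfg, dimensionality="2D")
        assert x2.shape == (32, 32)

    def test_binary_mode_two_valued(self, small_cohort):
        _, records = small_cohort
        cfg = PreprocessConfig(target_spacing=2.0, input_extent=32,
                               crop_extent=32, input_mode="binary")
        x = preprocess_record(records[0], cfg)
        assert set(np.unique(x)) <= {-1.0, 1.0}

    def test_tumor_centered_in_canvas(self, small_cohort):
        _, records = small_cohort
        cfg = PreprocessConfig(target_spacing=2.0, input_extent=32, crop_extent=24)
        x = preprocess_record(records[0], cfg)
        # centroid centering guarantees tumor voxels survive the central crop
        assert (x > -1.0).sum() > 0
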