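import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt

from seqrubric.conspicuity import (
    conspicuity_series,
    conspicuity_values,
    mask_family,
    morph_binary,
    morph_mask,
    slice_conspicuity,
)
from seqrubric.data_model import pool_and_filter

from conftest import make_mask, make_volume, sphere_mask


def brute_force_expand(voxels, spacing, d):
    dt = distance_transform_edt(~voxels, sampling=spacing)
    return dt <= d


class TestMorphology:
    def test_zero_distance_is_identity(self):
        m = sphere_mask((12, 12, 10), (6, 6, 5), 3)
        out = morph_mask(m, 0.0)
        np.testing.assert_array_equal(out.voxels, m.voxels)

    def test_single_voxel_expanded_1mm_gives_face_cross(self):
        vox = np.zeros((7, 7, 7), dtype=bool)
        vox[3, 3, 3] = True
        out = morph_binary(vox, (1.0, 1.0, 1.0), 1.0)
        assert out.sum() == 7
        assert out[3, 3, 3] and out[2, 3, 3] and out[3, 3, 4]
        assert not out[2, 2, 3]  # diagonal at sqrt(2) mm excluded

    @pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (0.8, 1.1, 2.0)])
    @pytest.mark.parametrize("d", [1.0, 2.0])
    def test_bbox_cropped_morph_matches_full_grid_transform(self, spacing, d):
        rng = np.random.default_rng(11)
        vox = np.zeros((14, 12, 10), dtype=bool)
        vox[rng.integers(2, 10), rng.integers(2, 9), rng.integers(2, 7)] = True
        vox |= sphere_mask((14, 12, 10), (7, 6, 5), 2).voxels
        np.testing.assert_array_equal(
            morph_binary(vox, spacing, d), brute_force_expand(vox, spacing, d)
        )
        dt_in = distance_transform_edt(vox, sampling=spacing)
        np.testing.assert_array_equal(morph_binary(vox, spacing, -d), dt_in > d)

    def test_opening_is_contained_in_original(self):
        m = sphere_mask((16, 16, 12), (8, 8, 6), 4)
        opened = morph_mask(morph_mask(m, -2.0), 2.0)
        assert not np.any(opened.voxels & ~m.voxels)

    def test_family_nesting_invariant(self):
        m = sphere_mask((20, 20, 16), (10, 10, 8), 5, spacing=(1.2, 1.2, 1.5))
        fam = mask_family(m)
        assert fam.nested()

    def test_contraction_may_empty_without_raising(self):
        m = sphere_mask((10, 10, 8), (5, 5, 4), 1)
        out = morph_mask(m, -5.0)
        assert out.n_voxels == 0


class TestSliceConspicuity:
    def build(self, core_val=100.0, ring_val=50.0, ring_sd=10.0, seed=0):
        """Sphere of radius 4 at 1 mm spacing; background carries noise."""
        shape = (24, 24, 16)
        rng = np.random.default_rng(seed)
        data = np.full(shape, ring_val) + rng.normal(0, ring_sd, shape)
        mask = sphere_mask(shape, (12, 12, 8), 4)
        data[mask.voxels] = core_val
        return make_volume(data), mask

    def test_conspicuity_equals_contrast_over_ring_sd(self):
        vol, mask = self.build()
        fam = mask_family(mask)
        v = slice_conspicuity(vol, fam, 8)
        ring = fam.surround_ring[:, :, 8]
        expected = abs(
            vol.intensities[:, :, 8][fam.contracted_1[:, :, 8]].mean()
            - vol.intensities[:, :, 8][ring].mean()
        ) / vol.intensities[:, :, 8][ring].std(ddof=1)
        assert v == pytest.approx(expected)
        # roughly contrast 50 over SD 10
        assert 2.5 < v < 8.5

    def test_zero_contrast_gives_zero(self):
        vol, mask = self.build(core_val=50.0, ring_sd=5.0)
        fam = mask_family(mask)
        vals = [slice_conspicuity(vol, fam, z) for z in (7, 8, 9)]
        assert all(v < 1.0 for v in vals)  # contrast is pure noise

    def test_noiseless_ring_hits_complexity_floor_not_zero_division(self):
        vol, mask = self.build(ring_sd=0.0)
        fam = mask_family(mask)
        v = slice_conspicuity(vol, fam, 8)
        assert np.isfinite(v) and v > 0

    def test_unusable_slice_returns_sentinel(self):
        vol, mask = self.build()
        fam = mask_family(mask)
        assert slice_conspicuity(vol, fam, 0) is None  # far from the sphere

    def test_shift_and_scale_invariance(self):
        vol, mask = self.build()
        fam = mask_family(mask)
        base = slice_conspicuity(vol, fam, 8)
        shifted = make_volume(vol.intensities + 123.4)
        scaled = make_volume(vol.intensities * 5.5)
        assert slice_conspicuity(shifted, fam, 8) == pytest.approx(base)
        assert slice_conspicuity(scaled, fam, 8) == pytest.approx(base)


class TestConspicuitySeries:
    def test_series_counts_occupied_valid_slices(self):
        shape = (24, 24, 16)
        rng = np.random.default_rng(5)
        data = 50.0 + rng.normal(0, 8, shape)
        mask = sphere_mask(shape, (12, 12, 8), 5)
        data[mask.voxels] = 100.0
        vol = make_volume(data)
        sample = conspicuity_series(vol, mask)
        values, slices, skipped = conspicuity_values(vol, mask)
        occupied = int(mask.voxels.any(axis=(0, 1)).sum())
        assert sample.n == len(values) == occupied - len(skipped)
        assert all(p[2] in slices for p in sample.provenance)
        assert not sample.filtered

    def test_identical_volumes_give_identical_samples(self):
        vol, mask = TestSliceConspicuity().build()
        a = conspicuity_series(vol, mask)
        b = conspicuity_series(vol, mask)
        np.testing.assert_array_equal(a.values, b.values)

    def test_pooled_sample_size_after_filter_is_ninety_percent(self):
        # 5 observers x 5 subjects x 20 valid slices -> ~450 after filtering
        rng = np.random.default_rng(8)
        pooled = rng.normal(4.0, 0.5, 500)
        assert pool_and_filter(pooled).size in (449, 450, 451)

    def test_conspicuity_increases_with_configured_contrast(self):
        medians = []
        for core in (60.0, 80.0, 110.0):
            vol, mask = TestSliceConspicuity().build(
                core_val=core, ring_val=50.0, ring_sd=8.0, seed=3
            )
            values, _, _ = conspicuity_values(vol, mask)
            medians.append(np.median(values))
        assert medians[0] < medians[1] < medians[2]
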