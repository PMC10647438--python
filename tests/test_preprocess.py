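"""Preprocessing: resampling, normalization, patch sampling, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhseg.errors import SamplingError, ValidationError
from mhseg.grid import MultiparametricStudy, VolumeGrid
from mhseg.phantom import PhantomSpec, generate_study
from mhseg.preprocess import (AugmentConfig, Patch, PatchSpec, augment,
                              normalize_channel, resample_study, sample_patch)


@pytest.fixture(scope="module")
def study():
    spec = PhantomSpec(grid_shape=(24, 24, 12), spacing_mm=(1.5, 1.5, 3.0),
                       tumor_radii_mm=(8.0, 8.0, 9.0), noise_sigma=0.02)
    return generate_study(spec)


class TestResample:
    def test_identity_spacing_keeps_mask_voxel_identical(self, study):
        out = resample_study(study, study.grid.spacing)
        assert np.array_equal(out.mask.data, study.mask.data)

    def test_mask_stays_binary_after_resampling(self, study):
        out = resample_study(study, (1.0, 1.0, 3.0))
        assert set(np.unique(out.mask.data)) <= {0, 1}

    def test_adc_values_are_preserved_not_interpolated(self, study):
        out = resample_study(study, (1.0, 1.0, 3.0))
        assert set(np.unique(out.channels["adc"].data)) <= set(
            np.unique(study.channels["adc"].data))

    def test_physical_tumor_volume_preserved_within_5_percent(self):
        # ~20-voxel radius in-plane at fine spacing
        spec = PhantomSpec(grid_shape=(64, 64, 12), spacing_mm=(0.6, 0.6, 4.0),
                           tumor_radii_mm=(12.0, 12.0, 12.0))
        s = generate_study(spec)
        before = s.mask.data.sum() * s.mask.voxel_volume_mm3
        out = resample_study(s, (0.9, 0.9, 4.0))
        after = out.mask.data.sum() * out.mask.voxel_volume_mm3
        assert abs(after - before) / before < 0.05


class TestNormalize:
    def test_zero_mean_unit_variance(self, study):
        out = normalize_channel(study.channels["t2w"])
        assert abs(out.data.mean()) < 1e-6
        assert abs(out.data.std() - 1.0) < 1e-6

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=st.floats(min_value=0.1, max_value=10.0),
           b=st.floats(min_value=-5.0, max_value=5.0))
    def test_affine_invariance(self, a, b):
        base = np.arange(24, dtype=np.float64).reshape(2, 3, 4)
        ref = normalize_channel(VolumeGrid(base, (1, 1, 1))).data
        out = normalize_channel(VolumeGrid(a * base + b, (1, 1, 1))).data
        assert np.abs(out - ref).max() < 1e-9

    def test_two_voxel_closed_form(self):
        out = normalize_channel(VolumeGrid(np.array([[[0.0, 2.0]]]), (1, 1, 1)))
        assert np.allclose(out.data, [[[-1.0, 1.0]]])

    def test_constant_volume_rejected(self):
        with pytest.raises(ValidationError):
            normalize_channel(VolumeGrid(np.ones((3, 3, 3)), (1, 1, 1)))


class TestSamplePatch:
    def test_hundred_seeded_draws_always_contain_tumor(self, study):
        spec = PatchSpec(size_voxels=(12, 12, 8))
        rng = np.random.default_rng(0)
        for _ in range(100):
            patch = sample_patch(study, spec, rng)
            assert patch.channels.shape[1:] == (12, 12, 8)
            assert patch.mask.any(axis=(0, 1)).any()  # >= 1 non-empty slice

    def test_patch_sized_volume_returns_the_volume(self, study):
        spec = PatchSpec(size_voxels=study.grid.shape)
        patch = sample_patch(study, spec, np.random.default_rng(0))
        assert np.array_equal(patch.mask, study.mask.data)
        assert np.array_equal(patch.channels,
                              study.channel_stack(patch.channel_names))

    def test_small_volume_zero_padded_to_patch_size(self, study):
        spec = PatchSpec(size_voxels=(32, 32, 16))
        patch = sample_patch(study, spec, np.random.default_rng(0))
        assert patch.channels.shape[1:] == (32, 32, 16)
        assert patch.mask.sum() == study.mask.data.sum()

    def test_same_seed_gives_identical_corner(self, study):
        spec = PatchSpec(size_voxels=(12, 12, 8))
        p1 = sample_patch(study, spec, np.random.default_rng(77))
        p2 = sample_patch(study, spec, np.random.default_rng(77))
        assert p1.corner == p2.corner
        assert np.array_equal(p1.channels, p2.channels)

    def test_empty_mask_with_require_tumor_raises(self, study):
        empty = MultiparametricStudy(
            "empty", dict(study.channels),
            study.mask.with_data(np.zeros_like(study.mask.data)))
        with pytest.raises(SamplingError):
            sample_patch(empty, PatchSpec(size_voxels=(8, 8, 8)),
                         np.random.default_rng(0))


class TestAugment:
    def _patch(self, rng, value=None):
        data = (np.full((2, 10, 10, 6), value) if value is not None
                else rng.normal(size=(2, 10, 10, 6)))
        mask = np.zeros((10, 10, 6), dtype=np.uint8)
        mask[4:7, 4:7, 2:4] = 1
        return Patch(data, mask, (0, 0, 0), ("t2w", "adc"))

    def test_zero_probability_is_identity(self, rng):
        patch = self._patch(rng)
        out = augment(patch, rng, AugmentConfig(probability=0.0))
        assert out is patch

    def test_mask_stays_binary_and_never_intensity_transformed(self, rng):
        patch = self._patch(rng)
        for _ in range(20):
            out = augment(patch, rng)
            assert set(np.unique(out.mask)) <= {0, 1}
            assert out.mask.sum() <= patch.mask.sum()  # jitter may clip only

    def test_constant_patch_maps_to_affine_constant(self, rng):
        patch = self._patch(rng, value=3.0)
        cfg = AugmentConfig(probability=1.0, max_crop_jitter=0)
        out = augment(patch, rng, cfg)
        # constant in, constant out (shift of a zero-std channel is zero)
        for c in range(out.channels.shape[0]):
            vals = np.unique(out.channels[c])
            assert len(vals) == 1

    def test_shapes_unchanged(self, rng):
        patch = self._patch(rng)
        out = augment(patch, rng)
        assert out.channels.shape == patch.channels.shape
        assert out.mask.shape == patch.mask.shape
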