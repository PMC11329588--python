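"""Preprocessing chain: resampling, recentering, z-scoring, crop/upsample."""

import numpy as np
import pytest

from tongueseg import (
    LabeledVolume,
    PhantomSpec,
    compute_cohort_stats,
    generate_phantom,
    preprocess_cohort,
    reorient_center,
    resample_isotropic,
    to_segmentation_grid,
    tongue_volume,
    znormalize,
)
from tongueseg.preprocess import GridSpec, NormalizationStats, _central_roi_mean

from conftest import TINY_SPEC


def _ball_volume(radius=20.0, n=64, spacing=1.0):
    x = (np.arange(n) - (n - 1) / 2) * spacing
    r2 = x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2
    mask = (r2 <= radius**2).astype(np.uint8)
    return LabeledVolume(mask * 100.0, mask, (spacing,) * 3)


class TestResampleIsotropic:
    def test_identity_is_bit_exact(self):
        vol = _ball_volume()
        out = resample_isotropic(vol, GridSpec(64, 1.0))
        assert np.array_equal(out.intensity, vol.intensity)
        assert np.array_equal(out.mask, vol.mask)

    def test_upsampling_preserves_mask_volume(self):
        vol = _ball_volume(radius=20.0, n=64, spacing=1.0)
        out = resample_isotropic(vol, GridSpec(128, 0.5))
        v_in = vol.mask.sum() * vol.voxel_volume_mm3
        v_out = out.mask.sum() * out.voxel_volume_mm3
        assert v_out == pytest.approx(v_in, rel=0.02)

    def test_anisotropic_to_isotropic_preserves_extent(self):
        rng = np.random.default_rng(0)
        vol = LabeledVolume(
            rng.normal(size=(64, 64, 32)).astype(np.float32), None, (1.0, 1.0, 2.0)
        )
        out = resample_isotropic(vol, GridSpec(64, 1.0))
        assert out.shape == (64, 64, 64)
        assert out.spacing_mm == (1.0, 1.0, 1.0)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            resample_isotropic(_ball_volume(), GridSpec(64, 0.0))


class TestReorientCenter:
    def test_landmark_at_center_is_identity(self, tiny_phantom):
        n = tiny_phantom.shape[0]
        out = reorient_center(tiny_phantom, (n // 2,) * 3)
        assert np.array_equal(out.intensity, tiny_phantom.intensity)
        assert np.array_equal(out.mask, tiny_phantom.mask)

    def test_offset_landmark_shifts_content(self, tiny_phantom):
        n = tiny_phantom.shape[0]
        out = reorient_center(tiny_phantom, (n // 2 + 3, n // 2, n // 2))
        c0 = np.mean(np.nonzero(tiny_phantom.mask), axis=1)
        c1 = np.mean(np.nonzero(out.mask), axis=1)
        assert c1[0] == pytest.approx(c0[0] - 3, abs=1e-9)
        assert c1[1] == pytest.approx(c0[1], abs=1e-9)

    def test_phantom_centroid_lands_at_matrix_center(self):
        vol = generate_phantom(PhantomSpec(grid_shape=64, spacing_mm=2.0, seed=5))
        centroid = tuple(np.mean(np.nonzero(vol.mask), axis=1))
        out = reorient_center(vol, centroid)
        new_centroid = np.mean(np.nonzero(out.mask), axis=1)
        center = np.array([s // 2 for s in out.shape])
        assert np.all(np.abs(new_centroid - center) <= 1.0)

    def test_permuted_and_flipped_axes_are_canonicalized(self, tiny_phantom):
        # same physical volume stored (IS-reversed, AP, LR) must canonicalize
        # to the identical canonical-orientation array
        twisted = LabeledVolume(
            np.transpose(tiny_phantom.intensity, (2, 0, 1))[::-1].copy(),
            np.transpose(tiny_phantom.mask, (2, 0, 1))[::-1].copy(),
            (2.0, 2.0, 2.0),
            axis_labels=("SI", "AP", "LR"),
        )
        ref = reorient_center(
            tiny_phantom, tuple(np.mean(np.nonzero(tiny_phantom.mask), axis=1))
        )
        out = reorient_center(
            twisted, tuple(np.mean(np.nonzero(twisted.mask), axis=1))
        )
        assert np.array_equal(out.mask, ref.mask)
        assert np.array_equal(out.intensity, ref.intensity)

    def test_landmark_outside_grid_rejected(self, tiny_phantom):
        with pytest.raises(ValueError):
            reorient_center(tiny_phantom, (99, 0, 0))


class TestCohortNormalization:
    def _constant_cohort(self, means):
        return [
            LabeledVolume(np.full((16, 16, 16), m, np.float64), None, (2.0,) * 3)
            for m in means
        ]

    def test_stats_forced_arithmetic(self):
        stats = compute_cohort_stats(self._constant_cohort((90, 100, 110)), GridSpec(8, 2.0))
        assert stats.cohort_mean == pytest.approx(100.0)
        assert stats.cohort_std == pytest.approx(10.0)

    def test_identical_subjects_rejected(self):
        with pytest.raises(ValueError):
            compute_cohort_stats(self._constant_cohort((100, 100, 100)), GridSpec(8, 2.0))

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError):
            compute_cohort_stats(self._constant_cohort((100,)), GridSpec(8, 2.0))

    def test_stats_match_independent_two_pass_computation(self):
        vols = [
            generate_phantom(PhantomSpec(grid_shape=32, spacing_mm=2.0,
                                         volume_scale=0.5, seed=s))
            for s in range(3)
        ]
        roi = GridSpec(16, 2.0)
        stats = compute_cohort_stats(vols, roi)
        # independent oracle: explicit crop + mean per subject
        means = []
        for v in vols:
            c = v.intensity[8:24, 8:24, 8:24]
            means.append(c.mean(dtype=np.float64))
        assert stats.cohort_mean == pytest.approx(np.mean(means), abs=1e-12)
        assert stats.cohort_std == pytest.approx(np.std(means, ddof=1), abs=1e-12)

    def test_znormalize_pointwise(self):
        stats = NormalizationStats([90, 110], 100.0, 10.0, (8, 8, 8))
        vol = LabeledVolume(np.full((4, 4, 4), 100.0), None, (1.0,) * 3)
        assert np.all(znormalize(vol, stats).intensity == 0.0)
        vol.intensity[0, 0, 0] = 110.0
        assert znormalize(vol, stats).intensity[0, 0, 0] == 1.0

    def test_cohort_self_normalization_gives_unit_stats(self):
        vols = [
            generate_phantom(PhantomSpec(grid_shape=32, spacing_mm=2.0,
                                         volume_scale=0.5, seed=s))
            for s in range(4)
        ]
        roi = GridSpec(16, 2.0)
        stats = compute_cohort_stats(vols, roi)
        normed = [znormalize(v, stats) for v in vols]
        means = [_central_roi_mean(v, roi) for v in normed]
        assert np.mean(means) == pytest.approx(0.0, abs=1e-10)
        assert np.std(means, ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_normalization_is_affine_invariant(self):
        vols = [
            generate_phantom(PhantomSpec(grid_shape=32, spacing_mm=2.0,
                                         volume_scale=0.5, seed=s))
            for s in range(3)
        ]
        roi = GridSpec(16, 2.0)
        base = [
            znormalize(v, compute_cohort_stats(vols, roi)) for v in vols
        ]
        scaled = [
            LabeledVolume(v.intensity.astype(np.float64) * 3.7 + 12.5, v.mask, v.spacing_mm)
            for v in vols
        ]
        other = [
            znormalize(v, compute_cohort_stats(scaled, roi)) for v in scaled
        ]
        for a, b in zip(base, other):
            assert np.allclose(a.intensity, b.intensity, atol=1e-9)

    def test_zero_std_rejected(self):
        stats = NormalizationStats([1.0, 1.0], 1.0, 0.0, (8, 8, 8))
        vol = LabeledVolume(np.zeros((4, 4, 4)), None, (1.0,) * 3)
        with pytest.raises(ValueError):
            znormalize(vol, stats)


class TestSegmentationGrid:
    def test_identity_grid_is_noop(self, tiny_phantom):
        out = to_segmentation_grid(tiny_phantom, GridSpec(16, 2.0))
        assert np.array_equal(out.intensity, tiny_phantom.intensity)
        assert np.array_equal(out.mask, tiny_phantom.mask)

    def test_crop_and_upsample_preserves_volume(self):
        vol = generate_phantom(
            PhantomSpec(grid_shape=64, spacing_mm=2.0, volume_scale=0.5, seed=8)
        )
        out = to_segmentation_grid(vol, GridSpec(64, 1.0))
        assert out.shape == (64, 64, 64)
        v0 = tongue_volume(vol.mask, vol.spacing_mm)
        v1 = tongue_volume(out.mask, out.spacing_mm)
        assert v1 == pytest.approx(v0, rel=0.02)

    def test_oversized_segmentation_extent_rejected(self, tiny_phantom):
        with pytest.raises(ValueError):
            to_segmentation_grid(tiny_phantom, GridSpec(64, 2.0))


class TestFullChain:
    def test_full_chain_preserves_tongue_volume(self):
        vols = [
            generate_phantom(PhantomSpec(grid_shape=64, spacing_mm=2.0,
                                         volume_scale=s, seed=i))
            for i, s in enumerate((0.5, 0.55, 0.6))
        ]
        prepped, stats = preprocess_cohort(
            vols,
            working=GridSpec(64, 2.0),
            seg=GridSpec(64, 1.0),
            roi=GridSpec(32, 2.0),
        )
        for orig, out in zip(vols, prepped):
            v0 = tongue_volume(orig.mask, orig.spacing_mm)
            v1 = tongue_volume(out.mask, out.spacing_mm)
            assert v1 == pytest.approx(v0, rel=0.02)
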