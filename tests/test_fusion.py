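import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rmlp import fusion, metrics, pyramids

from conftest import majority_downsample_oracle


def two_stripe_mask(shape, n=2):
    h, w = shape
    mask = np.ones(shape, dtype=int)
    mask[h // 2 :, :] = 2
    return mask


class TestMaskPyramid:
    def test_uniform_mask_stays_uniform(self):
        levels = fusion.build_mask_pyramid(np.full((16, 16), 3), 3, n_sources=4)
        assert all(np.all(lv == 3) for lv in levels)
        assert [lv.shape for lv in levels] == [(16, 16), (8, 8), (4, 4)]

    def test_half_mask_halves_cleanly(self):
        mask = np.ones((8, 8), dtype=int)
        mask[:, 4:] = 2
        levels = fusion.build_mask_pyramid(mask, 3)
        for lv in levels:
            w = lv.shape[1]
            assert np.all(lv[:, : w // 2] == 1) and np.all(lv[:, w // 2 :] == 2)

    def test_tied_block_takes_smallest_label(self):
        mask = np.tile(np.array([[1, 2], [1, 2]]), (2, 2))  # every 2x2 block ties
        levels = fusion.build_mask_pyramid(mask, 2)
        assert np.all(levels[1] == 1)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(mask=hnp.arrays(np.int64, (9, 13), elements=st.integers(1, 4)))
    def test_matches_block_vote_oracle(self, mask):
        levels = fusion.build_mask_pyramid(mask, 2, n_sources=4)
        assert np.array_equal(levels[1], majority_downsample_oracle(mask, 4))

    def test_too_deep_rejected(self):
        with pytest.raises(ValueError):
            fusion.build_mask_pyramid(np.ones((8, 8), dtype=int), 9)


class TestMosaicSelection:
    def test_single_source_returned_verbatim(self, rng):
        lp = pyramids.build_laplacian_pyramid(rng.normal(size=(16, 16)), 3)
        masks = fusion.build_mask_pyramid(np.ones((16, 16), dtype=int), 3)
        fused = fusion.mosaic_fuse([lp], masks)
        for got, want in zip(fused, lp):
            assert np.array_equal(got, want)

    def test_constant_mask_selects_that_source(self, rng):
        lps = [pyramids.build_laplacian_pyramid(rng.normal(size=(16, 16)), 3)
               for _ in range(3)]
        masks = fusion.build_mask_pyramid(np.full((16, 16), 2), 3, n_sources=3)
        fused = fusion.mosaic_fuse(lps, masks)
        for got, want in zip(fused, lps[1]):
            assert np.array_equal(got, want)

    def test_half_mask_selects_per_side(self, rng):
        lps = [pyramids.build_laplacian_pyramid(rng.normal(size=(16, 16)), 3)
               for _ in range(2)]
        mask = np.ones((16, 16), dtype=int)
        mask[:, 8:] = 2
        fused = fusion.mosaic_fuse(lps, fusion.build_mask_pyramid(mask, 3))
        for k, level in enumerate(fused):
            w = level.shape[1]
            assert np.array_equal(level[:, : w // 2], lps[0][k][:, : w // 2])
            assert np.array_equal(level[:, w // 2 :], lps[1][k][:, w // 2 :])

    def test_label_exceeding_sources_rejected(self, rng):
        lp = pyramids.build_laplacian_pyramid(rng.normal(size=(16, 16)), 3)
        masks = fusion.build_mask_pyramid(np.full((16, 16), 2), 3)
        with pytest.raises(ValueError):
            fusion.mosaic_fuse([lp], masks)


class TestTopLayer:
    def test_identical_bases_any_mask(self, rng):
        base = rng.normal(size=(4, 4))
        mask = np.ones((4, 4), dtype=int)
        mask[2:] = 2
        assert np.array_equal(
            fusion.fuse_top_layer([base, base.copy()], mask), base
        )

    def test_striped_mask_selects_per_cell(self, rng):
        bases = [rng.normal(size=(4, 4)) for _ in range(2)]
        mask = two_stripe_mask((4, 4))
        got = fusion.fuse_top_layer(bases, mask)
        assert np.array_equal(got[:2], bases[0][:2])
        assert np.array_equal(got[2:], bases[1][2:])

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fusion.fuse_top_layer([rng.normal(size=(4, 4))], np.ones((5, 5), int))


class TestRmlpPipeline:
    def test_identical_stack_is_identity(self, rng):
        img = np.clip(rng.normal(128, 40, size=(64, 64)), 0, 255)
        stack = np.stack([img] * 4)
        result = fusion.rmlp_fuse_gray(stack)
        assert np.max(np.abs(result.fused - img)) < 1e-6

    def test_single_frame_warns_and_copies(self, rng):
        img = rng.normal(128, 10, size=(32, 32))
        with pytest.warns(UserWarning):
            result = fusion.rmlp_fuse_gray(img[None])
        assert np.array_equal(result.fused, img)

    def test_fused_beats_each_source_frame(self, small_bundle):
        b = small_bundle
        result = fusion.rmlp_fuse_gray(b.frames, radius=8)
        fused_rmse = metrics.rmse(result.fused, b.ground_truth)
        assert all(
            fused_rmse < metrics.rmse(f, b.ground_truth) for f in b.frames
        )

    def test_region_provenance_inside_block_aligned_regions(self, rng):
        # regions aligned to 2^K blocks: every band-pass cell strictly inside
        # a region must be copied bit-for-bit from its source pyramid
        depth = 3
        frames = np.clip(rng.normal(128, 30, size=(2, 32, 32)), 0, 255)
        mask = np.ones((32, 32), dtype=int)
        mask[:, 16:] = 2
        lps = [pyramids.build_laplacian_pyramid(f, depth) for f in frames]
        fused = fusion.mosaic_fuse(lps, fusion.build_mask_pyramid(mask, depth))
        for k in range(depth - 1):
            w = fused[k].shape[1]
            assert np.array_equal(fused[k][:, : w // 2], lps[0][k][:, : w // 2])
            assert np.array_equal(fused[k][:, w // 2 :], lps[1][k][:, w // 2 :])

    def test_idempotent_on_own_output(self, small_bundle):
        fused = fusion.rmlp_fuse_gray(small_bundle.frames, radius=8).fused
        again = fusion.rmlp_fuse_gray(np.stack([fused, fused]), radius=8).fused
        assert np.max(np.abs(again - fused)) < 1e-6

    def test_permutation_covariance(self, small_bundle):
        frames = small_bundle.frames
        perm = [2, 0, 3, 1]
        a = fusion.rmlp_fuse_gray(frames, radius=8).fused
        b = fusion.rmlp_fuse_gray(frames[perm], radius=8).fused
        assert np.max(np.abs(a - b)) < 1e-6

    def test_literal_top_mask_variant_runs(self, small_bundle):
        result = fusion.rmlp_fuse_gray(
            small_bundle.frames, radius=8, top_mask_mode="sml"
        )
        assert result.fused.shape == small_bundle.ground_truth.shape

    def test_mixed_shapes_rejected(self):
        with pytest.raises(ValueError):
            fusion.rmlp_fuse_gray([np.ones((8, 8)), np.ones((8, 9))])


class TestColorPipeline:
    def test_gray_as_rgb_replicates_gray_result(self, rng):
        frames = np.clip(rng.normal(128, 30, size=(3, 32, 32)), 0, 255)
        rgb = np.repeat(frames[..., None], 3, axis=-1)
        gray = fusion.rmlp_fuse_gray(frames, radius=4).fused
        color = fusion.rmlp_fuse_color(rgb, radius=4).fused
        for c in range(3):
            assert np.allclose(color[..., c], gray)

    def test_identical_color_stack_is_identity(self, rng):
        img = np.clip(rng.normal(128, 30, size=(32, 32, 3)), 0, 255)
        result = fusion.rmlp_fuse_color(np.stack([img] * 3))
        assert np.max(np.abs(result.fused - img)) < 1e-6

    def test_shared_mask_mode_uses_one_mask(self, rng):
        frames = np.clip(rng.normal(128, 30, size=(3, 32, 32)), 0, 255)
        rgb = np.repeat(frames[..., None], 3, axis=-1)
        result = fusion.rmlp_fuse_color(rgb, radius=4, color_mode="shared-mask")
        assert result.params["color_mode"] == "shared-mask"
        assert result.mask.shape == (32, 32)

    def test_color_fusion_beats_best_frame_ssim(self):
        import rmlp

        b = rmlp.simulate(shape=(96, 96), n_frames=4, sigma_max=4.0,
                          noise_sd=0.0, seed=11, rgb=True)
        fused = fusion.rmlp_fuse_color(b.frames, radius=8).fused
        fused_ssim = metrics.ssim(fused, b.ground_truth)
        best = max(metrics.ssim(f, b.ground_truth) for f in b.frames)
        assert fused_ssim > best

    def test_channel_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fusion.rmlp_fuse_color(rng.normal(size=(3, 16, 16, 4)))
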