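"""Depth crop normalization, DMA/DMH maps, HOG geometry, windowing."""

import numpy as np
import pytest

from depthact import (
    BoundingBox,
    DepthFrame,
    FeatureWindow,
    colorize_frame,
    compute_dma,
    compute_dmh,
    crop_resize_recover,
    hog_descriptor,
    window_descriptor,
    windows_from_sequence,
)
from depthact.features import DESCRIPTOR_DIM, HOG_DIM


def _window(crops):
    return FeatureWindow(crops=np.stack(crops))


class TestCropResizeRecover:
    def test_uniform_region_decodes_to_uniform_crop(self, crange):
        frame = DepthFrame(values=np.full((60, 80), 2.0))
        color = colorize_frame(frame, crange)
        crop = crop_resize_recover(color, BoundingBox(10, 10, 50, 40), crange)
        assert crop.shape == (128, 128)
        # one flat value, within a quantization step of the original
        assert np.ptp(crop) == 0.0
        assert abs(crop[0, 0] - 2.0) <= 2.0**2 * crange.disp_span / 1529

    def test_any_box_is_normalized_to_128(self, crange):
        frame = DepthFrame(values=np.linspace(1.0, 3.0, 64 * 64).reshape(64, 64))
        color = colorize_frame(frame, crange)
        crop = crop_resize_recover(color, BoundingBox(0, 0, 64, 64), crange)
        assert crop.shape == (128, 128)

    def test_box_outside_frame_rejected(self, crange):
        color = colorize_frame(DepthFrame(values=np.full((20, 20), 2.0)), crange)
        with pytest.raises(ValueError):
            crop_resize_recover(color, BoundingBox(5, 5, 25, 15), crange)


class TestDepthMotionAppearance:
    def test_identical_crops_give_scaled_crop(self):
        crop = np.linspace(1.0, 2.0, 64).reshape(8, 8)
        dma = compute_dma(_window([crop] * 5))
        expected = np.floor((crop - crop.min()) / np.ptp(crop) * 255 + 0.5)
        np.testing.assert_array_equal(dma.values, expected)

    def test_per_pixel_mean_before_scaling(self):
        crops = [np.full((8, 8), 2.0) for _ in range(5)]
        for t, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0]):
            crops[t] = crops[t].copy()
            crops[t][3, 3] = v
        mean = np.stack(crops).mean(axis=0)
        assert mean[3, 3] == pytest.approx(3.0)
        dma = compute_dma(_window(crops))
        # only two distinct mean values: 2.0 background, 3.0 at the pixel
        assert dma.values[3, 3] == 255.0 and dma.values[0, 0] == 0.0

    def test_constant_window_maps_to_zero(self):
        dma = compute_dma(_window([np.full((8, 8), 1.5)] * 5))
        assert np.all(dma.values == 0.0)

    def test_output_bounded_for_random_windows(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            dma = compute_dma(_window(list(rng.uniform(0.5, 5.0, (5, 16, 16)))))
            assert dma.values.min() >= 0.0 and dma.values.max() <= 255.0


class TestDepthMotionHistory:
    def test_static_window_is_all_zero(self):
        dmh = compute_dmh(_window([np.full((8, 8), 2.0)] * 5))
        assert np.all(dmh.values == 0.0)

    @pytest.mark.parametrize("change_at,expected", [(4, 255.0), (2, 128.0), (1, 64.0)])
    def test_recency_coding(self, change_at, expected):
        crops = [np.full((8, 8), 2.0) for _ in range(5)]
        for t in range(change_at, 5):
            crops[t] = np.full((8, 8), 2.0)
            crops[t][2, 2] = 2.5  # moved at pair (change_at-1 -> change_at) only
        dmh = compute_dmh(_window(crops))
        assert dmh.values[2, 2] == expected
        assert dmh.values[0, 0] == 0.0

    def test_later_motion_overwrites_earlier(self):
        crops = [np.full((8, 8), 2.0) for _ in range(5)]
        crops[1][5, 5] = 2.5   # motion at pair 1->2
        crops[4] = crops[3].copy()
        crops[4][5, 5] = 3.0   # motion again at pair 4->5
        dmh = compute_dmh(_window(crops))
        assert dmh.values[5, 5] == 255.0

    def test_time_reversal_changes_the_map(self):
        crops = [np.full((8, 8), 2.0) for _ in range(5)]
        crops[1] = crops[1].copy()
        crops[1][4, 4] = 2.6
        crops[2] = crops[1]  # motion happens early, then holds
        crops[3] = crops[1]
        crops[4] = crops[1]
        fwd = compute_dmh(_window(crops)).values
        rev = compute_dmh(_window(crops[::-1])).values
        assert not np.array_equal(fwd, rev)

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError):
            compute_dmh(_window([np.zeros((8, 8))] * 5), epsilon=0.0)


class TestHogDescriptor:
    def test_standard_map_gives_8100(self):
        rng = np.random.default_rng(1)
        assert hog_descriptor(rng.uniform(0, 255, (128, 128))).shape == (HOG_DIM,)

    def test_diagnostic_64_map_gives_1764(self):
        rng = np.random.default_rng(2)
        assert hog_descriptor(rng.uniform(0, 255, (64, 64))).shape == (7 * 7 * 4 * 9,)

    def test_constant_map_gives_zero_descriptor(self):
        assert np.all(hog_descriptor(np.full((128, 128), 80.0)) == 0.0)

    def test_descriptor_nonnegative_with_unit_bounded_blocks(self):
        rng = np.random.default_rng(3)
        desc = hog_descriptor(rng.uniform(0, 255, (128, 128)))
        assert np.all(desc >= 0.0)
        blocks = desc.reshape(-1, 36)
        assert np.all(np.linalg.norm(blocks, axis=1) <= 1.0 + 1e-9)

    @pytest.mark.parametrize("shape", [(100, 100), (128, 130), (8, 8)])
    def test_incompatible_sizes_rejected(self, shape):
        with pytest.raises(ValueError):
            hog_descriptor(np.zeros(shape))


class TestWindowDescriptor:
    def test_concatenated_length_and_order(self):
        rng = np.random.default_rng(4)
        window = _window(list(rng.uniform(0.5, 5.0, (5, 128, 128))))
        desc = window_descriptor(window)
        assert desc.shape == (DESCRIPTOR_DIM,)
        np.testing.assert_array_equal(desc[:HOG_DIM], hog_descriptor(compute_dma(window)))

    def test_static_window_has_zero_motion_half(self):
        crop = np.linspace(1.0, 3.0, 128 * 128).reshape(128, 128)
        desc = window_descriptor(_window([crop] * 5))
        assert np.all(desc[HOG_DIM:] == 0.0)
        assert np.any(desc[:HOG_DIM] > 0.0)

    def test_deterministic_bit_for_bit(self):
        rng = np.random.default_rng(5)
        crops = list(rng.uniform(0.5, 5.0, (5, 128, 128)))
        np.testing.assert_array_equal(
            window_descriptor(_window(crops)), window_descriptor(_window(crops))
        )


class TestWindowing:
    @pytest.mark.parametrize("n,expected", [(60, 12), (5, 1), (63, 12), (4, 0)])
    def test_window_counts(self, n, expected):
        crops = [np.zeros((8, 8))] * n
        windows = windows_from_sequence(crops)
        assert len(windows) == expected
        if windows:
            assert windows[-1].frame_indices[-1] == expected * 5 - 1

    def test_window_validation(self):
        with pytest.raises(ValueError):
            FeatureWindow(crops=np.zeros((4, 8, 8)))
        with pytest.raises(ValueError):
            FeatureWindow(crops=np.full((5, 8, 8), np.nan))
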