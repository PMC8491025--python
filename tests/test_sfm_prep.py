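"""Capture pre-processing: blur scores, gray-world balance, segmentation,
match-pair planning."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from rootcrown3d.sfm_prep import (BackgroundModel, blur_score, flag_blurry,
                                  gray_world_normalize, pair_count_full,
                                  segment_foreground, sliding_window_pairs)


def _checkerboard(size=64, square=4):
    tile = np.kron([[0, 1], [1, 0]], np.ones((square, square)))
    reps = size // (2 * square) + 1
    return np.tile(tile, (reps, reps))[:size, :size] * 255.0


class TestBlurScore:
    def test_sharp_scores_higher_than_blurred(self):
        img = _checkerboard()
        assert blur_score(img) > blur_score(gaussian_filter(img, 4.0))

    def test_ordering_over_textures_and_sigmas(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            img = rng.uniform(0, 255, (48, 48))
            prev = blur_score(img)
            for sigma in (2.0, 4.0, 8.0):
                cur = blur_score(gaussian_filter(img, sigma))
                assert cur < prev
                prev = cur

    def test_constant_image_zero(self):
        assert blur_score(np.full((32, 32), 17.0)) == 0.0

    def test_offset_invariance(self):
        img = _checkerboard(48)
        assert np.isclose(blur_score(img), blur_score(img + 40.0), rtol=1e-6)

    def test_batch_flagging(self):
        rng = np.random.default_rng(1)
        sharp = [blur_score(rng.uniform(0, 255, (48, 48))) for _ in range(10)]
        blurred = blur_score(gaussian_filter(rng.uniform(0, 255, (48, 48)), 8))
        flags = flag_blurry(np.array(sharp + [blurred]))
        assert flags[-1]
        assert not flags[:-1].any()


class TestGrayWorld:
    def test_neutral_gray_unchanged(self):
        img = np.full((16, 16, 3), 128.0)
        out = gray_world_normalize(img)
        assert np.abs(out - img).max() <= 1.0

    def test_red_cast_equalized(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(30, 200, (32, 32, 3))
        img[..., 0] *= 1.5
        out = gray_world_normalize(img)
        luma = out @ np.array([0.299, 0.587, 0.114])
        means = (out * luma[..., None]).reshape(-1, 3).sum(0) / luma.sum()
        assert np.ptp(means) / means.mean() <= 0.02

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 255, (24, 24, 3))
        img[..., 2] *= 0.6
        once = gray_world_normalize(img)
        twice = gray_world_normalize(once)
        assert np.abs(once - twice).max() <= 1.0

    def test_all_black_warns_unchanged(self):
        img = np.zeros((8, 8, 3))
        with pytest.warns(UserWarning):
            out = gray_world_normalize(img)
        np.testing.assert_array_equal(out, img)


class TestSegmentation:
    def _composite(self, seed=0):
        rng = np.random.default_rng(seed)
        img = np.tile(np.array([12.0, 10.0, 9.0]), (96, 96, 1))
        img += rng.normal(0, 2, img.shape)
        truth = np.zeros((96, 96), bool)
        yy, xx = np.mgrid[:96, :96]
        truth |= (np.abs(xx - 48) < 6) & (yy > 10)          # root trunk
        truth |= (np.abs(yy - 2 * xx + 40) < 8) & (yy > 30)  # branch
        img[truth] = [120.0, 80.0, 50.0] + rng.normal(0, 8, (truth.sum(), 3))
        return img, truth

    def test_known_composite_iou(self):
        img, truth = self._composite()
        bg = BackgroundModel.from_images([img])
        mask = segment_foreground(img, bg)
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.9

    def test_background_only_empty(self):
        img = np.tile(np.array([12.0, 10.0, 9.0]), (32, 32, 1))
        bg = BackgroundModel.from_images([img])
        assert not segment_foreground(img, bg).any()

    def test_threshold_monotonicity(self):
        img, _ = self._composite(1)
        bg = BackgroundModel.from_images([img])
        lo = segment_foreground(img, bg, threshold=20.0, min_component_area=1)
        hi = segment_foreground(img, bg, threshold=60.0, min_component_area=1)
        assert not (hi & ~lo).any()  # raising threshold never grows the mask


class TestPairPlanning:
    def test_falling_product_values(self):
        assert pair_count_full(360) == 129240
        assert pair_count_full(2) == 2
        assert pair_count_full(5) == 20
        assert pair_count_full(100, 2, ordered=False) == 4950

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            pair_count_full(1, 2)

    def test_adjacent_window_bruteforce(self):
        pairs = sliding_window_pairs(6, 2)
        expected = {(i, j) for i in range(6) for j in range(6)
                    if i != j and min(abs(i - j), 6 - abs(i - j)) <= 1}
        assert set(pairs.pairs) == expected
        assert len(pairs) == 12

    def test_large_window_reduces_to_full(self):
        assert len(sliding_window_pairs(9, 9)) == pair_count_full(9)
        assert len(sliding_window_pairs(9, 40)) == pair_count_full(9)

    @pytest.mark.parametrize("n,w", [(10, 3), (25, 7), (50, 12)])
    def test_symmetry_and_circular_distance(self, n, w):
        pairs = set(sliding_window_pairs(n, w).pairs)
        for i, j in pairs:
            assert (j, i) in pairs
            assert min(abs(i - j), n - abs(i - j)) <= w - 1

    def test_count_monotone_in_window(self):
        counts = [len(sliding_window_pairs(20, w)) for w in range(2, 22)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 20 * 19

    def test_pair_list_file_format(self, tmp_path):
        pairs = sliding_window_pairs(4, 2)
        path = tmp_path / "pairs.txt"
        pairs.write(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == len(pairs)
        assert all(len(line.split()) == 2 for line in lines)
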