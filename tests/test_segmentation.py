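"""Augmentation ops, training-set assembly, scoring, and the LOO harness."""

import numpy as np
import pandas as pd
import pytest

from organoidaug import (
    OracleSegmenter,
    PixelSegmenter,
    build_training_set,
    classical_augment,
    leave_one_out,
    make_dataset,
    overlay,
    seg_scores,
)
from tests.conftest import downscale, downscale_mask


@pytest.fixture(scope="module")
def small_pairs():
    """Generated organoids downscaled to 48x48 with their masks."""
    data = make_dataset(20, seed=2)
    return [(downscale(img, 48), downscale_mask(mask, 48)) for img, mask in data]


@pytest.fixture(scope="module")
def ellipse_fixtures():
    """High-contrast ellipse images: easy segmentation targets."""
    rng = np.random.default_rng(5)
    pairs = []
    for _ in range(20):
        h = w = 48
        a, b = rng.uniform(8, 16), rng.uniform(8, 16)
        cy, cx = rng.uniform(18, 30), rng.uniform(18, 30)
        yy, xx = np.mgrid[0:h, 0:w]
        mask = ((((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2) <= 1).astype(np.uint8)
        img = np.where(mask, 40.0, 200.0) + rng.normal(0, 8, (h, w))
        pairs.append((np.clip(img, 0, 255).astype(np.uint8), mask))
    return pairs


class TestClassicalAugment:
    def test_flip_involution(self, small_pairs):
        img, mask = small_pairs[0]
        i2, m2 = classical_augment(*classical_augment(img, mask, "flip"), "flip")
        assert np.array_equal(i2, img) and np.array_equal(m2, mask)

    def test_rotate_four_quarter_turns_identity(self, small_pairs):
        img, mask = small_pairs[0]
        i, m = img, mask
        for _ in range(4):
            i, m = classical_augment(i, m, "rotate")
        assert np.array_equal(i, img) and np.array_equal(m, mask)

    @pytest.mark.parametrize("op", ["flip", "rotate"])
    def test_geometric_ops_preserve_mask_area(self, small_pairs, op):
        img, mask = small_pairs[1]
        _, m2 = classical_augment(img, mask, op)
        assert m2.sum() == mask.sum()

    def test_whiten_leaves_mask_untouched(self, small_pairs):
        img, mask = small_pairs[2]
        i2, m2 = classical_augment(img, mask, "whiten")
        assert np.array_equal(m2, mask)
        assert not np.array_equal(i2, img)

    def test_crop_restores_canvas_size(self, small_pairs):
        img, mask = small_pairs[3]
        i2, m2 = classical_augment(img, mask, "crop", seed=4)
        assert i2.shape == img.shape and m2.shape == mask.shape
        assert set(np.unique(m2)) <= {0, 1}

    def test_unknown_op_rejected(self, small_pairs):
        with pytest.raises(ValueError, match="unknown op"):
            classical_augment(*small_pairs[0], "sharpen")


class TestBuildTrainingSet:
    @staticmethod
    def _pools(n_orig=40, n_classical=60, votes=()):
        blank = np.zeros((8, 8), np.uint8)
        originals = [(blank, blank)] * n_orig
        classical = [(blank, blank)] * n_classical
        synthetic = [(blank, blank)] * len(votes)
        return originals, classical, synthetic

    def test_eight_expert_threshold_composition(self):
        """14 images at >= 8 votes -> 14 synthetic + 26 classical + 40 original."""
        votes = [8] * 14 + [5] * 20
        originals, classical, synthetic = self._pools(votes=votes)
        items, comp = build_training_set(originals, classical, synthetic, votes, k_experts=8)
        assert comp == {
            "n_original": 40,
            "n_synthetic": 14,
            "n_classical": 26,
            "total": 80,
            "k_experts": 8,
            "vote_mode": "at_least",
        }
        assert len(items) == 80

    def test_threshold_above_all_votes_pure_classical(self):
        votes = [3] * 10
        originals, classical, synthetic = self._pools(votes=votes)
        _, comp = build_training_set(originals, classical, synthetic, votes, k_experts=9)
        assert comp["n_synthetic"] == 0 and comp["n_classical"] == 40

    @pytest.mark.parametrize("k", [0, 2, 4, 6, 8])
    def test_total_always_80_across_threshold_sweep(self, k):
        rng = np.random.default_rng(k)
        votes = list(rng.integers(0, 9, 50))
        originals, classical, synthetic = self._pools(votes=votes)
        _, comp = build_training_set(originals, classical, synthetic, votes, k_experts=k)
        assert comp["total"] == 80

    def test_exact_vote_mode(self):
        votes = [8, 8, 4, 4, 4]
        originals, classical, synthetic = self._pools(votes=votes)
        _, comp = build_training_set(
            originals, classical, synthetic, votes, k_experts=4, vote_mode="exact"
        )
        assert comp["n_synthetic"] == 3

    def test_insufficient_classical_pool_rejected(self):
        originals, _, synthetic = self._pools(votes=[0])
        with pytest.raises(ValueError, match="classical pool"):
            build_training_set(originals, [], synthetic, [0], k_experts=8)


class TestSegScores:
    def test_perfect_prediction_all_ones(self, small_pairs):
        _, mask = small_pairs[0]
        s = seg_scores(mask, mask.copy())
        assert (
            s.dice == s.accuracy == s.sensitivity == s.specificity == s.precision == s.f1 == 1.0
        )

    def test_disjoint_masks(self):
        gt = np.zeros((6, 6), np.uint8)
        gt[:2, :2] = 1
        u = np.zeros((6, 6), np.uint8)
        u[4:, 4:] = 1
        s = seg_scores(gt, u)
        assert s.dice == 0.0 and s.sensitivity == 0.0

    def test_hand_confusion_example(self):
        """TP=2, FP=0, FN=2, TN=96 on a 10x10 grid."""
        gt = np.zeros((10, 10), np.uint8)
        gt[0, :4] = 1
        u = np.zeros((10, 10), np.uint8)
        u[0, :2] = 1
        s = seg_scores(gt, u)
        assert s.accuracy == pytest.approx(0.98)
        assert s.sensitivity == pytest.approx(0.5)
        assert s.specificity == pytest.approx(1.0)
        assert s.precision == pytest.approx(1.0)
        assert s.f1 == pytest.approx(2 * (1.0 * 0.5) / 1.5)
        assert s.dice == pytest.approx(s.f1)  # Dice = F1 on the same counts

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_pixel_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        gt = (rng.random((12, 12)) > 0.5).astype(np.uint8)
        u = (rng.random((12, 12)) > 0.5).astype(np.uint8)
        tp = fp = fn = tn = 0
        for i in range(12):
            for j in range(12):
                if gt[i, j] and u[i, j]:
                    tp += 1
                elif not gt[i, j] and u[i, j]:
                    fp += 1
                elif gt[i, j] and not u[i, j]:
                    fn += 1
                else:
                    tn += 1
        s = seg_scores(gt, u)
        assert s.dice == pytest.approx(2 * tp / (2 * tp + fp + fn))
        assert s.accuracy == pytest.approx((tp + tn) / 144)
        assert s.precision == pytest.approx(tp / (tp + fp))
        assert s.f1 == pytest.approx(s.dice)

    def test_empty_prediction_warns_nan(self):
        gt = np.zeros((4, 4), np.uint8)
        with pytest.warns(UserWarning):
            s = seg_scores(gt, gt)
        assert np.isnan(s.dice) and s.specificity == 1.0


class TestOverlay:
    def test_perfect_prediction_no_colour(self, small_pairs):
        img, mask = small_pairs[0]
        out = overlay(mask, mask, img)
        assert np.array_equal(out[..., 0], out[..., 1])
        assert np.array_equal(out[..., 1], out[..., 2])

    def test_all_fp_everything_pink(self):
        gt = np.zeros((5, 5), np.uint8)
        u = np.ones((5, 5), np.uint8)
        out = overlay(gt, u, np.zeros((5, 5), np.uint8))
        assert np.all(out == np.array([255, 182, 193]))

    def test_pink_count_matches_fp_count(self, small_pairs):
        img, gt = small_pairs[0]
        rng = np.random.default_rng(1)
        u = (rng.random(gt.shape) > 0.6).astype(np.uint8)
        out = overlay(gt, u, img)
        pink = np.all(out == np.array([255, 182, 193]), axis=-1).sum()
        fp = int(np.sum((gt == 0) & (u == 1)))
        assert pink == fp


class TestLeaveOneOut:
    @staticmethod
    def _originals(pairs, n):
        return [(f"img_{i}", img, mask) for i, (img, mask) in enumerate(pairs[:n])]

    def test_forty_originals_forty_sessions(self, small_pairs):
        data = make_dataset(40, seed=7)
        originals = [
            (f"o{i}", downscale(img, 24), downscale_mask(mask, 24))
            for i, (img, mask) in enumerate(data)
        ]
        df, _ = leave_one_out(
            originals,
            lambda held, rest: rest,
            OracleSegmenter([(im, mk) for _, im, mk in originals]),
        )
        assert len(df) == 40

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_n_originals_n_sessions(self, small_pairs, n):
        originals = self._originals(small_pairs, n)
        df, _ = leave_one_out(
            originals,
            lambda held, rest: rest,
            OracleSegmenter([(im, mk) for _, im, mk in originals]),
        )
        assert len(df) == n

    def test_oracle_segmenter_mean_dice_one(self, small_pairs):
        originals = self._originals(small_pairs, 6)
        _, means = leave_one_out(
            originals,
            lambda held, rest: rest,
            OracleSegmenter([(im, mk) for _, im, mk in originals]),
        )
        assert means["dice"] == pytest.approx(1.0)

    def test_leakage_aborts(self, small_pairs):
        originals = self._originals(small_pairs, 4)
        with pytest.raises(RuntimeError, match="leakage"):
            leave_one_out(originals, lambda held, rest: list(originals), OracleSegmenter())


class TestPixelSegmenter:
    def test_easy_fixture_dice_above_080(self, ellipse_fixtures):
        train = ellipse_fixtures[:16]
        test = ellipse_fixtures[16:]
        model = PixelSegmenter(random_state=0).fit(
            [im for im, _ in train], [mk for _, mk in train]
        )
        dices = [seg_scores(mk, model.predict(im)).dice for im, mk in test]
        assert np.mean(dices) > 0.8

    def test_deterministic_under_seed(self, ellipse_fixtures):
        train = ellipse_fixtures[:8]
        preds = []
        for _ in range(2):
            model = PixelSegmenter(random_state=3).fit(
                [im for im, _ in train], [mk for _, mk in train]
            )
            preds.append(model.predict(ellipse_fixtures[10][0]))
        assert np.array_equal(*preds)

    def test_too_few_pairs_rejected(self, ellipse_fixtures):
        img, mask = ellipse_fixtures[0]
        with pytest.raises(ValueError):
            PixelSegmenter().fit([img], [mask])

    def test_label_noise_does_not_improve_heldout_dice(self, ellipse_fixtures):
        """Corrupting training masks never raises mean held-out dice (trend)."""
        rng = np.random.default_rng(9)
        train = ellipse_fixtures[:12]
        test = ellipse_fixtures[12:]
        means = []
        for noise in (0.0, 0.25, 0.45):
            masks = []
            for _, mk in train:
                m = mk.copy()
                flip = rng.random(m.shape) < noise
                m[flip] = 1 - m[flip]
                masks.append(m)
            model = PixelSegmenter(random_state=0).fit([im for im, _ in train], masks)
            means.append(np.mean([seg_scores(mk, model.predict(im)).dice for im, mk in test]))
        assert means[0] >= means[1] >= means[2] - 0.02


def test_loo_with_pixel_segmenter_end_to_end(ellipse_fixtures):
    originals = [(f"e{i}", im, mk) for i, (im, mk) in enumerate(ellipse_fixtures[:8])]
    df, means = leave_one_out(
        originals, lambda held, rest: rest, PixelSegmenter(random_state=1)
    )
    assert isinstance(df, pd.DataFrame) and len(df) == 8
    assert means["dice"] > 0.7
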