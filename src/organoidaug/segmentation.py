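"""Segmentation training-set construction, scoring and leave-one-out harness.

Training sets of fixed size (default 80) mix the original images with
expert-vote-thresholded synthetic images, topped up from a pool of
classically augmented images (flips, rotations, whitening, crops).  Any
segmenter exposing ``fit(images, masks)`` / ``predict(image) -> mask`` plugs
into the leave-one-out harness, which trains one session per original image
and scores the held-out prediction with Dice, accuracy, sensitivity,
specificity, precision and F1.  A lightweight multiscale pixel-feature
logistic segmenter is provided as the desk-scale default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize
from sklearn.base import BaseEstimator, clone
from sklearn.linear_model import LogisticRegression

__all__ = [
    "SegScores",
    "classical_augment",
    "build_training_set",
    "seg_scores",
    "overlay",
    "leave_one_out",
    "PixelSegmenter",
    "OracleSegmenter",
]

AUGMENT_OPS = ("flip", "rotate", "whiten", "crop")

#: overlay colours (RGB)
LIGHTPINK = (255, 182, 193)
LIGHTGREEN = (144, 238, 144)


# ---------------------------------------------------------------------------
# classical augmentation
# ---------------------------------------------------------------------------


def classical_augment(image, mask, op: str, seed: int = 0, **kwargs):
    """Apply one label-preserving transform to an (image, mask) pair.

    ``flip`` mirrors horizontally; ``rotate`` turns by ``k`` quarter-turns
    (default 1); ``whiten`` standardises the image intensities and rescales
    to [0, 255] (mask untouched); ``crop`` takes a random sub-window (at
    least half the canvas) and resizes both members back to the canvas.
    Geometric ops apply identically to image and mask.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if op == "flip":
        return np.flip(image, axis=1).copy(), np.flip(mask, axis=1).copy()
    if op == "rotate":
        k = int(kwargs.get("k", 1))
        return np.rot90(image, k).copy(), np.rot90(mask, k).copy()
    if op == "whiten":
        img = image.astype(float)
        sd = img.std()
        if sd == 0:
            return image.copy(), mask.copy()
        z = (img - img.mean()) / sd
        z = (z - z.min()) / (z.max() - z.min()) * 255.0
        return np.rint(z).astype(np.uint8), mask.copy()
    if op == "crop":
        rng = np.random.default_rng(seed)
        h, w = image.shape
        ch = int(rng.integers(h // 2, h))
        cw = int(rng.integers(w // 2, w))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        sub_img = image[top : top + ch, left : left + cw]
        sub_mask = mask[top : top + ch, left : left + cw]
        out_img = resize(sub_img.astype(float), (h, w), preserve_range=True, order=1)
        out_mask = resize(sub_mask.astype(float), (h, w), preserve_range=True, order=0)
        return (
            np.clip(np.rint(out_img), 0, 255).astype(np.uint8),
            (out_mask > 0.5).astype(np.uint8),
        )
    raise ValueError(f"unknown op {op!r}; expected one of {AUGMENT_OPS}")


# ---------------------------------------------------------------------------
# training-set construction
# ---------------------------------------------------------------------------


def build_training_set(
    originals: Sequence[tuple],
    classical_pool: Sequence[tuple],
    synthetic_pool: Sequence[tuple],
    votes: Sequence[int],
    k_experts: int,
    total: int = 80,
    vote_mode: str = "at_least",
):
    """Assemble a fixed-size training set under an expert-vote threshold.

    All ``originals`` are always included.  Synthetic items whose vote count
    satisfies the threshold (``votes >= k`` by default, ``votes == k`` with
    ``vote_mode="exact"``) fill the remaining slots, capped at availability;
    the rest is taken from ``classical_pool`` in order.

    Returns ``(items, composition)`` where every item is
    ``(image, mask, provenance)`` and ``composition`` logs the counts.
    """
    if len(votes) != len(synthetic_pool):
        raise ValueError("votes must align with synthetic_pool")
    if vote_mode not in ("at_least", "exact"):
        raise ValueError("vote_mode must be 'at_least' or 'exact'")
    if len(originals) > total:
        raise ValueError("total smaller than the number of originals")
    slots = total - len(originals)
    if vote_mode == "at_least":
        selected = [s for s, v in zip(synthetic_pool, votes) if v >= k_experts]
    else:
        selected = [s for s, v in zip(synthetic_pool, votes) if v == k_experts]
    selected = selected[:slots]
    n_classical = slots - len(selected)
    if n_classical > len(classical_pool):
        raise ValueError(
            f"classical pool too small: need {n_classical}, have {len(classical_pool)}"
        )
    items = (
        [(im, mk, "original") for im, mk in originals]
        + [(im, mk, "synthetic") for im, mk in selected]
        + [(im, mk, "classical") for im, mk in classical_pool[:n_classical]]
    )
    composition = {
        "n_original": len(originals),
        "n_synthetic": len(selected),
        "n_classical": n_classical,
        "total": len(items),
        "k_experts": k_experts,
        "vote_mode": vote_mode,
    }
    return items, composition


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegScores:
    dice: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float


def _confusion(gt: np.ndarray, u: np.ndarray):
    gt = np.asarray(gt).astype(bool)
    u = np.asarray(u).astype(bool)
    if gt.shape != u.shape:
        raise ValueError("mask shapes differ")
    tp = int(np.sum(gt & u))
    fp = int(np.sum(~gt & u))
    fn = int(np.sum(gt & ~u))
    tn = int(np.sum(~gt & ~u))
    return tp, fp, fn, tn


def seg_scores(gt, u) -> SegScores:
    """Six overlap scores between a ground-truth and a predicted mask.

    Zero-denominator ratios return NaN with a warning rather than raising,
    so empty-mask sessions remain reportable.
    """

    tp, fp, fn, tn = _confusion(gt, u)

    def ratio(num, den, what):
        if den == 0:
            warnings.warn(f"{what} undefined (zero denominator); returning NaN")
            return float("nan")
        return num / den

    dice = ratio(2 * tp, 2 * tp + fp + fn, "dice")
    accuracy = ratio(tp + tn, tp + fp + tn + fn, "accuracy")
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        warnings.warn("f1 undefined; returning NaN")
        f1 = float("nan")
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return SegScores(dice, accuracy, sensitivity, specificity, precision, f1)


def overlay(gt, u, image) -> np.ndarray:
    """Render segmentation errors on the image: FP light-pink, FN light-green.

    All other pixels keep their grayscale value (replicated to RGB), so the
    pixel classes are exactly recoverable from the output colours.
    """
    gt = np.asarray(gt).astype(bool)
    u = np.asarray(u).astype(bool)
    image = np.asarray(image)
    if not (gt.shape == u.shape == image.shape):
        raise ValueError("gt, u, and image must share a shape")
    out = np.repeat(image[..., None], 3, axis=-1).astype(np.uint8)
    out[~gt & u] = LIGHTPINK
    out[gt & ~u] = LIGHTGREEN
    return out


# ---------------------------------------------------------------------------
# leave-one-out harness
# ---------------------------------------------------------------------------


def leave_one_out(
    originals: Sequence[tuple],
    set_builder: Callable,
    segmenter,
    scorer: Callable = seg_scores,
) -> tuple[pd.DataFrame, dict]:
    """One training session per original image, testing only on the held-out one.

    Parameters
    ----------
    originals : sequence of (image_id, image, mask)
    set_builder : callable(held_out_id, remaining) -> list of (image_id, image, mask)
        Builds each session's training set from the non-held-out originals
        (plus whatever augmentation it chooses).  If the held-out id appears
        in its output the harness aborts (leakage guard).
    segmenter : estimator with fit(images, masks) / predict(image)
        A fresh clone is trained per session.
    scorer : callable(gt, predicted) -> SegScores

    Returns ``(per_image_scores, mean_scores)``.
    """
    if len(originals) < 2:
        raise ValueError("need >= 2 originals for leave-one-out")
    rows = []
    for held_id, held_img, held_mask in originals:
        remaining = [item for item in originals if item[0] != held_id]
        train_items = set_builder(held_id, remaining)
        if any(item[0] == held_id for item in train_items):
            raise RuntimeError(f"leakage: held-out image {held_id!r} in training set")
        model = clone(segmenter) if isinstance(segmenter, BaseEstimator) else segmenter
        model.fit([it[1] for it in train_items], [it[2] for it in train_items])
        pred = model.predict(held_img)
        scores = scorer(held_mask, pred)
        rows.append({"image_id": held_id, **scores.__dict__})
    df = pd.DataFrame(rows)
    means = df.drop(columns=["image_id"]).mean().to_dict()
    return df, means


class OracleSegmenter:
    """Returns the true mask for any image in its preloaded ground-truth table.

    A harness-sanity tool: with the full ground truth preloaded the
    leave-one-out mean Dice is 1.0 only if the plumbing (pairing, hold-out,
    scoring) is correct.  ``fit`` adds training pairs but is otherwise a
    no-op; unknown images get an empty mask.
    """

    def __init__(self, known_pairs=()):
        self._lookup = {
            np.asarray(im).tobytes(): np.asarray(mk) for im, mk in known_pairs
        }

    def fit(self, images, masks):
        for im, mk in zip(images, masks):
            self._lookup[np.asarray(im).tobytes()] = np.asarray(mk)
        return self

    def predict(self, image):
        key = np.asarray(image).tobytes()
        if key in self._lookup:
            return self._lookup[key]
        return np.zeros(np.asarray(image).shape, dtype=np.uint8)


class PixelSegmenter(BaseEstimator):
    """Desk-scale default segmenter: multiscale pixel features + logistic model.

    Per-pixel features are the raw intensity, Gaussian-smoothed intensities
    at several scales, a local-contrast channel, and normalised image
    coordinates; a scikit-learn logistic regression classifies each pixel and
    the probability map is thresholded at 0.5.  Deterministic under
    ``random_state`` (pixel subsampling only).

    Parameters
    ----------
    scales : tuple of float
        Gaussian smoothing scales (pixels).
    max_pixels_per_image : int
        Training pixels subsampled per image.
    threshold : float
        Probability cut for the output mask (no post-processing).
    """

    def __init__(
        self,
        scales=(1.0, 2.0, 4.0),
        max_pixels_per_image=3000,
        threshold=0.5,
        C=1.0,
        random_state=0,
    ):
        self.scales = scales
        self.max_pixels_per_image = max_pixels_per_image
        self.threshold = threshold
        self.C = C
        self.random_state = random_state

    def _features(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=float) / 255.0
        h, w = img.shape
        chans = [img]
        for s in self.scales:
            sm = ndimage.gaussian_filter(img, s)
            chans.append(sm)
            chans.append(np.abs(img - sm))  # local contrast
        yy, xx = np.mgrid[0:h, 0:w]
        chans.append(yy / max(h - 1, 1))
        chans.append(xx / max(w - 1, 1))
        return np.stack([c.ravel() for c in chans], axis=1)

    def fit(self, images, masks):
        if len(images) < 2:
            raise ValueError("need >= 2 training pairs")
        rng = np.random.default_rng(self.random_state)
        X_parts, y_parts = [], []
        for img, mask in zip(images, masks):
            feats = self._features(img)
            labels = np.asarray(mask).astype(int).ravel()
            n = feats.shape[0]
            take = min(self.max_pixels_per_image, n)
            idx = rng.choice(n, size=take, replace=False)
            X_parts.append(feats[idx])
            y_parts.append(labels[idx])
        X = np.concatenate(X_parts)
        y = np.concatenate(y_parts)
        if len(np.unique(y)) < 2:
            raise ValueError("training masks contain a single class")
        self.model_ = LogisticRegression(C=self.C, max_iter=200)
        self.model_.fit(X, y)
        return self

    def predict(self, image) -> np.ndarray:
        image = np.asarray(image)
        proba = self.model_.predict_proba(self._features(image))[:, 1]
        return (proba.reshape(image.shape) >= self.threshold).astype(np.uint8)
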