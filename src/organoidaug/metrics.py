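"""Full-reference similarity and quality metrics for image groups.

Seven metrics: a pixel-statistic Fréchet distance between groups (FID),
global SSIM, the universal quality index (UQI/UQM), normalised mutual
information, MSE, PSNR, and a no-reference blur index based on prediction
residues.  A group-aggregation layer computes the original-image reference
range and the per-loss-group averages over the full 40x40 pairwise
cross-product.

The Fréchet distance here is deliberately computed on pixel statistics (per
image: mean, standard deviation, and an 8x8 intensity thumbnail), not on
deep-network embeddings; the feature map is injectable for testing and
calibration.
"""

from __future__ import annotations

import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from skimage.transform import resize

__all__ = [
    "fid",
    "ssim",
    "uqm",
    "mutual_information",
    "mse",
    "psnr",
    "blur_index",
    "pairwise_group_average",
    "group_report",
    "PAIRWISE_METRICS",
]

#: cap (dB) reported for PSNR of identical images
PSNR_CAP = 100.0


def _img(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _check_same_shape(o, g):
    o, g = _img(o), _img(g)
    if o.shape != g.shape:
        raise ValueError(f"image shapes differ: {o.shape} vs {g.shape}")
    return o, g


# ---------------------------------------------------------------------------
# group metric: pixel-statistic Fréchet distance
# ---------------------------------------------------------------------------


def _pixel_stat_features(images: Sequence[np.ndarray]) -> np.ndarray:
    """Per-image feature vector: (mean, std, flattened 8x8 thumbnail)."""
    feats = []
    for img in images:
        img = _img(img)
        thumb = resize(img, (8, 8), anti_aliasing=True, preserve_range=True)
        feats.append(np.concatenate([[img.mean(), img.std()], thumb.ravel()]))
    return np.asarray(feats)


def fid(
    group_a: Sequence[np.ndarray],
    group_b: Sequence[np.ndarray],
    features: Callable[[Sequence[np.ndarray]], np.ndarray] | None = None,
    eps: float = 1e-6,
) -> float:
    """Fréchet distance between Gaussian fits to per-image feature vectors.

    ``||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2})``.  Symmetric,
    zero for identical groups.  Singular covariances are handled by diagonal
    loading (``eps``), which is reported via a warning.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 images")
    feat_fn = features or _pixel_stat_features
    fa, fb = np.atleast_2d(feat_fn(group_a)), np.atleast_2d(feat_fn(group_b))
    mu_a, mu_b = fa.mean(axis=0), fb.mean(axis=0)
    ca = np.atleast_2d(np.cov(fa, rowvar=False))
    cb = np.atleast_2d(np.cov(fb, rowvar=False))
    def _sqrtm(m):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = linalg.sqrtm(m)
        return out[0] if isinstance(out, tuple) else out

    covmean = _sqrtm(ca @ cb)
    if not np.isfinite(covmean).all():
        warnings.warn("singular covariance in FID; applying diagonal loading")
        offset = eps * np.eye(ca.shape[0])
        covmean = _sqrtm((ca + offset) @ (cb + offset))
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    value = float(np.sum((mu_a - mu_b) ** 2) + np.trace(ca + cb - 2.0 * covmean))
    return max(value, 0.0)


# ---------------------------------------------------------------------------
# pairwise metrics
# ---------------------------------------------------------------------------


def ssim(o, g, k1: float = 0.01, k2: float = 0.03, data_range: float = 255.0) -> float:
    """Structural similarity evaluated on whole-image statistics.

    Uses the standard stabilising constants ``c1 = (k1 L)^2``,
    ``c2 = (k2 L)^2`` with dynamic range ``L``; returns 1 for identical
    images, including the constant-image case (guarded by c1, c2).
    """
    o, g = _check_same_shape(o, g)
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    mo, mg = o.mean(), g.mean()
    vo, vg = o.var(), g.var()
    cov = ((o - mo) * (g - mg)).mean()
    return float(
        ((2 * mo * mg + c1) * (2 * cov + c2))
        / ((mo**2 + mg**2 + c1) * (vo + vg + c2))
    )


def uqm(o, g) -> float:
    """Universal quality index: ``4 mu_o mu_g sigma_og / ((mu_o^2+mu_g^2)(sigma_o^2+sigma_g^2))``.

    Equals 1 for identical non-constant images.  For a degenerate pair of two
    constant images the index is undefined; the documented limit is 1.0 when
    the constants agree and 0.0 otherwise, returned with a warning.
    """
    o, g = _check_same_shape(o, g)
    mo, mg = o.mean(), g.mean()
    vo, vg = o.var(), g.var()
    if vo == 0 and vg == 0:
        warnings.warn("uqm undefined for two constant images; returning limit value")
        return 1.0 if mo == mg else 0.0
    cov = ((o - mo) * (g - mg)).mean()
    denom = (mo**2 + mg**2) * (vo + vg)
    if denom == 0:
        warnings.warn("uqm denominator degenerate; returning 0")
        return 0.0
    return float(4 * mo * mg * cov / denom)


def mutual_information(o, g, bins: int = 64, normalized: bool = True) -> float:
    """Histogram mutual information of paired intensities.

    Raw MI is computed from the joint ``bins x bins`` intensity histogram in
    nats.  With ``normalized=True`` (default) the value is divided by
    ``min(H(o), H(g))`` so that identical images score 1 and the stated 0-1
    range holds regardless of log base.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    o, g = _check_same_shape(o, g)
    if o.size == 0:
        raise ValueError("empty images")
    joint, _, _ = np.histogram2d(o.ravel(), g.ravel(), bins=bins)
    p = joint / joint.sum()
    po, pg = p.sum(axis=1), p.sum(axis=0)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / (po[:, None] * pg[None, :])[nz])))
    if not normalized:
        return mi
    ho = -float(np.sum(po[po > 0] * np.log(po[po > 0])))
    hg = -float(np.sum(pg[pg > 0] * np.log(pg[pg > 0])))
    hmin = min(ho, hg)
    if hmin == 0:  # at least one constant image
        return 1.0 if np.array_equal(o, g) else 0.0
    return mi / hmin


def mse(o, g) -> float:
    """Mean squared error between two images."""
    o, g = _check_same_shape(o, g)
    return float(np.mean((o - g) ** 2))


def psnr(o, g, printed_form: bool = False) -> float:
    """Peak signal-to-noise ratio in dB, with the peak taken from ``o``.

    Default is the standard ``10 log10(max(o)^2 / MSE)``, which matches the
    ~12-16 dB regime of bright-field organoid comparisons.  The alternative
    ``20 log10(max) - 20 log10(MSE)`` form is available via ``printed_form``.
    Identical images return the documented cap (:data:`PSNR_CAP`).
    """
    o, g = _check_same_shape(o, g)
    err = mse(o, g)
    if err == 0:
        return PSNR_CAP
    peak = float(o.max())
    if printed_form:
        return float(20 * np.log10(peak) - 20 * np.log10(err))
    return float(10 * np.log10(peak**2 / err))


def blur_index(img) -> float:
    """No-reference blur index from horizontal prediction residues.

    Residues ``p(i,j) = x(i,j+1) - x(i,j)``; the index is the mean squared
    deviation of the residues from their per-image median.  Zero for constant
    images; on a textured image it shrinks as the image is blurred (Gaussian
    smoothing flattens local differences), so sharper images score higher.
    """
    img = _img(img)
    if img.ndim != 2 or img.shape[1] < 2:
        raise ValueError("blur_index requires a 2-D image with >= 2 columns")
    residues = img[:, 1:] - img[:, :-1]
    return float(np.mean((residues - np.median(residues)) ** 2))


PAIRWISE_METRICS: Mapping[str, Callable] = {
    "ssim": ssim,
    "uqm": uqm,
    "mi": mutual_information,
    "mse": mse,
    "psnr": psnr,
}


# ---------------------------------------------------------------------------
# group aggregation
# ---------------------------------------------------------------------------


def pairwise_group_average(
    metric: str | Callable,
    group_o: Sequence[np.ndarray],
    group_g: Sequence[np.ndarray],
    exclude_diagonal: bool = False,
) -> float:
    """Mean of a pairwise metric over the full cross-product of two groups.

    ``exclude_diagonal`` drops pairs with equal indices, which is how the
    original-vs-original reference range avoids trivial self-comparisons.
    """
    if isinstance(metric, str):
        if metric not in PAIRWISE_METRICS:
            raise ValueError(
                f"{metric!r} is not a pairwise metric; choose from {sorted(PAIRWISE_METRICS)}"
            )
        metric = PAIRWISE_METRICS[metric]
    if not len(group_o) or not len(group_g):
        raise ValueError("groups must be non-empty")
    values = [
        metric(o, g)
        for i, o in enumerate(group_o)
        for j, g in enumerate(group_g)
        if not (exclude_diagonal and i == j)
    ]
    if not values:
        raise ValueError("no pairs left after excluding the diagonal")
    return float(np.mean(values))


def _pairwise_values(metric, group, exclude_diagonal=True):
    fn = PAIRWISE_METRICS[metric]
    return [
        fn(a, b)
        for i, a in enumerate(group)
        for j, b in enumerate(group)
        if not (exclude_diagonal and i == j)
    ]


def group_report(
    original: Sequence[np.ndarray],
    synthetic_groups: Mapping[str, Sequence[np.ndarray]],
    original_stages: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Reference ranges on the originals plus per-group averages, tidy layout.

    For each pairwise metric the original row is the (min, max) over all
    ordered original pairs (diagonal excluded) and each synthetic group gets
    the mean over the full cross-product against the originals.  FID is
    group-wise: the reference range comes from comparing original
    developmental-stage subgroups (``original_stages`` labels; default three
    contiguous chunks), each synthetic group is compared against all
    originals.  Blur is per-image: originals report min/max, synthetic groups
    the group mean.

    Returns a DataFrame with columns ``group, metric, statistic, value``.
    """
    if not isinstance(synthetic_groups, Mapping):
        raise TypeError("synthetic_groups must map group label -> image list")
    rows = []

    # pairwise metrics
    for name in PAIRWISE_METRICS:
        vals = _pairwise_values(name, original)
        rows.append(("original", name, "min", float(np.min(vals))))
        rows.append(("original", name, "max", float(np.max(vals))))
        for label, group in synthetic_groups.items():
            rows.append(
                (label, name, "mean", pairwise_group_average(name, original, group))
            )

    # FID reference range from developmental-stage subgroups
    if original_stages is None:
        stages = np.array_split(np.arange(len(original)), 3)
    else:
        labels = np.asarray(original_stages)
        stages = [np.flatnonzero(labels == s) for s in np.unique(labels)]
    stages = [s for s in stages if len(s) >= 2]
    fids = [
        fid([original[i] for i in sa], [original[i] for i in sb])
        for k, sa in enumerate(stages)
        for sb in stages[k + 1 :]
    ]
    if fids:
        rows.append(("original", "fid", "min", float(np.min(fids))))
        rows.append(("original", "fid", "max", float(np.max(fids))))
    for label, group in synthetic_groups.items():
        rows.append((label, "fid", "mean", fid(original, group)))

    # blur: per-image
    blur_orig = [blur_index(img) for img in original]
    rows.append(("original", "blur", "min", float(np.min(blur_orig))))
    rows.append(("original", "blur", "max", float(np.max(blur_orig))))
    for label, group in synthetic_groups.items():
        rows.append((label, "blur", "mean", float(np.mean([blur_index(i) for i in group]))))

    return pd.DataFrame(rows, columns=["group", "metric", "statistic", "value"])
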