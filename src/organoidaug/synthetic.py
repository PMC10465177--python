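"""Synthetic bright-field organoid images, masks, and simulated expert sessions.

The generator emulates the look of transmitted-light acquisitions of brain
organoids: an ovoid body on a light-to-dark vertical illumination gradient,
a brighter speckled neuroepithelial rim, a sparse halo of dispersed cells,
optional acquisition artifacts, and controllable blur/noise.  Every generated
image comes with its exact ground-truth support mask.

A companion simulator produces expert decision records (real / generated /
pass, plus a decision time) from configurable per-group false-positive
probabilities, so the psychovisual analysis stages can be exercised and their
parameter recovery tested without human sessions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "OrganoidParams",
    "ExpertProfile",
    "DecisionRecord",
    "make_organoid",
    "make_dataset",
    "default_params_sampler",
    "degrade",
    "simulate_experts",
    "write_session_csvs",
    "read_session_csvs",
]

#: loss-group labels used throughout the toolkit
SYNTHETIC_GROUPS = ("BCE", "BCE_L1", "LS", "POISSON", "WASS", "P_WASS")
ORIGINAL_GROUP = "original"
ANSWERS = ("real", "generated", "pass")


@dataclass(frozen=True)
class OrganoidParams:
    """Parameters of one synthetic organoid acquisition.

    Intensities are 8-bit units; lengths are pixels.  The same params + seed
    always produce bit-identical output.
    """

    canvas_size: tuple[int, int] = (250, 250)
    center: tuple[float, float] | None = None  # (row, col); None -> canvas centre
    semi_axes: tuple[float, float] = (70.0, 55.0)  # (row, col) semi-axes
    rim_width: float = 8.0
    rim_texture_amplitude: float = 18.0
    halo_density: float = 0.02
    background_gradient: tuple[float, float] = (215.0, 70.0)  # top, bottom
    artifact_count: int = 0
    blur_sigma: float = 0.0
    noise_sigma: float = 0.0
    boundary_wobble: float = 0.0  # relative amplitude of rim undulation; 0 = exact ellipse
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.canvas_size
        if h < 8 or w < 8:
            raise ValueError("canvas too small")
        if self.halo_density < 0 or self.halo_density > 1:
            raise ValueError("halo_density must be in [0, 1]")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("blur/noise sigma must be >= 0")
        if self.artifact_count < 0:
            raise ValueError("artifact_count must be >= 0")
        a, b = self.semi_axes
        cy, cx = self.effective_center
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        if cy - a < 0 or cy + a > h - 1 or cx - b < 0 or cx + b > w - 1:
            raise ValueError(
                f"semi-axes {self.semi_axes} at centre ({cy}, {cx}) exceed the "
                f"{h}x{w} canvas"
            )

    @property
    def effective_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        h, w = self.canvas_size
        return ((h - 1) / 2.0, (w - 1) / 2.0)


def _ellipse_field(params: OrganoidParams, rng: np.random.Generator):
    """Normalised elliptic radius r(y,x) (<=1 inside body), with optional wobble."""
    h, w = params.canvas_size
    cy, cx = params.effective_center
    a, b = params.semi_axes
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.sqrt(((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2)
    if params.boundary_wobble > 0:
        theta = np.arctan2(yy - cy, xx - cx)
        k1, k2 = rng.integers(2, 6, size=2)
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        wobble = 0.6 * np.cos(k1 * theta + p1) + 0.4 * np.cos(k2 * theta + p2)
        r = r * (1.0 + params.boundary_wobble * wobble)
    return r


def make_organoid(params: OrganoidParams) -> tuple[np.ndarray, np.ndarray]:
    """Render one organoid image and its ground-truth mask.

    Returns
    -------
    image : (H, W) uint8
        Bright-field style intensity image.
    mask : (H, W) uint8, values {0, 1}
        Support of the organoid body.  With ``boundary_wobble = 0`` this is
        the exact discrete ellipse implied by ``semi_axes``.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.canvas_size
    r = _ellipse_field(params, rng)
    mask = (r <= 1.0).astype(np.uint8)

    top, bottom = params.background_gradient
    col = np.linspace(top, bottom, h)
    img = np.repeat(col[:, None], w, axis=1)

    # body: darker interior with mild radial shading (denser tissue at core)
    body = 120.0 - 35.0 * (1.0 - np.clip(r, 0, 1)) ** 1.5
    img = np.where(mask == 1, body, img)

    # neuroepithelial rim: bright band with speckle texture just inside the edge
    a, b = params.semi_axes
    rim_rel = params.rim_width / min(a, b)
    rim = (r <= 1.0) & (r >= 1.0 - rim_rel)
    if rim.any():
        speckle = rng.normal(0.0, 1.0, size=(h, w))
        speckle = ndimage.gaussian_filter(speckle, 1.0)
        img[rim] = 165.0 + params.rim_texture_amplitude * speckle[rim]

    # halo of dispersed cells outside the rim
    halo_zone = (r > 1.02) & (r < 1.45)
    if params.halo_density > 0 and halo_zone.any():
        dots = (rng.random((h, w)) < params.halo_density) & halo_zone
        dot_img = ndimage.grey_dilation(dots.astype(float), size=(2, 2))
        img = np.where(dot_img > 0, np.minimum(img, 60.0), img)

    # acquisition artifacts: bright elongated smears anywhere on the canvas
    for _ in range(params.artifact_count):
        ay, ax = rng.integers(0, h), rng.integers(0, w)
        length = int(rng.integers(8, 25))
        angle = rng.uniform(0, np.pi)
        ys = np.clip((ay + np.arange(length) * np.sin(angle)).astype(int), 0, h - 1)
        xs = np.clip((ax + np.arange(length) * np.cos(angle)).astype(int), 0, w - 1)
        img[ys, xs] = 245.0

    if params.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma)
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


def default_params_sampler(rng: np.random.Generator) -> OrganoidParams:
    """Sample realistic acquisition-to-acquisition variability.

    Emulates the batch syndrome of organoid cultures: sizes, eccentricity and
    position vary between acquisitions, as do rim texture and focus quality.
    """
    a = rng.uniform(50, 85)
    b = rng.uniform(45, min(80, a + 10))
    h = w = 250
    cy = rng.uniform(a + 2, h - 3 - a)
    cx = rng.uniform(b + 2, w - 3 - b)
    return OrganoidParams(
        canvas_size=(h, w),
        center=(cy, cx),
        semi_axes=(a, b),
        rim_width=rng.uniform(5, 12),
        rim_texture_amplitude=rng.uniform(10, 25),
        halo_density=rng.uniform(0.005, 0.04),
        background_gradient=(rng.uniform(200, 230), rng.uniform(50, 90)),
        artifact_count=int(rng.integers(0, 3)),
        blur_sigma=rng.uniform(0.0, 1.2),
        noise_sigma=rng.uniform(0.0, 6.0),
    )


def make_dataset(
    n: int,
    params_sampler: Callable[[np.random.Generator], OrganoidParams] | None = None,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate ``n`` (image, mask) pairs with per-image seeds derived from ``seed``."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    sampler = params_sampler or default_params_sampler
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n):
        rng = np.random.default_rng(child)
        params = sampler(rng)
        params = replace(params, seed=int(child.generate_state(1)[0] % 2**31))
        out.append(make_organoid(params))
    return out


def degrade(
    image: np.ndarray, blur_sigma: float, noise_sigma: float, seed: int = 0
) -> np.ndarray:
    """Apply Gaussian blur and additive Gaussian noise; identity at zero sigmas."""
    if blur_sigma < 0 or noise_sigma < 0:
        raise ValueError("sigmas must be >= 0")
    img = np.asarray(image)
    if blur_sigma == 0 and noise_sigma == 0:
        return img.copy()
    out = img.astype(float)
    if blur_sigma > 0:
        out = ndimage.gaussian_filter(out, blur_sigma)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    return np.clip(np.rint(out), 0, 255).astype(img.dtype)


# ---------------------------------------------------------------------------
# simulated experts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpertProfile:
    """Behavioural model of one simulated evaluator.

    ``fp_prob_by_group`` maps each synthetic loss group to the probability of
    calling its images "real" (a false positive).  ``fn_prob`` is the chance
    of calling an original image "generated".  Decision times are lognormal
    per category; errors are parameterised slower than correct answers, which
    mirrors the longer hesitation observed on wrong calls.
    """

    expert_id: str
    fp_prob_by_group: dict[str, float] = field(
        default_factory=lambda: {g: 0.3 for g in SYNTHETIC_GROUPS}
    )
    fn_prob: float = 0.07
    pass_prob: float = 0.0
    #: category -> (mu, sigma) of log-time; categories: correct, error, pass
    time_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "correct": (np.log(2.0), 0.45),
            "error": (np.log(3.5), 0.45),
            "pass": (np.log(1.5), 0.45),
        }
    )

    def __post_init__(self) -> None:
        for p in (*self.fp_prob_by_group.values(), self.fn_prob, self.pass_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class DecisionRecord:
    """One expert's answer for one image."""

    expert_id: str
    image_id: str
    group: str
    true_label: str  # real | generated
    answer: str  # real | generated | pass
    time_s: float

    def __post_init__(self) -> None:
        if self.answer not in ANSWERS:
            raise ValueError(f"answer must be one of {ANSWERS}")
        if self.time_s <= 0:
            raise ValueError("time_s must be > 0")


def simulate_experts(
    images: Sequence[tuple[str, str]],
    profiles: Sequence[ExpertProfile],
    seed: int = 0,
) -> list[DecisionRecord]:
    """Simulate one full session per expert over ``images``.

    Parameters
    ----------
    images : sequence of (image_id, group)
        ``group`` is ``"original"`` or one of the synthetic loss groups.
    profiles : sequence of ExpertProfile
    seed : int
        Master seed; the run is fully deterministic.

    Returns one record per (expert, image).
    """
    if not profiles:
        raise ValueError("at least one expert profile is required")
    for _, group in images:
        if group != ORIGINAL_GROUP:
            for prof in profiles:
                if group not in prof.fp_prob_by_group:
                    raise KeyError(
                        f"group {group!r} missing from fp_prob_by_group of "
                        f"expert {prof.expert_id!r}"
                    )
    rng = np.random.default_rng(seed)
    records: list[DecisionRecord] = []
    for prof in profiles:
        for image_id, group in images:
            true_label = "real" if group == ORIGINAL_GROUP else "generated"
            u = rng.random()
            if u < prof.pass_prob:
                answer, category = "pass", "pass"
            else:
                v = rng.random()
                if group == ORIGINAL_GROUP:
                    wrong = v < prof.fn_prob
                    answer = "generated" if wrong else "real"
                else:
                    wrong = v < prof.fp_prob_by_group[group]
                    answer = "real" if wrong else "generated"
                category = "error" if wrong else "correct"
            mu, sigma = prof.time_model[category]
            time_s = float(np.exp(rng.normal(mu, sigma)))
            records.append(
                DecisionRecord(prof.expert_id, image_id, group, true_label, answer, time_s)
            )
    return records


# ---------------------------------------------------------------------------
# session CSV round-trip
# ---------------------------------------------------------------------------

RANDOMIZATION_COLUMNS = ["presentation_index", "image_path", "true_label", "group"]
DECISION_COLUMNS = ["expert_id", "timestamp", "presentation_index", "answer", "time_s"]


def write_session_csvs(
    records: Iterable[DecisionRecord],
    randomization_path: str | Path,
    decisions_path: str | Path,
) -> None:
    """Write the two per-session CSV files (presentation order + decisions).

    The randomization file lists each distinct image once, in presentation
    order, with its hidden true label and group; the decision file holds one
    row per (expert, image) answer.  ``read_session_csvs`` inverts this
    losslessly.
    """
    records = list(records)
    order: dict[str, int] = {}
    meta: dict[str, tuple[str, str]] = {}
    for rec in records:
        if rec.image_id not in order:
            order[rec.image_id] = len(order)
            meta[rec.image_id] = (rec.true_label, rec.group)
    with open(randomization_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RANDOMIZATION_COLUMNS)
        for image_id, idx in order.items():
            true_label, group = meta[image_id]
            writer.writerow([idx, image_id, true_label, group])
    with open(decisions_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DECISION_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.expert_id, "", order[rec.image_id], rec.answer, repr(rec.time_s)]
            )


def _check_header(got: list[str] | None, want: list[str], path) -> None:
    if got != want:
        raise ValueError(f"{path}: line 1: expected header {want}, got {got}")


def read_session_csvs(
    randomization_path: str | Path, decisions_path: str | Path
) -> list[DecisionRecord]:
    """Read a session back into decision records (inverse of the writer)."""
    images: dict[int, tuple[str, str, str]] = {}
    with open(randomization_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        _check_header(next(reader, None), RANDOMIZATION_COLUMNS, randomization_path)
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 4:
                raise ValueError(f"{randomization_path}: line {lineno}: expected 4 fields")
            try:
                idx = int(row[0])
            except ValueError as exc:
                raise ValueError(
                    f"{randomization_path}: line {lineno}: bad presentation_index {row[0]!r}"
                ) from exc
            images[idx] = (row[1], row[2], row[3])
    records = []
    with open(decisions_path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        _check_header(next(reader, None), DECISION_COLUMNS, decisions_path)
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 5:
                raise ValueError(f"{decisions_path}: line {lineno}: expected 5 fields")
            expert_id, _, idx_s, answer, time_s = row
            try:
                idx = int(idx_s)
                time = float(time_s)
            except ValueError as exc:
                raise ValueError(f"{decisions_path}: line {lineno}: bad numeric field") from exc
            if answer not in ANSWERS:
                raise ValueError(
                    f"{decisions_path}: line {lineno}: answer {answer!r} not in {ANSWERS}"
                )
            if idx not in images:
                raise ValueError(
                    f"{decisions_path}: line {lineno}: presentation_index {idx} "
                    "absent from randomization file"
                )
            image_id, true_label, group = images[idx]
            records.append(DecisionRecord(expert_id, image_id, group, true_label, answer, time))
    return records
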