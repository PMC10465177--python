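"""Discriminator/reconstruction losses for the adversarial autoencoder.

Six losses are available, each comparing a real image tensor ``y`` with a
predicted/generated tensor ``y_prime``:

``bce``
    binary cross-entropy, the GAN baseline.
``bce_l1``
    BCE plus an L1 deviation term weighted by ``alpha`` (default 1e-4).
``ls``
    least squares (mean squared difference).
``poisson``
    Poisson-likelihood-style loss with regulariser ``epsilon`` (default 0.25).
``wass``
    order-1 optimal-transport cost between the two empirical intensity
    distributions, computed exactly by the 1-D sorted-sample coupling.
``p_wass``
    "perceptual Wasserstein": the same transport plan with a squared
    ground distance.

All functions accept array-likes of any shape; the batch is flattened and the
loss is a mean over elements.  ``loss_and_grad`` additionally returns the
gradient with respect to ``y_prime``, which is what the training loop
backpropagates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LOSS_NAMES",
    "LossSpec",
    "bce_loss",
    "bce_l1_loss",
    "ls_loss",
    "poisson_loss",
    "wasserstein_loss",
    "perceptual_wasserstein_loss",
    "get_loss",
    "loss_and_grad",
]

LOSS_NAMES = ("bce", "bce_l1", "ls", "poisson", "wass", "p_wass")

#: clipping floor for BCE probabilities; keeps log() finite and tests exact
BCE_DELTA = 1e-7


@dataclass(frozen=True)
class LossSpec:
    """Configuration of one generative-loss variant.

    Parameters
    ----------
    name : str
        One of :data:`LOSS_NAMES`.
    alpha : float
        Weight of the L1 term in ``bce_l1`` (default 1e-4).
    epsilon : float
        Additive regulariser inside the Poisson log (default 0.25).
    """

    name: str
    alpha: float = 1e-4
    epsilon: float = 0.25

    def __post_init__(self) -> None:
        if self.name not in LOSS_NAMES:
            raise ValueError(f"unknown loss {self.name!r}; expected one of {LOSS_NAMES}")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def _pair(y, y_prime):
    y = np.asarray(y, dtype=float)
    yp = np.asarray(y_prime, dtype=float)
    if y.shape != yp.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs y_prime {yp.shape}")
    if y.size == 0:
        raise ValueError("empty batch")
    return y.ravel(), yp.ravel()


def bce_loss(y, y_prime) -> float:
    """Mean binary cross-entropy; ``y_prime`` is clipped to (delta, 1-delta)."""
    y, yp = _pair(y, y_prime)
    if yp.min() < 0 or yp.max() > 1:
        raise ValueError("y_prime must lie in [0, 1] for BCE")
    yp = np.clip(yp, BCE_DELTA, 1 - BCE_DELTA)
    return float(np.mean(-(y * np.log(yp) + (1 - y) * np.log(1 - yp))))


def bce_l1_loss(y, y_prime, alpha: float = 1e-4) -> float:
    """BCE plus ``alpha`` times the mean absolute deviation."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    y_, yp_ = _pair(y, y_prime)
    return bce_loss(y, y_prime) + alpha * float(np.mean(np.abs(y_ - yp_)))


def ls_loss(y, y_prime) -> float:
    """Mean squared difference."""
    y, yp = _pair(y, y_prime)
    return float(np.mean((y - yp) ** 2))


def poisson_loss(y, y_prime, epsilon: float = 0.25) -> float:
    """Mean of ``(y' - y) * log(y' + epsilon)``.

    May be negative; the sign carries information about under- vs
    over-prediction and is documented rather than clamped.
    """
    y, yp = _pair(y, y_prime)
    if np.any(yp + epsilon <= 0):
        raise ValueError("y_prime + epsilon must be > 0")
    return float(np.mean((yp - y) * np.log(yp + epsilon)))


def wasserstein_loss(y, y_prime) -> float:
    """Exact order-1 transport cost between the flattened empirical distributions.

    In 1-D the optimal coupling pairs sorted samples, so the cost is the mean
    absolute difference of the order statistics.
    """
    y, yp = _pair(y, y_prime)
    return float(np.mean(np.abs(np.sort(y) - np.sort(yp))))


def perceptual_wasserstein_loss(y, y_prime) -> float:
    """Transport cost with squared ground distance on the sorted coupling."""
    y, yp = _pair(y, y_prime)
    return float(np.mean((np.sort(y) - np.sort(yp)) ** 2))


def get_loss(spec: LossSpec):
    """Return ``f(y, y_prime) -> float`` for a :class:`LossSpec`."""
    if spec.name == "bce":
        return bce_loss
    if spec.name == "bce_l1":
        return lambda y, yp: bce_l1_loss(y, yp, alpha=spec.alpha)
    if spec.name == "ls":
        return ls_loss
    if spec.name == "poisson":
        return lambda y, yp: poisson_loss(y, yp, epsilon=spec.epsilon)
    if spec.name == "wass":
        return wasserstein_loss
    if spec.name == "p_wass":
        return perceptual_wasserstein_loss
    raise ValueError(spec.name)  # pragma: no cover - guarded by LossSpec


def loss_and_grad(spec: LossSpec, y: np.ndarray, y_prime: np.ndarray):
    """Loss value and its gradient w.r.t. ``y_prime`` (same shape as input).

    The sort-based transport losses are piecewise smooth; their gradient is
    routed back through the sorting permutation.
    """
    shape = np.asarray(y_prime).shape
    yf, ypf = _pair(y, y_prime)
    n = yf.size
    name = spec.name

    if name in ("bce", "bce_l1"):
        ypc = np.clip(ypf, BCE_DELTA, 1 - BCE_DELTA)
        grad = (ypc - yf) / (ypc * (1 - ypc)) / n
        value = bce_loss(yf, ypf)
        if name == "bce_l1":
            value += spec.alpha * float(np.mean(np.abs(yf - ypf)))
            grad = grad + spec.alpha * np.sign(ypf - yf) / n
    elif name == "ls":
        value = ls_loss(yf, ypf)
        grad = 2 * (ypf - yf) / n
    elif name == "poisson":
        value = poisson_loss(yf, ypf, epsilon=spec.epsilon)
        grad = (np.log(ypf + spec.epsilon) + (ypf - yf) / (ypf + spec.epsilon)) / n
    else:
        order_y = np.sort(yf)
        perm = np.argsort(ypf, kind="stable")
        diff_sorted = ypf[perm] - order_y
        grad = np.empty(n)
        if name == "wass":
            value = float(np.mean(np.abs(diff_sorted)))
            grad[perm] = np.sign(diff_sorted) / n
        else:
            value = float(np.mean(diff_sorted**2))
            grad[perm] = 2 * diff_sorted / n
    return value, grad.reshape(shape)
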