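"""Adversarial autoencoder for small grayscale image sets.

The generator is an encoder-decoder: a dense encoder maps each image to a
latent vector, a mirrored decoder reconstructs it.  A small discriminator on
the latent space is trained to tell encoded latents from draws of a standard
Gaussian prior; the encoder is simultaneously trained to fool it, which
regularises the latent distribution toward the prior so that decoding prior
samples yields new images.

The reconstruction criterion is pluggable: any of the six losses in
:mod:`organoidaug.losses` (BCE, BCE+L1, least squares, Poisson, Wasserstein,
perceptual Wasserstein) can drive the generator.  Training is plain
minibatch Adam implemented in numpy, fully deterministic under a seed.

Defaults follow the study conditions (2000 epochs, 250x250 images, latent
dimension 64); tests and examples use a desk-scale profile (64x64, <=100
epochs) which already exhibits the contract behaviour (reconstruction error
strictly decreases; synthesis produces in-range images).
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator

from .losses import LossSpec, loss_and_grad

__all__ = ["AdversarialAutoencoder", "train_aae", "synthesize"]


def _adam_step(param, grad, state, lr, t, b1=0.9, b2=0.999, eps=1e-8):
    m, v = state
    m[...] = b1 * m + (1 - b1) * grad
    v[...] = b2 * v + (1 - b2) * grad**2
    mhat = m / (1 - b1**t)
    vhat = v / (1 - b2**t)
    param -= lr * mhat / (np.sqrt(vhat) + eps)


class _MLP:
    """Two-layer perceptron with tanh hidden activation."""

    def __init__(self, sizes, rng, out_activation):
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self.out_activation = out_activation
        self.opt = [(np.zeros_like(w), np.zeros_like(w)) for w in self.W] + [
            (np.zeros_like(b), np.zeros_like(b)) for b in self.b
        ]

    def forward(self, x):
        cache = [x]
        h = x
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            z = h @ w + b
            last = i == len(self.W) - 1
            if not last:
                h = np.tanh(z)
            elif self.out_activation == "sigmoid":
                h = 1.0 / (1.0 + np.exp(-z))
            else:
                h = z
            cache.append(h)
        return h, cache

    def backward(self, cache, grad_out, lr, t):
        """Backprop grad of loss w.r.t. output; Adam-update weights in place.

        Returns grad w.r.t. the input (for chaining encoder <- decoder /
        discriminator).
        """
        g = grad_out
        out = cache[-1]
        if self.out_activation == "sigmoid":
            g = g * out * (1 - out)
        for i in range(len(self.W) - 1, -1, -1):
            h_in = cache[i]
            gW = h_in.T @ g
            gb = g.sum(axis=0)
            g_in = g @ self.W[i].T
            _adam_step(self.W[i], gW, self.opt[i], lr, t)
            _adam_step(self.b[i], gb, self.opt[len(self.W) + i], lr, t)
            if i > 0:
                g_in = g_in * (1 - cache[i] ** 2)  # through tanh
            g = g_in
        return g


class AdversarialAutoencoder(BaseEstimator):
    """Seedable adversarial autoencoder with a pluggable generative loss.

    Parameters
    ----------
    loss : str
        One of ``bce, bce_l1, ls, poisson, wass, p_wass``.
    alpha, epsilon : float
        Loss hyper-parameters (L1 weight, Poisson regulariser).
    epochs : int
        Training epochs (study default 2000; use ~50-100 at desk scale).
    batch_size : int or None
        None trains full-batch.
    latent_dim, hidden_dim : int
        Latent size and hidden width of encoder/decoder.
    lr, adv_lr : float
        Adam learning rates of the autoencoder and of the latent adversarial
        game.
    adv_weight : float
        Weight of the encoder's fooling term relative to reconstruction.
    recon_weight : float
        Weight of the pixelwise-MSE autoencoding backbone that anchors the
        reconstruction under every configured loss.
    random_state : int
        Seed controlling init, batching, and the prior draws.

    Attributes
    ----------
    history_ : list of float
        Per-epoch training loss (reconstruction criterion).
    initial_mse_, final_mse_ : float
        Reconstruction MSE (on [0,1]-scaled pixels) before and after training.
    image_shape_ : tuple
        Shape of the training images.
    """

    def __init__(
        self,
        loss="bce",
        alpha=1e-4,
        epsilon=0.25,
        epochs=2000,
        batch_size=None,
        latent_dim=64,
        hidden_dim=128,
        lr=1e-3,
        adv_lr=1e-3,
        adv_weight=0.05,
        recon_weight=1.0,
        random_state=0,
    ):
        self.loss = loss
        self.alpha = alpha
        self.epsilon = epsilon
        self.epochs = epochs
        self.batch_size = batch_size
        self.latent_dim = latent_dim
        self.hidden_dim = hidden_dim
        self.lr = lr
        self.adv_lr = adv_lr
        self.adv_weight = adv_weight
        self.recon_weight = recon_weight
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    @property
    def group_label_(self) -> str:
        """Loss-group tag attached to synthesized images (e.g. ``P_WASS``)."""
        return self.loss.upper()

    def _validate_images(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[0] < 2:
            raise ValueError("expected >= 2 images of identical size, shape (n, h, w)")
        return X

    def _recon(self, flat):
        z, _ = self.encoder_.forward(flat)
        out, _ = self.decoder_.forward(z)
        return out

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y=None):
        """Train on a stack of grayscale images, shape (n, h, w), range [0, 255]."""
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        spec = LossSpec(self.loss, alpha=self.alpha, epsilon=self.epsilon)
        X = self._validate_images(X)
        n, h, w = X.shape
        self.image_shape_ = (h, w)
        flat = (X / 255.0).reshape(n, h * w)

        rng = np.random.default_rng(self.random_state)
        d = h * w
        self.encoder_ = _MLP([d, self.hidden_dim, self.latent_dim], rng, "linear")
        self.decoder_ = _MLP([self.latent_dim, self.hidden_dim, d], rng, "sigmoid")
        self.discriminator_ = _MLP([self.latent_dim, 32, 1], rng, "sigmoid")

        self.initial_mse_ = float(np.mean((self._recon(flat) - flat) ** 2))
        self.history_ = []
        batch = n if self.batch_size is None else min(self.batch_size, n)
        t = 0
        eps = 1e-8
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            nb = 0
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                xb = flat[idx]
                t += 1

                # --- reconstruction phase (generative loss) ---
                z, enc_cache = self.encoder_.forward(xb)
                xr, dec_cache = self.decoder_.forward(z)
                value, grad = loss_and_grad(spec, xb, xr)
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"non-finite {self.loss} loss at epoch {epoch}; aborting"
                    )
                # autoencoding backbone: pixelwise MSE always anchors the
                # reconstruction; the configured loss shapes it on top (for
                # the transport losses this is what keeps spatial structure)
                grad = grad + self.recon_weight * 2.0 * (xr - xb) / xr.size
                g_z = self.decoder_.backward(dec_cache, grad, self.lr, t)
                self.encoder_.backward(enc_cache, g_z, self.lr, t)
                epoch_loss += value
                nb += 1

                # --- latent adversarial phase ---
                z, enc_cache = self.encoder_.forward(xb)
                z_prior = rng.standard_normal(z.shape)
                # discriminator: prior -> 1, encoded -> 0 (BCE)
                for latents, target in ((z_prior, 1.0), (z, 0.0)):
                    p, cache = self.discriminator_.forward(latents)
                    gd = (p - target) / (p * (1 - p) + eps) / len(p)
                    self.discriminator_.backward(cache, gd, self.adv_lr, t)
                # encoder fools: encoded -> 1, gradient through frozen critic
                p, cache = self.discriminator_.forward(z)
                g_out = (p - 1.0) / (p * (1 - p) + eps) / len(p)
                g = g_out * p * (1 - p)
                for i in range(len(self.discriminator_.W) - 1, -1, -1):
                    g = g @ self.discriminator_.W[i].T
                    if i > 0:
                        g = g * (1 - cache[i] ** 2)
                self.encoder_.backward(enc_cache, self.adv_weight * g, self.adv_lr, t)
            self.history_.append(epoch_loss / nb)

        self.final_mse_ = float(np.mean((self._recon(flat) - flat) ** 2))
        self.final_loss_ = self.history_[-1]
        return self

    def reconstruct(self, X):
        """Reconstruct images through the autoencoder, returned as uint8."""
        X = self._validate_images(X)
        n = X.shape[0]
        out = self._recon((X / 255.0).reshape(n, -1))
        return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8).reshape(X.shape)

    def sample(self, n, random_state=None):
        """Decode ``n`` prior draws into synthetic images (uint8, [0, 255])."""
        if not hasattr(self, "decoder_"):
            raise RuntimeError("model is not fitted")
        if n <= 0:
            raise ValueError("n must be >= 1")
        seed = self.random_state if random_state is None else random_state
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, self.latent_dim))
        out, _ = self.decoder_.forward(z)
        h, w = self.image_shape_
        return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8).reshape(n, h, w)

    # -- persistence ------------------------------------------------------
    def save(self, path):
        """Save weights + config as a single-file npz archive."""
        arrays = {}
        for name, net in (
            ("enc", self.encoder_),
            ("dec", self.decoder_),
            ("dis", self.discriminator_),
        ):
            for i, (w, b) in enumerate(zip(net.W, net.b)):
                arrays[f"{name}_W{i}"] = w
                arrays[f"{name}_b{i}"] = b
        config = {**self.get_params(), "image_shape": list(self.image_shape_)}
        arrays["config"] = np.frombuffer(
            json.dumps(config).encode("utf-8"), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path) as data:
            config = json.loads(bytes(data["config"]).decode("utf-8"))
            image_shape = tuple(config.pop("image_shape"))
            model = cls(**config)
            model.image_shape_ = image_shape
            rng = np.random.default_rng(0)
            d = image_shape[0] * image_shape[1]
            model.encoder_ = _MLP([d, model.hidden_dim, model.latent_dim], rng, "linear")
            model.decoder_ = _MLP([model.latent_dim, model.hidden_dim, d], rng, "sigmoid")
            model.discriminator_ = _MLP([model.latent_dim, 32, 1], rng, "sigmoid")
            for name, net in (
                ("enc", model.encoder_),
                ("dec", model.decoder_),
                ("dis", model.discriminator_),
            ):
                for i in range(len(net.W)):
                    net.W[i] = data[f"{name}_W{i}"]
                    net.b[i] = data[f"{name}_b{i}"]
        return model


def train_aae(images, loss_spec: LossSpec, **config) -> AdversarialAutoencoder:
    """Functional wrapper: train an AAE with the given loss on an image stack."""
    model = AdversarialAutoencoder(
        loss=loss_spec.name, alpha=loss_spec.alpha, epsilon=loss_spec.epsilon, **config
    )
    return model.fit(np.asarray(images))


def synthesize(model: AdversarialAutoencoder, n: int, seed: int | None = None):
    """Generate ``n`` images tagged with the model's loss-group label."""
    images = model.sample(n, random_state=seed)
    return [(img, model.group_label_) for img in images]
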