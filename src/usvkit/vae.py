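"""Variational autoencoder over syllable spectrogram images.

A VAE compresses each 128x128 syllable image x into a low-dimensional latent
vector z by jointly training a probabilistic encoder q(z|x) = N(mu(x),
diag(sigma^2(x))) and decoder p(x|z) = N(decode(z), sigma_obs^2 I), maximizing
the evidence lower bound

    ELBO = E_q[log p(x|z)] - KL(q(z|x) || N(0, I)).

The latent posterior means are the "latent syllable representations" used by
all repertoire statistics.  Because the KL term prices every latent
coordinate, the model tends to collapse unneeded coordinates back to the
prior; a coordinate is counted as informative when its average posterior
variance drops below a threshold (:func:`effective_dim`).

The implementation is a compact pure-NumPy MLP VAE trained with Adam and
manual backpropagation.  Two modes are provided: ``linear_fast`` (no hidden
layers; trains in seconds on CPU and is used throughout the test suite) and
``mlp`` (hidden ReLU layers for higher-fidelity reconstructions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "VAEConfig",
    "VAEModel",
    "LatentSet",
    "train_vae",
    "encode",
    "decode",
    "effective_dim",
    "interpolate_latents",
]


@dataclass(frozen=True)
class VAEConfig:
    latent_dim: int = 32
    hidden: tuple[int, ...] = (256,)
    learning_rate: float = 1e-3
    epochs: int = 20
    batch_size: int = 64
    obs_noise: float = 0.1  # fixed Gaussian observation scale
    seed: int = 0
    mode: Literal["linear_fast", "mlp"] = "linear_fast"

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def hidden_layers(self) -> tuple[int, ...]:
        return () if self.mode == "linear_fast" else self.hidden


@dataclass
class LatentSet:
    """Posterior means/variances per syllable, with provenance labels."""

    means: np.ndarray  # (n, latent_dim)
    variances: np.ndarray  # (n, latent_dim)
    labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.means.shape != self.variances.shape:
            raise ValueError("means and variances must have the same shape")
        if self.labels is not None and len(self.labels) != len(self.means):
            raise ValueError("labels row count must equal number of latent rows")

    def __len__(self) -> int:
        return len(self.means)


class VAEModel:
    """Trained encoder/decoder parameters plus training history."""

    def __init__(self, config: VAEConfig, input_dim: int):
        self.config = config
        self.input_dim = input_dim
        rng = np.random.default_rng(config.seed)
        d = config.latent_dim
        hid = config.hidden_layers

        def layer(n_in, n_out, scale=None):
            s = scale if scale is not None else np.sqrt(2.0 / n_in)
            return [rng.normal(0, s, (n_in, n_out)), np.zeros(n_out)]

        # encoder trunk (ReLU) + linear mu / logvar heads
        self.enc_trunk = []
        prev = input_dim
        for h in hid:
            self.enc_trunk.append(layer(prev, h))
            prev = h
        self.W_mu = layer(prev, d, scale=1.0 / np.sqrt(prev))
        # logvar head starts at zero: untrained posterior variance is exactly 1
        self.W_lv = [np.zeros((prev, d)), np.zeros(d)]

        # decoder: (ReLU hidden layers reversed) + linear output -> sigmoid
        self.dec_layers = []
        prev = d
        for h in reversed(hid):
            self.dec_layers.append(layer(prev, h))
            prev = h
        self.dec_out = layer(prev, input_dim, scale=1.0 / np.sqrt(prev))

        self.history = {"elbo": [], "reconstruction": [], "kl": []}
        self.posterior_var: np.ndarray | None = None  # (latent_dim,) after training
        self._rng = rng

    # ------------------------------------------------------------------ utils
    def _params(self):
        out = []
        for lay in self.enc_trunk:
            out.extend(lay)
        out.extend(self.W_mu)
        out.extend(self.W_lv)
        for lay in self.dec_layers:
            out.extend(lay)
        out.extend(self.dec_out)
        return out

    # ---------------------------------------------------------------- forward
    def _encode_batch(self, X: np.ndarray):
        acts = [X]
        h = X
        for W, b in self.enc_trunk:
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        mu = h @ self.W_mu[0] + self.W_mu[1]
        logvar = np.clip(h @ self.W_lv[0] + self.W_lv[1], -10.0, 10.0)
        return mu, logvar, acts

    def _decode_batch(self, Z: np.ndarray):
        acts = [Z]
        h = Z
        for W, b in self.dec_layers:
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        pre = h @ self.dec_out[0] + self.dec_out[1]
        Y = 1.0 / (1.0 + np.exp(-pre))
        return Y, acts


def _adam_step(params, grads, state, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
    for k, (p, g) in enumerate(zip(params, grads)):
        m, v = state[k]
        m *= beta1
        m += (1 - beta1) * g
        v *= beta2
        v += (1 - beta2) * g * g
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        p -= lr * mhat / (np.sqrt(vhat) + eps)


def train_vae(images: np.ndarray, cfg: VAEConfig | None = None) -> VAEModel:
    """Train a VAE on a stack of images in [0, 1].

    ``images`` has shape (n, H, W) or (n, d).  Training is deterministic
    given ``cfg.seed`` (initialization, minibatch shuffling, and the
    reparameterization noise all derive from it).
    """
    cfg = cfg or VAEConfig()
    X = np.asarray(images, dtype=np.float64)
    if X.ndim == 3:
        X = X.reshape(len(X), -1)
    if X.ndim != 2:
        raise ValueError("images must be (n, H, W) or (n, d)")
    n, dim = X.shape
    if n < cfg.batch_size:
        raise ValueError(f"need at least batch_size={cfg.batch_size} images, got {n}")
    if X.min() < -1e-6 or X.max() > 1 + 1e-6:
        raise ValueError("image values must lie in [0, 1]")

    model = VAEModel(cfg, dim)
    # start the decoder at the dataset mean image (logit-space bias init):
    # the first reconstructions already match the mean-image baseline
    p = np.clip(X.mean(axis=0), 1e-3, 1 - 1e-3)
    model.dec_out[1][:] = np.log(p / (1 - p))
    rng = model._rng
    params = model._params()
    state = [(np.zeros_like(p), np.zeros_like(p)) for p in params]
    inv_s2 = 1.0 / cfg.obs_noise**2
    t = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_recon = ep_kl = 0.0
        n_batches = 0
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = X[idx]
            B = len(xb)

            mu, logvar, eacts = model._encode_batch(xb)
            eps_z = rng.standard_normal(mu.shape)
            std = np.exp(0.5 * logvar)
            z = mu + eps_z * std
            y, dacts = model._decode_batch(z)

            resid = y - xb
            recon = 0.5 * inv_s2 * np.sum(resid**2) / B
            kl = 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar) / B
            if not np.isfinite(recon + kl):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: recon={recon}, kl={kl}"
                )

            # ---- backward (every parameter's gradient is assigned below)
            grads: list = [None] * len(params)
            gi = {id(p): i for i, p in enumerate(params)}

            dpre = (inv_s2 * resid / B) * y * (1.0 - y)
            h_last = dacts[-1]
            grads[gi[id(model.dec_out[0])]] = h_last.T @ dpre
            grads[gi[id(model.dec_out[1])]] = dpre.sum(0)
            dh = dpre @ model.dec_out[0].T
            for (W, b), h_in, h_out in zip(
                reversed(model.dec_layers), reversed(dacts[:-1]), reversed(dacts[1:])
            ):
                dh = dh * (h_out > 0)
                grads[gi[id(W)]] = h_in.T @ dh
                grads[gi[id(b)]] = dh.sum(0)
                dh = dh @ W.T
            dz = dh

            dmu = dz + mu / B
            dlv = dz * eps_z * 0.5 * std + 0.5 * (np.exp(logvar) - 1.0) / B
            h_enc = eacts[-1]
            grads[gi[id(model.W_mu[0])]] = h_enc.T @ dmu
            grads[gi[id(model.W_mu[1])]] = dmu.sum(0)
            grads[gi[id(model.W_lv[0])]] = h_enc.T @ dlv
            grads[gi[id(model.W_lv[1])]] = dlv.sum(0)
            dh = dmu @ model.W_mu[0].T + dlv @ model.W_lv[0].T
            for (W, b), h_in, h_out in zip(
                reversed(model.enc_trunk), reversed(eacts[:-1]), reversed(eacts[1:])
            ):
                dh = dh * (h_out > 0)
                grads[gi[id(W)]] = h_in.T @ dh
                grads[gi[id(b)]] = dh.sum(0)
                dh = dh @ W.T

            t += 1
            _adam_step(params, grads, state, cfg.learning_rate, t)
            ep_recon += recon
            ep_kl += kl
            n_batches += 1

        model.history["reconstruction"].append(-ep_recon / n_batches)
        model.history["kl"].append(ep_kl / n_batches)
        model.history["elbo"].append(-(ep_recon + ep_kl) / n_batches)

    # average posterior variance per latent dimension over the training set
    variances = []
    for start in range(0, n, 1024):
        _, lv, _ = model._encode_batch(X[start:start + 1024])
        variances.append(np.exp(lv))
    model.posterior_var = np.concatenate(variances).mean(axis=0)
    return model


def encode(model: VAEModel, images: np.ndarray,
           labels: pd.DataFrame | None = None) -> LatentSet:
    """Posterior means and variances for a stack of images (order preserved)."""
    X = np.asarray(images, dtype=np.float64)
    if X.ndim == 3:
        X = X.reshape(len(X), -1)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(f"expected images with {model.input_dim} pixels, got shape {X.shape}")
    mus, lvs = [], []
    for start in range(0, len(X), 1024):
        mu, lv, _ = model._encode_batch(X[start:start + 1024])
        mus.append(mu)
        lvs.append(np.exp(lv))
    return LatentSet(np.concatenate(mus), np.concatenate(lvs), labels)


def decode(model: VAEModel, z: np.ndarray) -> np.ndarray:
    """Decode latent vectors to images in [0, 1]."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    if z.shape[1] != model.config.latent_dim:
        raise ValueError(
            f"latent vectors must have {model.config.latent_dim} entries, got {z.shape[1]}"
        )
    Y, _ = model._decode_batch(z)
    side = int(round(np.sqrt(model.input_dim)))
    if side * side == model.input_dim:
        return Y.reshape(len(z), side, side)
    return Y


def effective_dim(
    model: VAEModel,
    threshold: float = 0.5,
    method: Literal["posterior_variance", "pca"] = "posterior_variance",
    latents: LatentSet | None = None,
    pca_variance: float = 0.99,
) -> int:
    """Number of informative (non-collapsed) latent dimensions.

    ``posterior_variance``: coordinates whose average posterior variance is
    below ``threshold`` (a collapsed coordinate reverts to the prior's unit
    variance).  ``pca``: number of principal components of the posterior
    means needed to reach ``pca_variance`` of total variance (requires
    ``latents``).
    """
    if method == "posterior_variance":
        if model.posterior_var is None:
            return 0
        return int(np.sum(model.posterior_var < threshold))
    if method == "pca":
        if latents is None:
            raise ValueError("pca method requires a LatentSet")
        centered = latents.means - latents.means.mean(0)
        sv = np.linalg.svd(centered, compute_uv=False)
        var = sv**2
        frac = np.cumsum(var) / var.sum()
        return int(np.searchsorted(frac, pca_variance) + 1)
    raise ValueError(f"unknown method {method!r}")


def interpolate_latents(model: VAEModel, z1: np.ndarray, z2: np.ndarray, n: int) -> np.ndarray:
    """Decode n images along the straight latent-space line from z1 to z2."""
    if n < 2:
        raise ValueError("n must be >= 2")
    z1 = np.asarray(z1, dtype=np.float64)
    z2 = np.asarray(z2, dtype=np.float64)
    alphas = np.linspace(0.0, 1.0, n)
    Z = (1 - alphas)[:, None] * z1[None, :] + alphas[:, None] * z2[None, :]
    return decode(model, Z)
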