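"""Unsupervised patch features from a variational autoencoder.

A small dense VAE maps each square RGB superpixel patch to the mean of a
diagonal-Gaussian posterior in a 100-dimensional latent space (the feature
vector), trained with per-pixel mean-squared reconstruction error plus the
closed-form KL divergence from the standard-normal prior,

    KL = 1/2 * sum_k (mu_k^2 + sigma_k^2 - 1 - log sigma_k^2).

Training uses the reparameterization z = mu + sigma * eps; inference uses the
posterior mean only, so feature extraction is deterministic.  The network is
implemented directly in numpy (forward pass, backpropagation and Adam), small
enough to train on a single CPU core in seconds to minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .errors import ArgumentError, DegenerateInputError, TrainingDivergenceError

_LOGVAR_CLIP = 10.0


@dataclass
class VaeConfig:
    latent_dim: int = 100
    patch_size: int = 64
    hidden_dim: int = 128
    epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 1e-3
    kl_weight: float | None = None  # default 0.1 / n_pixels, see train_vae
    seed: int = 0

    def validate(self) -> None:
        if self.latent_dim < 2:
            raise ArgumentError(f"latent_dim must be >= 2, got {self.latent_dim}")
        if self.epochs < 1:
            raise ArgumentError(f"epochs must be >= 1, got {self.epochs}")
        if self.learning_rate <= 0:
            raise ArgumentError(f"learning_rate must be > 0, got {self.learning_rate}")


@dataclass
class FeatureMatrix:
    """Row-aligned patch ids and latent feature vectors."""

    ids: list[str]
    values: np.ndarray  # (n_patches, latent_dim)

    def __post_init__(self) -> None:
        if len(self.ids) != self.values.shape[0]:
            raise ArgumentError("ids and values row count differ")
        if not np.all(np.isfinite(self.values)):
            raise ArgumentError("feature matrix contains non-finite entries")


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """Per-sample KL of diagonal Gaussians N(mu, e^logvar) from N(0, I)."""
    mu = np.atleast_2d(mu)
    logvar = np.atleast_2d(logvar)
    return 0.5 * np.sum(mu ** 2 + np.exp(logvar) - 1.0 - logvar, axis=1)


def _patch_array(patches: Sequence, patch_size: int) -> np.ndarray:
    arrs = [p.patch if hasattr(p, "patch") else np.asarray(p) for p in patches]
    for a in arrs:
        if a.shape[:2] != (patch_size, patch_size):
            raise ArgumentError(
                f"patch shape {a.shape[:2]} does not match configured "
                f"patch_size {patch_size}")
    x = np.stack(arrs).astype(np.float64)
    return x.reshape(len(arrs), -1)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Vae:
    """Dense encoder/decoder with diagonal-Gaussian latent."""

    def __init__(self, config: VaeConfig):
        config.validate()
        self.config = config
        d = 3 * config.patch_size ** 2
        h, k = config.hidden_dim, config.latent_dim
        rng = np.random.default_rng(config.seed)

        def glorot(n_in, n_out):
            s = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-s, s, size=(n_in, n_out))

        self.params = {
            "W1": glorot(d, h), "b1": np.zeros(h),
            "Wm": glorot(h, k), "bm": np.zeros(k),
            "Wv": glorot(h, k) * 0.01, "bv": np.zeros(k),
            "W3": glorot(k, h), "b3": np.zeros(h),
            "W4": glorot(h, d), "b4": np.zeros(d),
        }
        self._adam_m = {n: np.zeros_like(v) for n, v in self.params.items()}
        self._adam_v = {n: np.zeros_like(v) for n, v in self.params.items()}
        self._adam_t = 0

    # -- forward pieces -----------------------------------------------------
    def _encode_raw(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        p = self.params
        h1 = _relu(x @ p["W1"] + p["b1"])
        mu = h1 @ p["Wm"] + p["bm"]
        logvar = np.clip(h1 @ p["Wv"] + p["bv"], -_LOGVAR_CLIP, _LOGVAR_CLIP)
        return h1, mu, logvar

    def _decode_raw(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = self.params
        h2 = _relu(z @ p["W3"] + p["b3"])
        y = 1.0 / (1.0 + np.exp(-(h2 @ p["W4"] + p["b4"])))
        return h2, y

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Posterior means (deterministic feature vectors)."""
        return self._encode_raw(x)[1]

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self._decode_raw(self.encode(x))[1]

    # -- training -----------------------------------------------------------
    def _step(self, x: np.ndarray, rng: np.random.Generator,
              kl_weight: float) -> tuple[float, float, float]:
        p = self.params
        n, d = x.shape
        h1 = _relu(x @ p["W1"] + p["b1"])
        mu = h1 @ p["Wm"] + p["bm"]
        logvar_pre = h1 @ p["Wv"] + p["bv"]
        logvar = np.clip(logvar_pre, -_LOGVAR_CLIP, _LOGVAR_CLIP)
        eps = rng.standard_normal(mu.shape)
        sigma = np.exp(0.5 * logvar)
        z = mu + sigma * eps
        h2 = _relu(z @ p["W3"] + p["b3"])
        y = 1.0 / (1.0 + np.exp(-(h2 @ p["W4"] + p["b4"])))

        recon = float(np.mean((y - x) ** 2))
        kl = float(np.mean(kl_divergence(mu, logvar)))
        loss = recon + kl_weight * kl

        # Backward pass.
        dy = 2.0 * (y - x) / (n * d)
        dpre4 = dy * y * (1.0 - y)
        g = {"W4": h2.T @ dpre4, "b4": dpre4.sum(0)}
        dh2 = dpre4 @ p["W4"].T
        dpre3 = dh2 * (h2 > 0)
        g["W3"] = z.T @ dpre3
        g["b3"] = dpre3.sum(0)
        dz = dpre3 @ p["W3"].T
        dmu = dz + kl_weight * mu / n
        inside = (logvar_pre > -_LOGVAR_CLIP) & (logvar_pre < _LOGVAR_CLIP)
        dlogvar = (dz * eps * 0.5 * sigma
                   + kl_weight * 0.5 * (np.exp(logvar) - 1.0) / n) * inside
        g["Wm"] = h1.T @ dmu
        g["bm"] = dmu.sum(0)
        g["Wv"] = h1.T @ dlogvar
        g["bv"] = dlogvar.sum(0)
        dh1 = (dmu @ p["Wm"].T + dlogvar @ p["Wv"].T) * (h1 > 0)
        g["W1"] = x.T @ dh1
        g["b1"] = dh1.sum(0)

        # Adam update.
        self._adam_t += 1
        lr, b1, b2, epsi = self.config.learning_rate, 0.9, 0.999, 1e-8
        for name, grad in g.items():
            self._adam_m[name] = b1 * self._adam_m[name] + (1 - b1) * grad
            self._adam_v[name] = b2 * self._adam_v[name] + (1 - b2) * grad ** 2
            mhat = self._adam_m[name] / (1 - b1 ** self._adam_t)
            vhat = self._adam_v[name] / (1 - b2 ** self._adam_t)
            p[name] -= lr * mhat / (np.sqrt(vhat) + epsi)
        return loss, recon, kl

    def save(self, path) -> None:
        np.savez(path, **self.params,
                 _cfg=np.array([self.config.latent_dim, self.config.patch_size,
                                self.config.hidden_dim]))

    @classmethod
    def load(cls, path) -> "Vae":
        data = np.load(path)
        k, ps, h = (int(v) for v in data["_cfg"])
        vae = cls(VaeConfig(latent_dim=k, patch_size=ps, hidden_dim=h))
        for name in vae.params:
            vae.params[name] = data[name]
        return vae


def train_vae(patches: Sequence, config: VaeConfig | None = None) -> tuple[Vae, dict]:
    """Train a VAE on square patches; returns the model and a loss history.

    History holds per-epoch means of the total loss, the reconstruction MSE
    and the KL term.  The KL weight defaults to 0.1 over the number of pixels
    per patch: the scale 1/n_pixels aligns the per-pixel reconstruction error
    with the per-sample KL (the canonical sum-over-pixels formulation), and
    the extra factor 0.1 keeps the regularizer from collapsing the posterior
    on low-variance seafloor patches, where rare organism patches would
    otherwise lose their latent separation from the background.
    Raises :class:`TrainingDivergenceError` naming the epoch if the loss goes
    non-finite.
    """
    config = config or VaeConfig()
    config.validate()
    if len(patches) < config.batch_size:
        raise ArgumentError(
            f"need at least batch_size={config.batch_size} patches, got {len(patches)}")
    x = _patch_array(patches, config.patch_size)
    if x.min() < 0 or x.max() > 1:
        raise ArgumentError("patch pixel values must lie in [0, 1]")
    kl_weight = config.kl_weight if config.kl_weight is not None else 0.1 / x.shape[1]

    vae = Vae(config)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                       spawn_key=(1,)))
    history: dict = {"loss": [], "recon": [], "kl": []}
    n = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, recons, kls = [], [], []
        for i in range(0, n, config.batch_size):
            batch = x[order[i:i + config.batch_size]]
            loss, recon, kl = vae._step(batch, rng, kl_weight)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(f"non-finite loss at epoch {epoch}")
            assert kl >= -1e-12, "KL term must be non-negative"
            losses.append(loss)
            recons.append(recon)
            kls.append(kl)
        history["loss"].append(float(np.mean(losses)))
        history["recon"].append(float(np.mean(recons)))
        history["kl"].append(float(np.mean(kls)))
    return vae, history


def encode_patches(vae: Vae, patches: Sequence) -> FeatureMatrix:
    """Deterministic features (posterior means), one row per patch."""
    x = _patch_array(patches, vae.config.patch_size)
    ids = [p.patch_id if hasattr(p, "patch_id") else str(i)
           for i, p in enumerate(patches)]
    # Chunked to bound memory on large patch sets.
    rows = [vae.encode(x[i:i + 1024]) for i in range(0, x.shape[0], 1024)]
    return FeatureMatrix(ids=ids, values=np.vstack(rows))


def project_2d(features: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Top-2 PCA projection of the centered feature matrix.

    Returns the (n, 2) scores and the explained-variance fractions of the two
    components (non-increasing).
    """
    x = features.values
    if x.shape[0] < 3:
        raise ArgumentError(f"need >= 3 rows for a 2-D projection, got {x.shape[0]}")
    if np.allclose(x, x[0]):
        raise DegenerateInputError("feature matrix has zero variance (rank 0)")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(x)
    return coords, pca.explained_variance_ratio_
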