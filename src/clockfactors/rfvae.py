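"""Relevance-factor variational autoencoder (RF-VAE).

A VAE over 64x64 clock drawings whose objective adds two terms to the
ELBO: a total-correlation (TC) penalty that pushes the aggregate
posterior toward a factorized distribution (disentanglement), and a
per-dimension relevance gate r in [0,1] that suppresses nuisance latent
dimensions — those whose posterior barely diverges from the prior —
while tolerating large prior KL on the relevant ones.

The TC term KL(q(z) || prod_d q(z_d)) is estimated by a density-ratio
discriminator trained to tell joint latent samples from
dimension-permuted ones; its logit is an estimate of the log density
ratio, so the batch-mean logit estimates the TC.  The penalty is applied
to the gated code r*z and scaled by mean(r), so fully closed gates
contribute exactly zero.  A closed-form Gaussian estimator
(-1/2 log det corr(z)) is available as a cheap deterministic
alternative.

Everything runs in float64 numpy with hand-written backprop; gradients
are exact (finite-difference checked in the test suite).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import MLP, Adam, Param, sigmoid
from .preprocess import TARGET_SIZE, ClockImage

__all__ = [
    "LatentPosterior", "RelevanceVector", "LossBreakdown", "TrainConfig",
    "RFVAE", "kl_to_prior", "reconstruction_loss", "permute_dims",
    "tc_estimate", "gaussian_tc", "rfvae_loss", "train",
]

_EPS = 1e-7
INPUT_DIM = TARGET_SIZE * TARGET_SIZE


@dataclass
class LatentPosterior:
    """Diagonal-Gaussian posterior q(z|x): per-dimension mean/log-variance."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.logvar = np.asarray(self.logvar, dtype=np.float64)
        if self.mu.shape != self.logvar.shape:
            raise ValueError("mu and logvar shapes differ")
        if not (np.isfinite(self.mu).all() and np.isfinite(self.logvar).all()):
            raise ValueError("non-finite posterior parameters")


@dataclass
class RelevanceVector:
    """Per-dimension relevance gates in [0, 1]."""

    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        if np.any(self.r < 0) or np.any(self.r > 1):
            raise ValueError("relevance gates must lie in [0, 1]")


@dataclass
class LossBreakdown:
    recon: float
    kl_per_dim: np.ndarray
    tc: float
    relevance_penalty: float
    total: float

    def __post_init__(self) -> None:
        vals = [self.recon, self.tc, self.relevance_penalty, self.total]
        if not (np.all(np.isfinite(vals)) and np.isfinite(self.kl_per_dim).all()):
            bad = [n for n, v in zip(("recon", "tc", "relevance_penalty", "total"),
                                     vals) if not np.isfinite(v)]
            raise FloatingPointError(f"non-finite loss component(s): {bad or ['kl']}")


@dataclass
class TrainConfig:
    """RF-VAE training settings.

    The full-scale protocol is 1400 epochs at learning rate 1e-4 with
    batch size 64 under Adam; ``epochs`` defaults to a desk-scale 100.
    ``tc_weight`` is the TC coefficient gamma; ``relevance_sparsity``
    and ``kl_relevance_coupling`` set the gate penalty
    lambda*sum(r) + eta*sum((1-r_d)*KL_d).
    """

    epochs: int = 100
    learning_rate: float = 1e-4
    batch_size: int = 64
    tc_weight: float = 6.4
    relevance_sparsity: float = 0.2
    kl_relevance_coupling: float = 1.0
    tc_estimator: str = "discriminator"   # or "gaussian"
    disc_lr: float = 1e-4
    relevance_lr: float = 1e-2
    seed: int = 0
    checkpoint_every: int = 0
    checkpoint_dir: str | None = None

    def validate(self) -> None:
        for name in ("epochs", "learning_rate", "batch_size", "tc_weight",
                     "disc_lr"):
            if getattr(self, name) < 0 or (name in ("epochs", "learning_rate",
                                                    "batch_size")
                                           and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.tc_estimator not in ("discriminator", "gaussian"):
            raise ValueError(f"unknown tc_estimator {self.tc_estimator!r}")

    @classmethod
    def full_scale(cls, **overrides) -> "TrainConfig":
        """The full-scale protocol (1400 epochs)."""
        return cls(epochs=1400, **overrides)


# --- pure loss pieces ----------------------------------------------------

def kl_to_prior(posterior: LatentPosterior) -> np.ndarray:
    """Per-dimension KL(q(z|x) || N(0, I)), closed form.

    ``0.5 * (mu^2 + sigma^2 - 1 - log sigma^2)`` elementwise; zero iff
    mu=0 and sigma=1.  Shape matches ``posterior.mu``.
    """
    mu, lv = posterior.mu, posterior.logvar
    return 0.5 * (mu ** 2 + np.exp(lv) - 1.0 - lv)


def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray,
                        eps: float = _EPS) -> float:
    """Bernoulli cross-entropy summed over pixels (batch-averaged).

    ``x`` holds targets in [0,1]; ``x_hat`` predicted probabilities,
    clipped to [eps, 1-eps].  Non-negative for binary targets and
    minimized at x_hat = x.
    """
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if np.isnan(x).any() or np.isnan(x_hat).any():
        raise ValueError("NaN in reconstruction inputs")
    p = np.clip(x_hat, eps, 1.0 - eps)
    ce = -(x * np.log(p) + (1.0 - x) * np.log(1.0 - p))
    if ce.ndim <= 2 and x.shape == (TARGET_SIZE, TARGET_SIZE):
        return float(ce.sum())
    # batched: sum over pixel axes, mean over batch
    return float(ce.reshape(ce.shape[0], -1).sum(axis=1).mean())


def permute_dims(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently shuffle each latent coordinate across the batch.

    Preserves every coordinate's marginal exactly while destroying the
    joint structure — the surrogate for the product of marginals.
    """
    z = np.asarray(z)
    if z.shape[0] < 2:
        raise ValueError("need a batch of >= 2 samples to permute")
    out = np.empty_like(z)
    for d in range(z.shape[1]):
        out[:, d] = z[rng.permutation(z.shape[0]), d]
    return out


def gaussian_tc(z: np.ndarray) -> float:
    """Closed-form TC under a Gaussian fit: -1/2 log det corr(z)."""
    z = np.asarray(z, dtype=np.float64)
    c = np.corrcoef(z, rowvar=False)
    sign, logdet = np.linalg.slogdet(c)
    return float(-0.5 * logdet)


def tc_estimate(z_batch: np.ndarray, discriminator: MLP) -> float:
    """Density-ratio TC estimate: mean discriminator logit on joint samples."""
    z_batch = np.asarray(z_batch, dtype=np.float64)
    if z_batch.shape[0] < 2:
        raise ValueError("TC estimation needs a batch of >= 2 samples")
    return float(discriminator.forward(z_batch).mean())


def train_discriminator_to_convergence(disc: MLP, z: np.ndarray,
                                       rng: np.random.Generator,
                                       steps: int = 2000, lr: float = 1e-3,
                                       batch_size: int = 256) -> None:
    """Fit a density-ratio discriminator on a fixed latent sample.

    Used when estimating the TC of a static sample (rather than inside
    the adversarial training loop): logistic regression of joint vs
    dimension-permuted samples, minibatch Adam.
    """
    opt = Adam(disc.params, lr=lr, beta1=0.5, beta2=0.9)
    n = z.shape[0]
    for _ in range(steps):
        idx = rng.choice(n, size=min(batch_size, n), replace=False)
        zb = z[idx]
        zp = permute_dims(z[rng.choice(n, size=min(batch_size, n), replace=False)],
                          rng)
        opt.zero_grad()
        _disc_step_grads(disc, zb, zp)
        opt.step()


def _disc_step_grads(disc: MLP, z_joint: np.ndarray, z_perm: np.ndarray) -> float:
    """Accumulate discriminator gradients for one logistic-loss step."""
    b = z_joint.shape[0]
    t_j = disc.forward(z_joint)
    g_j = -sigmoid(-t_j) / b          # d softplus(-t)/dt
    disc.backward(g_j)
    t_p = disc.forward(z_perm)
    g_p = sigmoid(t_p) / z_perm.shape[0]
    disc.backward(g_p)
    loss = float(np.logaddexp(0, -t_j).mean() + np.logaddexp(0, t_p).mean())
    return loss


# --- the model -----------------------------------------------------------

class RFVAE:
    """Encoder, decoder, relevance gates and TC discriminator.

    The encoder/decoder are fully-connected (4096 -> 256 -> 128 -> 2D
    and the mirror image); the final encoder layer is zero-initialized
    so the untrained posterior is exactly the prior.  Images enter and
    leave in white=1 polarity; internally the model works ink-bright
    (1 - pixels) so the Bernoulli targets are sparse positives.
    """

    def __init__(self, latent_dim: int = 10, seed: int = 0,
                 enc_hidden: tuple[int, ...] = (256, 128),
                 disc_hidden: tuple[int, ...] = (64, 64)):
        self.latent_dim = latent_dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoder = MLP([INPUT_DIM, *enc_hidden, 2 * latent_dim], rng,
                           zero_init_last=True)
        self.decoder = MLP([latent_dim, *enc_hidden[::-1], INPUT_DIM], rng)
        self.rho = Param(np.full(latent_dim, 2.0))   # gates start open (~0.88)
        self.discriminator = MLP([latent_dim, *disc_hidden, 1], rng)

    # -- plumbing --

    @property
    def relevance(self) -> RelevanceVector:
        return RelevanceVector(sigmoid(self.rho.value))

    @property
    def params(self) -> list[Param]:
        return self.encoder.params + self.decoder.params + [self.rho]

    @staticmethod
    def _to_batch(images) -> np.ndarray:
        if isinstance(images, ClockImage):
            images = images.pixels
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 2 and x.shape == (TARGET_SIZE, TARGET_SIZE):
            x = x[None]   # one image; a (64, 4096) array is a flat batch
        if x.ndim == 3 and x.shape[1:] == (TARGET_SIZE, TARGET_SIZE):
            x = x.reshape(x.shape[0], -1)
        if x.ndim != 2 or x.shape[1] != INPUT_DIM:
            raise ValueError(
                f"expected {TARGET_SIZE}x{TARGET_SIZE} image(s), got {x.shape}")
        return x

    # -- forward passes --

    def encode(self, images) -> LatentPosterior:
        """Posterior parameters for one image or a batch (white=1 input)."""
        x = 1.0 - self._to_batch(images)
        h = self.encoder.forward(x)
        mu, logvar = h[:, :self.latent_dim], h[:, self.latent_dim:]
        if mu.shape[0] == 1:
            mu, logvar = mu[0], logvar[0]
        return LatentPosterior(mu=mu, logvar=logvar)

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Decode latent codes to images in white=1 polarity, values in (0,1)."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        probs = sigmoid(self.decoder.forward(z))
        imgs = 1.0 - probs.reshape(-1, TARGET_SIZE, TARGET_SIZE)
        return imgs[0] if imgs.shape[0] == 1 else imgs

    def latent_means(self, images) -> np.ndarray:
        """Posterior means for a batch — the features fed downstream."""
        return np.atleast_2d(self.encode(images).mu)

    # -- training objective --

    def _loss_and_grads(self, x_white: np.ndarray, config: TrainConfig,
                        rng: np.random.Generator, with_grads: bool = True
                        ) -> LossBreakdown:
        """Forward (and optionally backward) pass of the full objective.

        total = recon + sum_d KL_d + gamma * mean(r) * TC(r*z)
                + lambda*sum(r) + eta*sum((1-r_d)*KL_d)
        """
        B = x_white.shape[0]
        D = self.latent_dim
        gamma = config.tc_weight
        lam = config.relevance_sparsity
        eta = config.kl_relevance_coupling
        x = 1.0 - x_white

        h = self.encoder.forward(x)
        mu, lv = h[:, :D], h[:, D:]
        lv = np.clip(lv, -12.0, 12.0)
        eps = rng.standard_normal(mu.shape)
        std = np.exp(0.5 * lv)
        z = mu + std * eps

        logits = self.decoder.forward(z)
        probs = np.clip(sigmoid(logits), _EPS, 1.0 - _EPS)
        recon = float(-(x * np.log(probs)
                        + (1 - x) * np.log(1 - probs)).sum() / B)

        kl_elem = 0.5 * (mu ** 2 + np.exp(lv) - 1.0 - lv)    # (B, D)
        kl_per_dim = kl_elem.mean(axis=0)
        kl_total = float(kl_per_dim.sum())

        r = sigmoid(self.rho.value)
        rbar = float(r.mean())
        zg = r * z
        if config.tc_estimator == "gaussian" and B > D + 1:
            tc_val = gaussian_tc(zg)
        else:
            tc_val = float(self.discriminator.forward(zg).mean())
        tc_term = gamma * rbar * tc_val

        rel_pen = float(lam * r.sum() + eta * ((1.0 - r) * kl_per_dim).sum())
        total = recon + kl_total + tc_term + rel_pen
        breakdown = LossBreakdown(recon=recon, kl_per_dim=kl_per_dim,
                                  tc=tc_val, relevance_penalty=rel_pen,
                                  total=total)
        if not with_grads:
            return breakdown

        # ---- backward ----
        dlogits = (sigmoid(logits) - x) / B
        dz = self.decoder.backward(dlogits)

        dr = np.zeros(D)
        if gamma != 0.0 and rbar > 0.0:
            if config.tc_estimator == "gaussian" and B > D + 1:
                dzg = gamma * rbar * _gaussian_tc_grad(zg)
            else:
                dzg = self.discriminator.backward(
                    np.full((B, 1), gamma * rbar / B))
                for p in self.discriminator.params:   # disc is frozen here
                    p.zero_grad()
            dz += dzg * r
            dr += (dzg * z).sum(axis=0) + gamma * tc_val / D

        # KL appears with weight (1 + eta*(1-r)) per dimension
        w_kl = 1.0 + eta * (1.0 - r)
        dmu = dz + w_kl * mu / B
        dlv = dz * eps * 0.5 * std + w_kl * 0.5 * (np.exp(lv) - 1.0) / B
        self.encoder.backward(np.concatenate([dmu, dlv], axis=1))

        dr += lam - eta * kl_per_dim
        self.rho.grad += dr * r * (1.0 - r)
        return breakdown


def _gaussian_tc_grad(z: np.ndarray) -> np.ndarray:
    """Gradient of -1/2 log det corr(z) with respect to z."""
    B = z.shape[0]
    mu = z.mean(axis=0)
    sd = z.std(axis=0, ddof=0)
    sd = np.where(sd < 1e-12, 1e-12, sd)
    u = (z - mu) / sd
    R = u.T @ u / B
    G = -0.5 * np.linalg.inv(R)          # dL/dR, symmetric
    du = u @ (G + G.T) / B
    # back through the per-column standardization u = (z - mu)/sd
    m1 = du.mean(axis=0)
    m2 = (du * u).mean(axis=0)
    return (du - m1 - u * m2) / sd


def rfvae_loss(x, model: RFVAE, config: TrainConfig,
               rng: np.random.Generator) -> LossBreakdown:
    """Evaluate the full RF-VAE objective on a batch (no parameter update)."""
    config.validate()
    xb = RFVAE._to_batch(x)
    return model._loss_and_grads(xb, config, rng, with_grads=False)


# --- training loop -------------------------------------------------------

def train(images, config: TrainConfig, model: RFVAE | None = None,
          latent_dim: int = 10) -> tuple[RFVAE, pd.DataFrame]:
    """Train an RF-VAE on an image stack (N, 64, 64), white=1 polarity.

    Alternates one Adam step on the VAE objective with one logistic step
    of the TC discriminator on (joint vs dimension-permuted) latent
    samples.  Fully seeded: identical config + data give identical
    parameters.  Returns the model and a per-epoch loss history.
    """
    config.validate()
    x = RFVAE._to_batch(np.asarray(images))
    n = x.shape[0]
    if n < config.batch_size:
        raise ValueError(
            f"dataset of {n} images is smaller than batch_size="
            f"{config.batch_size}; reduce the batch size")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = RFVAE(latent_dim=latent_dim,
                      seed=int(rng.integers(0, 2 ** 31)))
    opt = Adam(model.encoder.params + model.decoder.params,
               lr=config.learning_rate)
    # the scalar gates ride a faster schedule than the network weights
    rho_opt = Adam([model.rho], lr=config.relevance_lr)
    disc_opt = Adam(model.discriminator.params, lr=config.disc_lr,
                    beta1=0.5, beta2=0.9)

    history = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        ep = {"recon": 0.0, "kl_total": 0.0, "tc": 0.0, "relevance_penalty": 0.0,
              "total": 0.0}
        kl_dims = np.zeros(model.latent_dim)
        n_batches = 0
        for start in range(0, n - 1, config.batch_size):
            idx = order[start:start + config.batch_size]
            if idx.size < 2:
                continue
            xb = x[idx]
            opt.zero_grad()
            rho_opt.zero_grad()
            bd = model._loss_and_grads(xb, config, rng)
            opt.step()
            rho_opt.step()

            if config.tc_estimator == "discriminator":
                post = model.encode(xb)
                mu = np.atleast_2d(post.mu)
                std = np.exp(0.5 * np.atleast_2d(post.logvar))
                zd = (mu + std * rng.standard_normal(mu.shape))
                zd *= sigmoid(model.rho.value)
                zp = permute_dims(zd, rng)
                disc_opt.zero_grad()
                _disc_step_grads(model.discriminator, zd, zp)
                disc_opt.step()

            ep["recon"] += bd.recon
            ep["kl_total"] += float(bd.kl_per_dim.sum())
            ep["tc"] += bd.tc
            ep["relevance_penalty"] += bd.relevance_penalty
            ep["total"] += bd.total
            kl_dims += bd.kl_per_dim
            n_batches += 1
        row = {k: v / n_batches for k, v in ep.items()}
        row["epoch"] = epoch
        r = sigmoid(model.rho.value)
        for d in range(model.latent_dim):
            row[f"kl_{d}"] = kl_dims[d] / n_batches
            row[f"relevance_{d}"] = r[d]
        history.append(row)
        if (config.checkpoint_every and config.checkpoint_dir
                and epoch % config.checkpoint_every == 0):
            save_model(model, Path(config.checkpoint_dir) / f"epoch{epoch:05d}",
                       config=config, epoch=epoch,
                       losses={k: row[k] for k in ep})
    return model, pd.DataFrame(history)


# --- persistence ---------------------------------------------------------

def save_model(model: RFVAE, path, config: TrainConfig | None = None,
               epoch: int | None = None, losses: dict | None = None) -> None:
    """Serialize parameters (.npz) with a JSON sidecar of run metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params)}
    arrays.update({f"d{i}": p.value for i, p in
                   enumerate(model.discriminator.params)})
    np.savez(path.with_suffix(".npz"), latent_dim=model.latent_dim,
             seed=model.seed, **arrays)
    sidecar = {"latent_dim": model.latent_dim, "seed": model.seed,
               "epoch": epoch, "losses": losses,
               "config": asdict(config) if config else None}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> RFVAE:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as data:
        model = RFVAE(latent_dim=int(data["latent_dim"]),
                      seed=int(data["seed"]))
        for i, p in enumerate(model.params):
            p.value[...] = data[f"p{i}"]
        for i, p in enumerate(model.discriminator.params):
            p.value[...] = data[f"d{i}"]
    return model
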