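"""X-shaped variational autoencoder for two-view data integration.

Two per-view encoder branches are fused into a shared latent space; a
mirrored decoder reconstructs both views from the latent code. The loss is
mean squared reconstruction error plus an MMD penalty pulling the latent
batch distribution toward a standard Gaussian:

    L = (1/n) sum_i( ||x1_i - x1'_i||^2 + ||x2_i - x2'_i||^2 )
        + beta * MMD^2(z_batch, prior_batch)

Conditional variants are built by attaching extra conditioning input blocks
to selected layers (see :mod:`xvaekit.deconfound`); this module's trainer is
shared by all of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .confound import ConfoundedDataset
from .data import PairedOmicsDataset
from .nn import Adam, Linear, Tensor, as_tensor, concat

__all__ = [
    "XvaeConfig",
    "XvaeModel",
    "LatentPosterior",
    "build_xvae",
    "mmd",
    "xvae_loss",
    "train_xvae",
    "encode",
    "sample_latent",
    "reconstruct",
]


@dataclass
class XvaeConfig:
    """Architecture and training hyperparameters."""

    view_hidden: int = 128
    fused_hidden: int = 128
    latent_dim: int = 50
    beta: float = 1.0
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    early_stop_patience: int = 10
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0,1)")


@dataclass
class LatentPosterior:
    """Per-sample latent Gaussian parameters."""

    mean: np.ndarray
    log_var: np.ndarray

    def __post_init__(self):
        if self.mean.shape != self.log_var.shape:
            raise ValueError("mean/log_var shape mismatch")
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.log_var))):
            raise ValueError("posterior parameters must be finite")


class XvaeModel:
    """Parameter container for the X-shaped VAE (optionally conditional).

    ``cond_levels`` is a set drawn from {"input", "fused", "embed"}
    indicating where conditioning covariates enter; empty for vanilla XVAE.
    """

    def __init__(self, p: int, q: int, cfg: XvaeConfig, rng: np.random.Generator):
        self.p, self.q, self.cfg = p, q, cfg
        h, f, d = cfg.view_hidden, cfg.fused_hidden, cfg.latent_dim
        self.enc1 = Linear(p, h, rng, activation="relu")
        self.enc2 = Linear(q, h, rng, activation="relu")
        self.fuse = Linear(2 * h, f, rng, activation="relu")
        self.mu_head = Linear(f, d, rng)
        self.logvar_head = Linear(f, d, rng)
        self.dec_fuse = Linear(d, f, rng, activation="relu")
        self.dec1 = Linear(f, h, rng, activation="relu")
        self.dec2 = Linear(f, h, rng, activation="relu")
        self.out1 = Linear(h, p, rng)
        self.out2 = Linear(h, q, rng)
        self.cond_levels: set[str] = set()
        self.cond_dim: int = 0

    @property
    def layers(self):
        return [self.enc1, self.enc2, self.fuse, self.mu_head, self.logvar_head,
                self.dec_fuse, self.dec1, self.dec2, self.out1, self.out2]

    @property
    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters]

    def _check_cond(self, cond):
        if self.cond_levels and cond is None:
            raise ValueError("conditional model requires conditioning covariates")
        return None if cond is None else as_tensor(cond)

    def encode_t(self, x1, x2, cond=None) -> tuple[Tensor, Tensor]:
        cond = self._check_cond(cond)
        h1 = self.enc1(x1, extra=cond if "input" in self.cond_levels else None)
        h2 = self.enc2(x2, extra=cond if "input" in self.cond_levels else None)
        fused = self.fuse(concat([h1, h2], axis=1),
                          extra=cond if "fused" in self.cond_levels else None)
        return self.mu_head(fused), self.logvar_head(fused)

    def decode_t(self, z, cond=None) -> tuple[Tensor, Tensor]:
        cond = self._check_cond(cond)
        g = self.dec_fuse(z, extra=cond if "embed" in self.cond_levels else None)
        return self.out1(self.dec1(g)), self.out2(self.dec2(g))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters]

    def load_state_arrays(self, arrays):
        for p, a in zip(self.parameters, arrays):
            p.data = a.copy()


def build_xvae(p: int, q: int, cfg: XvaeConfig) -> XvaeModel:
    """Build an XVAE with deterministic initialization from cfg.seed."""
    if p < 1 or q < 1:
        raise ValueError("input widths must be positive")
    rng = np.random.default_rng(cfg.seed)
    return XvaeModel(p, q, cfg, rng)


# ------------------------------------------------------------------- MMD

def _pairwise_sq_dists(a: Tensor, b: Tensor) -> Tensor:
    a2 = (a * a).sum(axis=1, keepdims=True)
    b2 = (b * b).sum(axis=1, keepdims=True)
    return a2 + b2.T - 2.0 * (a @ b.T)


def _mmd_t(a: Tensor, b: Tensor, kernel_scales=None) -> Tensor:
    """Biased V-statistic squared-MMD with a mixture of Gaussian kernels.

    Default bandwidths are {s/2, s, 2s} where s is the median pairwise
    distance of the pooled sample (held constant w.r.t. gradients).
    """
    if a.shape[1] != b.shape[1]:
        raise ValueError("samples must share dimensionality")
    if kernel_scales is None:
        joint = np.vstack([a.data, b.data])
        d2 = (np.sum(joint ** 2, 1)[:, None] + np.sum(joint ** 2, 1)[None, :]
              - 2 * joint @ joint.T)
        med = float(np.sqrt(np.clip(np.median(d2), 0, None)))
        s = max(med, 1e-6)
        kernel_scales = (s / 2, s, 2 * s)
    daa = _pairwise_sq_dists(a, a)
    dbb = _pairwise_sq_dists(b, b)
    dab = _pairwise_sq_dists(a, b)
    total = None
    for s in kernel_scales:
        gamma = 1.0 / (2.0 * s * s)
        term = ((-gamma * daa).exp().mean() + (-gamma * dbb).exp().mean()
                - 2.0 * (-gamma * dab).exp().mean())
        total = term if total is None else total + term
    return total / len(kernel_scales)


def mmd(sample_a: np.ndarray, sample_b: np.ndarray, kernel_scales=None) -> float:
    """Squared MMD between two samples (nonnegative, symmetric)."""
    val = _mmd_t(as_tensor(np.asarray(sample_a, dtype=np.float64)),
                 as_tensor(np.asarray(sample_b, dtype=np.float64)),
                 kernel_scales=kernel_scales).item()
    # V-statistic is mathematically >= 0; clamp float round-off
    return max(val, 0.0)


def xvae_loss(x1, x2, recon1, recon2, z_samples, prior_samples,
              beta: float = 1.0):
    """Total loss and its components (reconstruction, MMD regularizer).

    Accepts arrays or Tensors; returns Tensors (use ``.item()`` for floats).
    Reconstruction = mean over samples of the summed per-feature squared
    errors of both views (views weighted equally).
    """
    x1, x2 = as_tensor(x1), as_tensor(x2)
    recon1, recon2 = as_tensor(recon1), as_tensor(recon2)
    n = x1.shape[0]
    rec = (((x1 - recon1) ** 2).sum() + ((x2 - recon2) ** 2).sum()) / n
    reg = _mmd_t(as_tensor(z_samples), as_tensor(prior_samples))
    total = rec + beta * reg
    return total, rec, reg


# -------------------------------------------------------------- training

def _extract_views(data):
    if isinstance(data, ConfoundedDataset):
        return data.confounded1, data.confounded2
    if isinstance(data, PairedOmicsDataset):
        return data.view1.values, data.view2.values
    x1, x2 = data  # (x1, x2) tuple fallback
    return np.asarray(x1), np.asarray(x2)


def train_xvae(model: XvaeModel, data, cfg: XvaeConfig,
               conditioning: np.ndarray | None = None,
               loss_hook=None, epoch_hook=None):
    """Train with Adam, reparameterized sampling and early stopping.

    Parameters
    ----------
    data : ConfoundedDataset, PairedOmicsDataset or (x1, x2) tuple
    conditioning : covariate matrix for conditional models (n x m)
    loss_hook : optional ``f(z_tensor, batch_indices) -> Tensor`` added to
        the batch loss (used for deconfounding penalties); must not draw
        from the trainer's RNG
    epoch_hook : optional ``f(epoch, model) -> None`` called before each
        epoch (used for adversary updates); uses its own RNG

    Returns
    -------
    (model, history) where history is a dict of per-epoch lists
    ``train_loss``, ``val_loss``, ``recon``, ``mmd``. The model is left at
    the parameters with the best validation loss.
    """
    x1_all, x2_all = _extract_views(data)
    n = x1_all.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(cfg.seed)
    d = cfg.latent_dim

    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    opt = Adam(model.parameters, lr=cfg.learning_rate)
    history = {"train_loss": [], "val_loss": [], "recon": [], "mmd": []}
    best_val, best_state, patience_left = np.inf, None, cfg.early_stop_patience

    def batch_loss(idx, eps, prior):
        xb1, xb2 = x1_all[idx], x2_all[idx]
        cb = conditioning[idx] if conditioning is not None else None
        mu, lv = model.encode_t(xb1, xb2, cond=cb)
        z = mu + (lv * 0.5).exp() * eps
        r1, r2 = model.decode_t(z, cond=cb)
        total, rec, reg = xvae_loss(xb1, xb2, r1, r2, z,
                                    as_tensor(prior), beta=cfg.beta)
        if loss_hook is not None:
            extra = loss_hook(z, idx)
            if extra is not None:
                total = total + extra
        return total, rec, reg

    for epoch in range(cfg.epochs):
        if epoch_hook is not None:
            epoch_hook(epoch, model)
        order = rng.permutation(train_idx)
        ep_total = ep_rec = ep_reg = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            eps = rng.standard_normal((len(idx), d))
            prior = rng.standard_normal((len(idx), d))
            total, rec, reg = batch_loss(idx, eps, prior)
            if not np.isfinite(total.item()):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={total.item()}")
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_total += total.item()
            ep_rec += rec.item()
            ep_reg += reg.item()
            n_batches += 1
        history["train_loss"].append(ep_total / n_batches)
        history["recon"].append(ep_rec / n_batches)
        history["mmd"].append(ep_reg / n_batches)

        eps = rng.standard_normal((len(val_idx), d))
        prior = rng.standard_normal((len(val_idx), d))
        val_total, _, _ = batch_loss(val_idx, eps, prior)
        val = val_total.item()
        if not np.isfinite(val):
            raise RuntimeError(f"validation loss diverged at epoch {epoch}")
        history["val_loss"].append(val)

        if val < best_val - 1e-12:
            best_val, best_state = val, model.state_arrays()
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    if best_state is not None:
        model.load_state_arrays(best_state)
    else:  # pragma: no cover - defensive
        warnings.warn("validation loss never improved; keeping final state")
    return model, history


# ------------------------------------------------------------- inference

def encode(model: XvaeModel, x1, x2, conditioning=None) -> LatentPosterior:
    """Posterior mean and log-variance for every sample."""
    mu, lv = model.encode_t(np.asarray(x1), np.asarray(x2), cond=conditioning)
    return LatentPosterior(mean=mu.data.copy(), log_var=lv.data.copy())


def sample_latent(post: LatentPosterior, n_draws: int, seed: int = 0):
    """Reparameterized draws: mean + exp(log_var/2) * eps, eps ~ N(0,I)."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    sd = np.exp(post.log_var * 0.5)
    return [post.mean + sd * rng.standard_normal(post.mean.shape)
            for _ in range(n_draws)]


def reconstruct(model: XvaeModel, x1, x2, conditioning=None):
    """Decode the posterior mean into per-view reconstructions."""
    post = encode(model, x1, x2, conditioning=conditioning)
    r1, r2 = model.decode_t(post.mean, cond=conditioning)
    return r1.data.copy(), r2.data.copy()


# ----------------------------------------------------------- persistence

def save_model(model: XvaeModel, path) -> None:
    """Save parameters (.npz) plus a JSON sidecar with the architecture."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, **arrays)
    sidecar = {
        "p": model.p, "q": model.q,
        "cond_levels": sorted(model.cond_levels),
        "cond_dim": model.cond_dim,
        "config": dataclasses.asdict(model.cfg),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> XvaeModel:
    """Rebuild a model saved by :func:`save_model`."""
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = XvaeConfig(**sidecar["config"])
    model = build_xvae(sidecar["p"], sidecar["q"], cfg)
    levels = set(sidecar["cond_levels"])
    if levels:
        m = sidecar["cond_dim"]
        if "input" in levels:
            model.enc1.add_extra_input(m)
            model.enc2.add_extra_input(m)
        if "fused" in levels:
            model.fuse.add_extra_input(m)
        if "embed" in levels:
            model.dec_fuse.add_extra_input(m)
        model.cond_levels = levels
        model.cond_dim = m
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        arrays = [data[f"param_{i}"] for i in range(len(data.files))]
    model.load_state_arrays(arrays)
    return model
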