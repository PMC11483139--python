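"""Deconfounding strategies built on the XVAE, plus the LR+PCA baseline.

Four strategies are provided:

* **conditional (cXVAE)** — confounder covariates are appended as extra
  inputs to the encoder and/or decoder so the latent space need not encode
  them;
* **adversarial (adv-XVAE)** — an MLP adversary is trained to predict the
  confounder from the latent code while the VAE is trained to defeat it;
* **correlation regularization (cr-XVAE)** — the loss is augmented with a
  differentiable penalty on the association (Pearson or mutual information)
  between latent dimensions and the confounder;
* **latent feature selection (XVAE+FS)** — post-hoc removal of latent
  dimensions correlated with the confounder before clustering.

The LR+PCA baseline residualizes every feature on the confounders, then
applies PCA and KMeans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .nn import Adam, Linear, Tensor, as_tensor
from .xvae import XvaeConfig, XvaeModel, build_xvae, train_xvae

__all__ = [
    "ConfounderEncoding",
    "AdversaryConfig",
    "CrPenaltySpec",
    "FsCriterion",
    "encode_confounders",
    "build_cxvae",
    "train_adv_xvae",
    "cr_penalty",
    "train_cr_xvae",
    "filter_latent_features",
    "lr_pca_baseline",
]


# --------------------------------------------------------------- encodings

@dataclass
class ConfounderEncoding:
    """Conditioning covariate matrix with per-confounder encoding schemes."""

    matrix: np.ndarray
    schemes: list[str]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]


def _one_hot(values: np.ndarray) -> np.ndarray:
    levels = np.unique(values)
    return (values[:, None] == levels[None, :]).astype(np.float64)


def encode_confounders(confounders, schemes) -> ConfounderEncoding:
    """Build the conditioning matrix: one-hot per categorical confounder,
    standardized scalar per numeric confounder, concatenated column-wise."""
    confounders = [np.asarray(c) for c in confounders]
    if len(confounders) != len(schemes):
        raise ValueError("one scheme per confounder required")
    n = len(confounders[0])
    blocks = []
    for c, scheme in zip(confounders, schemes):
        if len(c) != n:
            raise ValueError("confounders must share length")
        if scheme == "onehot":
            blocks.append(_one_hot(c))
        elif scheme == "standardized_scalar":
            c = c.astype(np.float64)
            sd = c.std()
            if sd == 0:
                blocks.append(np.zeros((n, 1)))
            else:
                blocks.append(((c - c.mean()) / sd)[:, None])
        else:
            raise ValueError(f"unknown encoding scheme {scheme!r}")
    return ConfounderEncoding(np.hstack(blocks), list(schemes))


# ------------------------------------------------------------------ cXVAE

_LEVELS = {
    "input": {"input"},
    "fused": {"fused"},
    "embed": {"embed"},
    "input_embed": {"input", "embed"},
}


def build_cxvae(p: int, q: int, cfg: XvaeConfig, enc: ConfounderEncoding,
                level: str = "input_embed") -> XvaeModel:
    """Conditional XVAE: conditioning columns enter at the chosen level(s).

    The primary weight blocks are initialized identically to the vanilla
    XVAE with the same config, and conditioning blocks start at zero, so a
    zeroed conditioning matrix reproduces the vanilla model exactly.
    """
    if level not in _LEVELS:
        raise ValueError(f"invalid conditioning level {level!r}; "
                         f"choose from {sorted(_LEVELS)}")
    model = build_xvae(p, q, cfg)
    levels = _LEVELS[level]
    if "input" in levels:
        model.enc1.add_extra_input(enc.m)
        model.enc2.add_extra_input(enc.m)
    if "fused" in levels:
        model.fuse.add_extra_input(enc.m)
    if "embed" in levels:
        model.dec_fuse.add_extra_input(enc.m)
    model.cond_levels = levels
    model.cond_dim = enc.m
    return model


# -------------------------------------------------------------- adversary

@dataclass
class AdversaryConfig:
    """Adversary MLP and alternating-training settings."""

    hidden: tuple = (32,)
    lambda_adv: float = 1.0
    pretrain_epochs: int = 10
    steps_per_alternation: int = 1
    learning_rate: float = 1e-3

    def __post_init__(self):
        if self.lambda_adv < 0:
            raise ValueError("lambda_adv must be >= 0")


class _AdversaryMLP:
    def __init__(self, in_dim: int, hidden, n_classes: int,
                 rng: np.random.Generator):
        dims = [in_dim, *hidden]
        self.layers = [Linear(a, b, rng, activation="relu")
                       for a, b in zip(dims[:-1], dims[1:])]
        self.layers.append(Linear(dims[-1], n_classes, rng))

    def __call__(self, x) -> Tensor:
        h = as_tensor(x)
        for layer in self.layers:
            h = layer(h)
        return h

    @property
    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters]


def cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean multiclass cross-entropy from raw logits."""
    shift = logits - logits.data.max(axis=1, keepdims=True)  # constant shift
    log_probs = shift - shift.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(y)), np.asarray(y, dtype=np.int64)] = 1.0
    return -(as_tensor(onehot) * log_probs).sum() / len(y)


def _joint_classes(class_labels) -> np.ndarray:
    """Factorize one or more class label vectors into a single target."""
    stacked = np.column_stack([np.asarray(c) for c in class_labels])
    _, joint = np.unique(stacked, axis=0, return_inverse=True)
    return joint


def train_adv_xvae(data, cfg: XvaeConfig, adv_cfg: AdversaryConfig,
                   confounder_classes, variant: str = "multiclass"):
    """Adversarial training: plain XVAE pretraining, then alternation
    between (a) adversary epochs minimizing multiclass cross-entropy on
    frozen embeddings and (b) VAE epochs minimizing the XVAE loss minus
    ``lambda_adv`` times the (frozen) adversary's loss.

    Parameters
    ----------
    confounder_classes : list of integer class-label vectors, one per
        confounder. ``variant="multiclass"`` trains one shared adversary on
        the factorized joint labels; ``variant="sequential"`` trains one
        adversary per confounder and sums the penalty terms.

    Returns
    -------
    (model, history, adversaries)
    """
    from .xvae import _extract_views

    confounder_classes = [np.asarray(c) for c in confounder_classes]
    for c in confounder_classes:
        if not np.issubdtype(c.dtype, np.integer):
            raise ValueError(
                "adversarial training needs discrete class labels; "
                "discretize continuous confounders into classes first")
    if variant == "multiclass":
        targets = [_joint_classes(confounder_classes)]
    elif variant == "sequential":
        targets = [np.unique(c, return_inverse=True)[1] for c in confounder_classes]
    else:
        raise ValueError(f"unknown variant {variant!r}")

    x1_all, x2_all = _extract_views(data)
    p, q = x1_all.shape[1], x2_all.shape[1]
    model = build_xvae(p, q, cfg)
    d = cfg.latent_dim

    adv_rng = np.random.default_rng([cfg.seed, 0xADF1])
    adversaries = [
        _AdversaryMLP(d, adv_cfg.hidden, int(t.max()) + 1, adv_rng)
        for t in targets
    ]
    adv_opts = [Adam(a.parameters, lr=adv_cfg.learning_rate) for a in adversaries]
    state = {"epoch": 0}

    def epoch_hook(epoch, mdl):
        state["epoch"] = epoch
        if epoch < adv_cfg.pretrain_epochs:
            return
        # adversary update on frozen embeddings (posterior means)
        mu, _ = mdl.encode_t(x1_all, x2_all)
        emb = mu.data  # detached
        n = emb.shape[0]
        for _ in range(adv_cfg.steps_per_alternation):
            order = adv_rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                for adv, opt, t in zip(adversaries, adv_opts, targets):
                    loss = cross_entropy(adv(emb[idx]), t[idx])
                    opt.zero_grad()
                    loss.backward()
                    opt.step()

    def loss_hook(z, idx):
        if adv_cfg.lambda_adv == 0 or state["epoch"] < adv_cfg.pretrain_epochs:
            return None
        penalty = None
        for adv, t in zip(adversaries, targets):
            ce = cross_entropy(adv(z), t[idx])
            penalty = ce if penalty is None else penalty + ce
        return -adv_cfg.lambda_adv * penalty

    model, history = train_xvae(model, data, cfg, loss_hook=loss_hook,
                                epoch_hook=epoch_hook)
    return model, history, adversaries


# ------------------------------------------------- correlation regularizer

@dataclass
class CrPenaltySpec:
    """Latent-confounder association penalty specification."""

    method: str = "sq_corr"
    lambda_cr: float = 1.0
    bins: int = 10
    bandwidth: float | None = None  # None -> Scott's rule

    def __post_init__(self):
        if self.method not in ("abs_corr", "sq_corr", "mi_histogram", "mi_kde"):
            raise ValueError(f"unknown penalty method {self.method!r}")
        if self.lambda_cr < 0:
            raise ValueError("lambda_cr must be >= 0")


_EPS = 1e-12


def _corr_per_dim(z: Tensor, c: np.ndarray) -> Tensor:
    """Differentiable Pearson r between each latent dim and c (1 x d)."""
    n = z.shape[0]
    c = c.astype(np.float64)
    cc = c - c.mean()
    c_norm = float(np.sqrt(np.sum(cc ** 2)))
    zc = z - z.mean(axis=0, keepdims=True)
    cov = as_tensor(cc[None, :]) @ zc                      # 1 x d
    z_norm = ((zc * zc).sum(axis=0, keepdims=True) + _EPS).sqrt()
    return cov / (z_norm * (c_norm + _EPS))


def _soft_histogram_mi(zj: Tensor, classes: np.ndarray, bins: int) -> Tensor:
    """Soft-binned histogram MI between one latent dim and a class label."""
    vals = zj.data
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-12:
        return Tensor(0.0)
    centers = np.linspace(lo, hi, bins)
    width = (hi - lo) / (bins - 1)
    # soft assignment: Gaussian responsibility of each bin center
    diff = (zj - as_tensor(centers[None, :])) * (1.0 / (0.6 * width))
    resp = (-0.5 * diff * diff).exp()
    resp = resp / (resp.sum(axis=1, keepdims=True) + _EPS)   # n x bins
    levels, inv = np.unique(classes, return_inverse=True)
    n = len(classes)
    indic = np.zeros((len(levels), n))
    indic[inv, np.arange(n)] = 1.0
    p_class = indic.sum(axis=1) / n                          # K
    joint = (as_tensor(indic) @ resp) / n                    # K x bins
    p_bin = joint.sum(axis=0, keepdims=True)                 # 1 x bins
    ratio = joint / (as_tensor(p_class[:, None]) * p_bin + _EPS)
    mi = (joint * (ratio + _EPS).log()).sum()
    return mi.relu()


def _kde_mi(zj: Tensor, classes: np.ndarray, bandwidth: float | None) -> Tensor:
    """KDE estimate of MI between one latent dim and a class label:
    mean_i log( p(z_i | c_i) / p(z_i) ) with Gaussian kernels."""
    vals = zj.data
    n = len(vals)
    sd = float(vals.std())
    if sd < 1e-12:
        return Tensor(0.0)
    h = bandwidth if bandwidth is not None else 1.06 * sd * n ** (-0.2)
    col = zj  # n x 1
    diff = (col - col.T) * (1.0 / h)
    K = (-0.5 * diff * diff).exp()                           # n x n
    same = (classes[:, None] == classes[None, :]).astype(np.float64)
    counts = same.sum(axis=1)                                # class sizes
    p_all = K.sum(axis=1) * (1.0 / n)
    p_cond = (K * as_tensor(same)).sum(axis=1) / as_tensor(counts)
    mi = ((p_cond + _EPS).log() - (p_all + _EPS).log()).mean()
    return mi.relu()


def cr_penalty(z, c, spec: CrPenaltySpec) -> Tensor:
    """Association penalty between latent dims and a confounder, averaged
    over latent dimensions. Returns a Tensor (value before lambda scaling);
    use ``.item()`` for the float value.

    Zero-variance latent dims or a constant confounder contribute 0.
    """
    z = as_tensor(z)
    c = np.asarray(c, dtype=np.float64).ravel()
    n, d = z.shape
    if len(c) != n:
        raise ValueError("z and c must share the sample count")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if c.std() == 0:
        return Tensor(0.0)
    if spec.method in ("abs_corr", "sq_corr"):
        r = _corr_per_dim(z, c)
        per_dim = r.abs() if spec.method == "abs_corr" else r * r
        return per_dim.mean()
    classes = c  # MI methods treat the confounder as discrete classes
    total = None
    for j in range(d):
        zj = z[:, j: j + 1]
        mi = (_soft_histogram_mi(zj, classes, spec.bins)
              if spec.method == "mi_histogram"
              else _kde_mi(zj, classes, spec.bandwidth))
        total = mi if total is None else total + mi
    return total / d


def train_cr_xvae(data, cfg: XvaeConfig, spec: CrPenaltySpec, c):
    """Train an XVAE whose batch loss adds ``lambda_cr * cr_penalty``.

    ``c`` may be a single confounder vector or a list of vectors; with
    several confounders the per-confounder penalties are summed.
    """
    from .xvae import _extract_views

    cs = [np.asarray(ci, dtype=np.float64).ravel()
          for ci in (c if isinstance(c, (list, tuple)) else [c])]
    x1_all, x2_all = _extract_views(data)
    model = build_xvae(x1_all.shape[1], x2_all.shape[1], cfg)
    penalty_log: list[float] = []

    loss_hook = None
    if spec.lambda_cr > 0:
        def loss_hook(z, idx):
            pen = None
            for ci in cs:
                p = cr_penalty(z, ci[idx], spec)
                pen = p if pen is None else pen + p
            penalty_log.append(pen.item())
            return spec.lambda_cr * pen

    model, history = train_xvae(model, data, cfg, loss_hook=loss_hook)
    history["cr_penalty"] = penalty_log
    return model, history


# ------------------------------------------------------- feature selection

@dataclass
class FsCriterion:
    """Latent feature-selection rule: remove dims associated with any
    confounder by p-value or absolute-correlation threshold."""

    method: str = "abs_corr"
    threshold: float = 0.5

    def __post_init__(self):
        if self.method not in ("pvalue", "abs_corr"):
            raise ValueError(f"unknown criterion {self.method!r}")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0,1)")


def filter_latent_features(post_mean: np.ndarray, confounders,
                           crit: FsCriterion) -> np.ndarray:
    """Indices of latent dims retained after confounder-correlation removal.

    A dim is removed if it violates the criterion for ANY confounder. If
    every dim would be removed, the dim with the smallest max-|r| is kept
    and a warning is emitted.
    """
    post_mean = np.asarray(post_mean, dtype=np.float64)
    n, d = post_mean.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    confounders = [np.asarray(c, dtype=np.float64).ravel() for c in confounders]
    max_abs_r = np.zeros(d)
    removed = np.zeros(d, dtype=bool)
    for j in range(d):
        for c in confounders:
            if post_mean[:, j].std() == 0 or c.std() == 0:
                continue
            r, pval = stats.pearsonr(post_mean[:, j], c)
            max_abs_r[j] = max(max_abs_r[j], abs(r))
            if crit.method == "pvalue" and pval < crit.threshold:
                removed[j] = True
            elif crit.method == "abs_corr" and abs(r) > crit.threshold:
                removed[j] = True
    retained = np.flatnonzero(~removed)
    if len(retained) == 0:
        keep = int(np.argmin(max_abs_r))
        warnings.warn(
            "all latent dims violate the criterion; retaining the least "
            f"confounded dim {keep}", stacklevel=2)
        retained = np.array([keep])
    return retained


# ------------------------------------------------------------------ LR+PCA

def _design_matrix(n, confounders, schemes) -> np.ndarray:
    blocks = [np.ones((n, 1))]
    for c, scheme in zip(confounders, schemes):
        c = np.asarray(c)
        if scheme == "onehot":
            blocks.append(_one_hot(c)[:, 1:])  # drop one level vs intercept
        else:
            blocks.append(c.astype(np.float64)[:, None])
    design = np.hstack(blocks)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("collinear confounder design; using minimum-norm "
                      "least squares", stacklevel=3)
    return design


def lr_pca_baseline(x1: np.ndarray, x2: np.ndarray, confounders, schemes,
                    n_pcs: int = 50, k: int = 6, seed: int = 0):
    """Residualize each feature on the confounders with OLS, concatenate
    views, reduce to the top PCs and cluster with KMeans (10 inits).

    Returns
    -------
    (labels, embedding)
    """
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    n = x1.shape[0]
    design = _design_matrix(n, confounders, schemes)
    if n <= design.shape[1]:
        raise ValueError("need more samples than regression covariates")
    X = np.hstack([x1, x2])
    coef, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ coef
    n_comp = max(1, min(n_pcs, n - 1, resid.shape[1]))
    emb = PCA(n_components=n_comp, random_state=seed).fit_transform(resid)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(emb), emb
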