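"""Synthetic paired-omics data generation and preprocessing.

Generates two sample-aligned views with a known cluster structure: a
continuous, expression-like Gaussian view and a bimodal, methylation-like
beta view. Also provides the standard preprocessing operations used by the
rest of the package: per-feature [0,1] rescaling and top-variance feature
filtering, plus TSV/CSV round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "PairedOmicsDataset",
    "generate_paired_omics",
    "rescale_unit",
    "variance_filter",
    "read_omics_tsv",
    "write_omics_tsv",
    "read_labels_csv",
    "write_labels_csv",
]


@dataclass
class OmicsMatrix:
    """A samples x features matrix with aligned identifier lists."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, f = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"F{j}" for j in range(f)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.feature_ids) != f:
            raise ValueError("feature_ids length does not match column count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class PairedOmicsDataset:
    """Two sample-aligned omics views plus ground-truth cluster labels."""

    view1: OmicsMatrix
    view2: OmicsMatrix
    true_labels: np.ndarray
    rng_seed: int = 0

    def __post_init__(self):
        self.true_labels = np.asarray(self.true_labels, dtype=np.int64)
        if self.view1.sample_ids != self.view2.sample_ids:
            raise ValueError("views must share identical sample order")
        if len(self.true_labels) != self.view1.n_samples:
            raise ValueError("true_labels length mismatch")
        levels, counts = np.unique(self.true_labels, return_counts=True)
        if len(levels) < 2:
            raise ValueError("true_labels must have at least 2 levels")
        if counts.min() < 2:
            raise ValueError("every label level needs at least 2 members")

    @property
    def n_samples(self) -> int:
        return self.view1.n_samples

    @property
    def k(self) -> int:
        return len(np.unique(self.true_labels))


def _balanced_labels(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    base = np.tile(np.arange(k), n // k + 1)[:n]
    return rng.permutation(base)


def generate_paired_omics(n: int, p: int, q: int, k: int, signal: float,
                          seed: int) -> PairedOmicsDataset:
    """Generate a two-view dataset with ``k`` near-balanced clusters.

    View 1 is Gaussian noise around cluster-specific mean shifts whose
    magnitude scales with ``signal``. View 2 is a two-mode beta mixture
    (modes near 0 and near 1) whose per-feature mode preference is
    cluster-dependent with strength ``signal``.

    Draw order (fixed contract for reproducibility): labels, view1 cluster
    means, view1 noise, view2 mode logits, view2 mode membership, view2
    low-mode values, view2 high-mode values.
    """
    if n < k or k < 2:
        raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
    if p < 1 or q < 1:
        raise ValueError(f"feature counts must be positive, got p={p}, q={q}")
    if signal < 0:
        raise ValueError("signal must be >= 0")
    rng = np.random.default_rng(seed)

    labels = _balanced_labels(n, k, rng)

    # view 1: cluster mean shifts of per-entry sd signal/5 on unit noise
    centers = rng.normal(0.0, signal / 5.0, size=(k, p))
    x1 = centers[labels] + rng.normal(0.0, 1.0, size=(n, p))

    # view 2: Beta(2,10) / Beta(10,2) mixture, mixing biased by cluster
    logits = rng.normal(0.0, 1.0, size=(k, q))
    prob_hi = 1.0 / (1.0 + np.exp(-signal * logits))
    hi_mode = rng.random(size=(n, q)) < prob_hi[labels]
    lo_vals = rng.beta(2.0, 10.0, size=(n, q))
    hi_vals = rng.beta(10.0, 2.0, size=(n, q))
    x2 = np.where(hi_mode, hi_vals, lo_vals)

    sample_ids = [f"S{i}" for i in range(n)]
    return PairedOmicsDataset(
        view1=OmicsMatrix(x1, sample_ids, [f"G{j}" for j in range(p)]),
        view2=OmicsMatrix(x2, sample_ids, [f"M{j}" for j in range(q)]),
        true_labels=labels,
        rng_seed=seed,
    )


def rescale_unit(X: OmicsMatrix) -> OmicsMatrix:
    """Map each feature column to [0,1] via (x - min) / (max - min).

    Constant columns map to all-zeros.
    """
    vals = X.values
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    span = hi - lo
    out = np.zeros_like(vals)
    nz = span > 0
    out[:, nz] = (vals[:, nz] - lo[nz]) / span[nz]
    return OmicsMatrix(out, list(X.sample_ids), list(X.feature_ids))


def variance_filter(X: OmicsMatrix, m: int) -> OmicsMatrix:
    """Keep the ``m`` highest-variance features, preserving original order.

    Ties are broken by original column index (earlier column wins).
    """
    if m > X.n_features:
        raise ValueError(f"m={m} exceeds feature count {X.n_features}")
    if m < 0:
        raise ValueError("m must be nonnegative")
    var = X.values.var(axis=0, ddof=1) if X.n_samples > 1 else np.zeros(X.n_features)
    # stable sort on negated variance keeps first-index-wins tie-breaking
    top = np.sort(np.argsort(-var, kind="stable")[:m])
    return OmicsMatrix(X.values[:, top], list(X.sample_ids),
                       [X.feature_ids[j] for j in top])


def rescale_dataset(ds: PairedOmicsDataset) -> PairedOmicsDataset:
    """Unit-rescale both views of a paired dataset."""
    return PairedOmicsDataset(rescale_unit(ds.view1), rescale_unit(ds.view2),
                              ds.true_labels.copy(), ds.rng_seed)


# ---------------------------------------------------------------------- I/O

def write_omics_tsv(X: OmicsMatrix, path) -> None:
    df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.feature_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_omics_tsv(path) -> OmicsMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OmicsMatrix(df.to_numpy(dtype=np.float64),
                       [str(s) for s in df.index],
                       [str(c) for c in df.columns])


def write_labels_csv(sample_ids, values, path, value_name: str = "value") -> None:
    pd.DataFrame({"sample_id": sample_ids, value_name: values}).to_csv(path, index=False)


def read_labels_csv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    return [str(s) for s in df.iloc[:, 0]], df.iloc[:, 1].to_numpy()
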