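"""Evaluation statistics: relative reconstruction error, consensus
dispersion, and external clustering agreement (ARI / NMI)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

__all__ = [
    "relative_error_view",
    "relative_error_combined",
    "dispersion",
    "ari",
    "nmi",
    "EvalReport",
]


def relative_error_view(x: np.ndarray, x_hat: np.ndarray) -> float:
    """L2 relative error: ||x - x'||_F / ||x||_F."""
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    denom = np.sqrt(np.sum(x ** 2))
    if denom == 0:
        raise ValueError("input matrix is all-zero; relative error undefined")
    return float(np.sqrt(np.sum((x - x_hat) ** 2)) / denom)


def relative_error_combined(x1, x1_hat, x2, x2_hat) -> float:
    """Combined relative error: sum of per-view residual norms over sum of
    per-view input norms (both views weighted equally)."""
    num = 0.0
    den = 0.0
    for x, xh in ((x1, x1_hat), (x2, x2_hat)):
        x = np.asarray(x, dtype=np.float64)
        xh = np.asarray(xh, dtype=np.float64)
        if x.shape != xh.shape:
            raise ValueError(f"shape mismatch {x.shape} vs {xh.shape}")
        num += np.sqrt(np.sum((x - xh) ** 2))
        den += np.sqrt(np.sum(x ** 2))
    if den == 0:
        raise ValueError("both input matrices are all-zero")
    return float(num / den)


def dispersion(consensus_matrix: np.ndarray) -> float:
    """Consensus stability: mean over all entries of 4 * (a - 0.5)^2.

    Equals 1 iff every entry is 0 or 1; equals 0 for an all-0.5 matrix.
    The diagonal is included.
    """
    a = np.asarray(consensus_matrix, dtype=np.float64)
    if a.min() < 0 or a.max() > 1:
        raise ValueError("consensus entries must lie in [0,1]")
    n = a.shape[0]
    return float(np.sum((a - 0.5) ** 2 * 4.0) / (n * n))


def _check_pair(a, b):
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if len(a) != len(b):
        raise ValueError(f"label length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("need at least 2 samples")
    return a, b


def ari(a, b) -> float:
    """Adjusted Rand index (pair-counting, adjusted for chance)."""
    a, b = _check_pair(a, b)
    return float(adjusted_rand_score(a, b))


def nmi(a, b) -> float:
    """Normalized mutual information with arithmetic-mean normalization."""
    a, b = _check_pair(a, b)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


@dataclass
class EvalReport:
    """Bundle of evaluation metrics for one trained model run."""

    re_view1: float | None = None
    re_view2: float | None = None
    re_combined: float | None = None
    dispersion: float | None = None
    ari_true: float | None = None
    nmi_true: float | None = None
    ari_confounder: dict = field(default_factory=dict)
    nmi_confounder: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "re_view1": self.re_view1,
            "re_view2": self.re_view2,
            "re_combined": self.re_combined,
            "dispersion": self.dispersion,
            "ari_true": self.ari_true,
            "nmi_true": self.nmi_true,
            "ari_confounder": dict(self.ari_confounder),
            "nmi_confounder": dict(self.nmi_confounder),
        }
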