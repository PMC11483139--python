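"""Ground-truth confounding-effect simulators.

Three additive effect families on a pair of unit-rescaled views:

* linear   — ``E_v = (c + 5) outer w_v`` with a discrete numeric confounder
  ``c in {0..5}`` and per-feature weights ``w1 ~ U(0, 0.1)``,
  ``w2 ~ U(0, 0.2)``;
* square   — ``E_v = c^2 outer w_v`` with ``w1, w2 ~ U(0, 0.04)``;
* categorical — each sample is shifted toward its class's random direction
  (class shift vectors ~ U(0,1) per feature) scaled by a per-sample weight
  ``w ~ U(0,1)``.

Effects are purely additive and never clipped, so the injected signal is
exactly recoverable: ``X* - X == sum(E)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import PairedOmicsDataset

__all__ = [
    "NumericConfounder",
    "CategoricalConfounder",
    "ConfoundingEffect",
    "ConfoundedDataset",
    "draw_numeric_confounder",
    "linear_effect",
    "square_effect",
    "categorical_effect",
    "mixed_effect",
    "apply_effects",
]

N_LEVELS = 6  # default number of confounder levels


@dataclass
class NumericConfounder:
    """Discrete numeric confounder with levels {0..n_levels-1}."""

    values: np.ndarray
    seed: int = 0
    n_levels: int = N_LEVELS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 1:
            raise ValueError("confounder must be a vector")
        if self.values.min() < 0 or self.values.max() >= self.n_levels:
            raise ValueError(f"confounder values must lie in 0..{self.n_levels - 1}")

    def __len__(self):
        return len(self.values)


@dataclass
class CategoricalConfounder:
    """Class membership plus the shift geometry that realizes its effect."""

    class_of: np.ndarray          # n, values in 1..n_classes
    shift1: np.ndarray            # n_classes x p, entries in [0,1]
    shift2: np.ndarray            # n_classes x q, entries in [0,1]
    sample_weight: np.ndarray     # n, entries in [0,1]
    seed: int = 0

    def __post_init__(self):
        self.class_of = np.asarray(self.class_of, dtype=np.int64)
        self.sample_weight = np.asarray(self.sample_weight, dtype=np.float64)
        n_classes = self.shift1.shape[0]
        if self.class_of.min() < 1 or self.class_of.max() > n_classes:
            raise ValueError(f"classes must lie in 1..{n_classes}")
        for name, m in (("shift1", self.shift1), ("shift2", self.shift2)):
            if m.min() < 0 or m.max() > 1:
                raise ValueError(f"{name} entries must lie in [0,1]")
        if self.sample_weight.min() < 0 or self.sample_weight.max() > 1:
            raise ValueError("sample_weight entries must lie in [0,1]")


@dataclass
class ConfoundingEffect:
    """One additive effect with its evaluation label and generator state."""

    kind: str                     # linear | square | categorical
    E1: np.ndarray
    E2: np.ndarray
    confounder_label: np.ndarray
    feature_weight1: np.ndarray | None = None
    feature_weight2: np.ndarray | None = None
    confounder: object = None

    def __post_init__(self):
        if self.kind not in ("linear", "square", "categorical"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.E1.shape[0] != self.E2.shape[0]:
            raise ValueError("E1/E2 sample counts differ")
        if len(self.confounder_label) != self.E1.shape[0]:
            raise ValueError("confounder_label length mismatch")


@dataclass
class ConfoundedDataset:
    """Unit-rescaled base dataset plus additive confounding effects."""

    base: PairedOmicsDataset
    confounded1: np.ndarray
    confounded2: np.ndarray
    effects: list = field(default_factory=list)

    def __post_init__(self):
        if self.confounded1.shape != self.base.view1.values.shape:
            raise ValueError("confounded1 shape mismatch")
        if self.confounded2.shape != self.base.view2.values.shape:
            raise ValueError("confounded2 shape mismatch")

    @property
    def n_samples(self) -> int:
        return self.base.n_samples

    @property
    def true_labels(self) -> np.ndarray:
        return self.base.true_labels

    def confounder_labels(self) -> dict[str, np.ndarray]:
        """Per-effect evaluation labels keyed by effect kind."""
        return {e.kind: e.confounder_label for e in self.effects}


def draw_numeric_confounder(n: int, seed: int, n_levels: int = N_LEVELS) -> NumericConfounder:
    """Draw iid uniform discrete confounder values over ``n_levels`` levels."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return NumericConfounder(rng.integers(0, n_levels, size=n), seed=seed,
                             n_levels=n_levels)


def linear_effect(shape: tuple[int, int, int], c: NumericConfounder,
                  w1_hi: float = 0.1, w2_hi: float = 0.2,
                  seed: int = 0) -> ConfoundingEffect:
    """Rank-1 linear effect ``(c + 5) outer w_v`` with ``w_v ~ U(0, w_hi)``."""
    n, p, q = shape
    if len(c) != n:
        raise ValueError(f"confounder length {len(c)} != n={n}")
    rng = np.random.default_rng(seed)
    w1 = rng.uniform(0.0, w1_hi, size=p)
    w2 = rng.uniform(0.0, w2_hi, size=q)
    lin = c.values + 5.0
    return ConfoundingEffect("linear", np.outer(lin, w1), np.outer(lin, w2),
                             confounder_label=c.values.copy(),
                             feature_weight1=w1, feature_weight2=w2, confounder=c)


def square_effect(shape: tuple[int, int, int], c: NumericConfounder,
                  w_hi: float = 0.04, seed: int = 0) -> ConfoundingEffect:
    """Rank-1 squared effect ``c^2 outer w_v`` with ``w_v ~ U(0, w_hi)``."""
    n, p, q = shape
    if len(c) != n:
        raise ValueError(f"confounder length {len(c)} != n={n}")
    rng = np.random.default_rng(seed)
    w1 = rng.uniform(0.0, w_hi, size=p)
    w2 = rng.uniform(0.0, w_hi, size=q)
    sq = c.values.astype(np.float64) ** 2
    return ConfoundingEffect("square", np.outer(sq, w1), np.outer(sq, w2),
                             confounder_label=c.values.copy(),
                             feature_weight1=w1, feature_weight2=w2, confounder=c)


def categorical_effect(shape: tuple[int, int, int], n_classes: int = N_LEVELS,
                       seed: int = 0) -> ConfoundingEffect:
    """Class-wise directional shift ``diag(w) @ C_v`` with all draws ~ U(0,1).

    Samples are assigned to ``n_classes`` near-balanced random classes; the
    effect matrix stacks each sample's class shift vector scaled by its
    per-sample weight, so its rank is at most ``n_classes``.
    """
    n, p, q = shape
    if n < n_classes:
        raise ValueError(f"need n >= n_classes, got n={n}, n_classes={n_classes}")
    rng = np.random.default_rng(seed)
    base = np.tile(np.arange(1, n_classes + 1), n // n_classes + 1)[:n]
    class_of = rng.permutation(base)
    shift1 = rng.uniform(0.0, 1.0, size=(n_classes, p))
    shift2 = rng.uniform(0.0, 1.0, size=(n_classes, q))
    w = rng.uniform(0.0, 1.0, size=n)
    conf = CategoricalConfounder(class_of, shift1, shift2, w, seed=seed)
    E1 = w[:, None] * shift1[class_of - 1]
    E2 = w[:, None] * shift2[class_of - 1]
    return ConfoundingEffect("categorical", E1, E2,
                             confounder_label=class_of.copy(), confounder=conf)


def mixed_effect(shape: tuple[int, int, int],
                 seeds: tuple[int, int, int]) -> list[ConfoundingEffect]:
    """Three mutually independent effects: linear, square, categorical.

    Each effect carries its own independently drawn confounder variable so
    the three evaluation labels are (near-)independent.
    """
    s_lin, s_sq, s_cat = seeds
    n = shape[0]
    c_lin = draw_numeric_confounder(n, seed=s_lin)
    c_sq = draw_numeric_confounder(n, seed=s_sq)
    return [
        linear_effect(shape, c_lin, seed=s_lin + 1),
        square_effect(shape, c_sq, seed=s_sq + 1),
        categorical_effect(shape, seed=s_cat),
    ]


def apply_effects(base: PairedOmicsDataset, effects) -> ConfoundedDataset:
    """Add effects to a unit-rescaled dataset; no clipping is applied.

    Additivity is exact: ``confoundedV == base + sum(E_V)`` bit-for-bit
    (effects are summed first, then added to the base).
    """
    effects = list(effects)
    for e in effects:
        if (e.E1.shape != base.view1.values.shape
                or e.E2.shape != base.view2.values.shape):
            raise ValueError(f"effect {e.kind!r} shape mismatch with base views")
    x1 = base.view1.values + sum(e.E1 for e in effects)
    x2 = base.view2.values + sum(e.E2 for e in effects)
    return ConfoundedDataset(base=base, confounded1=np.asarray(x1, dtype=np.float64),
                             confounded2=np.asarray(x2, dtype=np.float64),
                             effects=effects)
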