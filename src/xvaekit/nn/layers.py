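"""Dense layers, parameter containers and the Adam optimizer."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor

__all__ = ["Linear", "Adam", "mlp_forward"]


class Linear:
    """Affine layer ``x @ W + b`` with an optional extra input block.

    The extra block (``W_extra``) receives a second input (conditioning
    covariates) that is added to the same output. Keeping it as a separate
    parameter lets a conditional model share the exact initialization of its
    unconditional counterpart for the primary block.
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 activation: str = "linear"):
        if in_dim <= 0 or out_dim <= 0:
            raise ValueError(f"layer widths must be positive, got {in_dim}x{out_dim}")
        scale = np.sqrt(2.0 / in_dim)
        self.W = Tensor(rng.normal(0.0, scale, size=(in_dim, out_dim)), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)
        self.W_extra: Tensor | None = None
        self.activation = activation

    def add_extra_input(self, extra_dim: int):
        # zero-init: the conditioning pathway starts inert (the conditional
        # model's forward pass equals its unconditional counterpart's) and
        # grows only as reconstruction gradients demand
        self.W_extra = Tensor(np.zeros((extra_dim, self.W.data.shape[1])),
                              requires_grad=True)

    def __call__(self, x, extra=None) -> Tensor:
        out = as_tensor(x) @ self.W + self.b
        if self.W_extra is not None:
            if extra is None:
                raise ValueError("layer has a conditioning block but no extra input given")
            out = out + as_tensor(extra) @ self.W_extra
        if self.activation == "relu":
            out = out.relu()
        elif self.activation != "linear":
            raise ValueError(f"unknown activation {self.activation!r}")
        return out

    @property
    def parameters(self):
        ps = [self.W, self.b]
        if self.W_extra is not None:
            ps.append(self.W_extra)
        return ps


def mlp_forward(layers, x) -> Tensor:
    h = as_tensor(x)
    for layer in layers:
        h = layer(h)
    return h


class Adam:
    """Adam with bias correction; state keyed by parameter identity order."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
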