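"""Dense layers, dropout and the Adam optimizer on top of `_autodiff`.

Parameters are held in plain lists of Tensors; initialization is
He-uniform for hidden layers, driven by an explicit numpy Generator so
model construction is fully seed-deterministic.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

__all__ = ["Linear", "MLP", "dropout", "Adam"]


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / n_in)
        self.W = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """Fully connected stack with ReLU between hidden layers.

    `widths` are hidden-layer sizes; the final Linear maps to `n_out`
    with no activation (callers apply sigmoid/softmax as needed).
    """

    def __init__(self, n_in: int, widths: list[int], n_out: int, rng: np.random.Generator):
        dims = [n_in] + list(widths) + [n_out]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor, dropout_rate: float = 0.0,
                 rng: np.random.Generator | None = None) -> Tensor:
        h = x
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i < len(self.layers) - 1:
                h = h.relu()
            if dropout_rate > 0.0:
                h = dropout(h, dropout_rate, rng)
        return h

    @property
    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters]


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when rate == 0."""
    if rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


class Adam:
    """Adaptive-moment gradient descent (bias-corrected)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
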