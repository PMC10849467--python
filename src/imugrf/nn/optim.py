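"""AdamW (decoupled weight decay) and the warmup–cosine schedule."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class AdamW:
    """Adam with decoupled weight decay applied to every parameter.

    The learning rate is supplied per step (see the schedule in
    :mod:`imugrf.training`), so ``step(lr)`` takes it explicitly.
    """

    def __init__(self, params: dict[str, Tensor], weight_decay: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = dict(params)
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self, lr: float) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= lr * self.weight_decay * p.data
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
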