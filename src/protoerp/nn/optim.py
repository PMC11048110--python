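"""Adam optimizer and cosine-annealing learning-rate schedule."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with decoupled learning rate (no weight decay).

    Defaults follow the trainer configuration: beta1 = 0.9 (the "momentum"
    of the optimizer), beta2 = 0.999.
    """

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                       ).astype(p.data.dtype, copy=False)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_lr(base_lr: float, epoch: int, total_epochs: int,
              floor_ratio: float = 0.01) -> float:
    """Cosine annealing from ``base_lr`` down to ``base_lr * floor_ratio``
    over ``total_epochs`` (no restarts)."""
    if total_epochs <= 1:
        return base_lr
    floor = base_lr * floor_ratio
    frac = epoch / (total_epochs - 1)
    return floor + 0.5 * (base_lr - floor) * (1.0 + np.cos(np.pi * frac))
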