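"""Optimisers and learning-rate schedules."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with bias correction (Kingma & Ba defaults)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def piecewise_constant_lr(initial_lr: float, drop_factor: float,
                          drop_period: int, epoch: int) -> float:
    """Learning rate for a 1-based epoch index.

    The rate is multiplied by ``drop_factor`` after each completed
    ``drop_period`` epochs, so with period 20 epochs 1-20 run at the initial
    rate and epoch 21 is the first reduced one.
    """
    if epoch < 1:
        raise ValueError("epoch index is 1-based")
    return initial_lr * drop_factor ** ((epoch - 1) // drop_period)
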