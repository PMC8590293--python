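"""Optimizers."""

from __future__ import annotations

import numpy as np

from .autograd import DTYPE, Tensor


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 warmup_steps: int = 0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.warmup_steps = warmup_steps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        lr = self.lr
        if self.warmup_steps > 0:
            lr *= min(1.0, self.t / self.warmup_steps)
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()
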