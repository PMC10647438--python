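"""Optimization: Adam with L2 weight decay and cosine-annealed learning rate."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter


class Adam:
    """Adam with the usual bias correction; ``weight_decay`` is classic L2
    regularization folded into the gradient (not decoupled)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1 ** self.t)
            vhat = self._v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_annealing_lr(lr0: float, epoch: int, total_epochs: int) -> float:
    """lr(e) = lr0 * (1 + cos(pi * e / E)) / 2 — lr(0)=lr0, lr(E)=0."""
    if total_epochs <= 0:
        return lr0
    return float(lr0 * 0.5 * (1.0 + np.cos(np.pi * min(epoch, total_epochs) / total_epochs)))
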