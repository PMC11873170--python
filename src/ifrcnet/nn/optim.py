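"""Optimizers: Adam (the default training algorithm) and SGD with momentum."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "Adam", "build_optimizer"]


class Optimizer:
    def __init__(self, params):
        self.params = [p for p in params if p.requires_grad]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):  # pragma: no cover - interface
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr: float, momentum: float = 0.0):
        super().__init__(params)
        self.lr, self.momentum = lr, momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            if self.momentum:
                v *= self.momentum
                v += p.grad
                p.data -= self.lr * v
            else:
                p.data -= self.lr * p.grad


class Adam(Optimizer):
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self):
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * (p.grad * p.grad)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def build_optimizer(name: str, params, lr: float):
    name = name.lower()
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "sgd":
        return SGD(params, lr=lr, momentum=0.9)
    raise ValueError(f"unknown optimizer {name!r} (expected 'adam' or 'sgd')")
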