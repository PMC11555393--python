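"""First-order optimizers: SGD with momentum, Adam, RMSprop."""

from __future__ import annotations

from typing import List

import numpy as np

from .layers import Param


class Optimizer:
    def __init__(self, params: List[Param], lr: float):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.params = params
        self.lr = lr

    def step(self) -> None:
        raise NotImplementedError


class SGDM(Optimizer):
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr, momentum: float = 0.9):
        super().__init__(params, lr)
        self.momentum = momentum
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        for p, v in zip(self.params, self.v):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v


class Adam(Optimizer):
    def __init__(self, params, lr, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, params, lr, rho: float = 0.9, eps: float = 1e-8):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        for p, v in zip(self.params, self.v):
            v *= self.rho
            v += (1 - self.rho) * p.grad ** 2
            p.value -= self.lr * p.grad / (np.sqrt(v) + self.eps)


_OPTIMIZERS = {"sgdm": SGDM, "adam": Adam, "rmsprop": RMSprop}


def make_optimizer(name: str, params: List[Param], lr: float) -> Optimizer:
    try:
        cls = _OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; "
                         f"choose from {sorted(_OPTIMIZERS)}") from None
    return cls(params, lr)
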