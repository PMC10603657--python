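"""Optimisers. Only classical SGD with momentum is needed here."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class SGD:
    """Stochastic gradient descent with (heavy-ball) momentum.

    v <- momentum * v + g;  p <- p - lr * v
    The learning rate may be changed between steps (polynomial schedules).
    """

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        rate = self.lr if lr is None else float(lr)
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= rate * v
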