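"""Adam optimizer and reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .tensor import F32, Parameter


class Adam:
    """Adam with optional L2 weight decay on parameters flagged ``decay``.

    The decay term corresponds to adding λ‖w‖² to the loss (gradient 2λw);
    it is applied only to convolution kernels, not normalization parameters.
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.90, 0.99),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and getattr(p, "decay", False):
                g = g + F32(2.0 * self.weight_decay) * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= F32(self.lr) * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def weights_sq_norm(self) -> float:
        """‖w‖² over decayed parameters (the L2 term reported in the loss)."""
        return float(sum(np.sum(p.data.astype(np.float64) ** 2)
                         for p in self.params if getattr(p, "decay", False)))


class ReduceLROnPlateau:
    """Divide the learning rate by a factor after ``patience`` consecutive
    epochs without validation-loss improvement."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5,
                 min_delta: float = 0.0):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.num_bad = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def step(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; returns True if lr was reduced."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.num_bad = 0
            return False
        self.num_bad += 1
        if self.num_bad >= self.patience:
            self.optimizer.lr *= self.factor
            self.num_bad = 0
            return True
        return False
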