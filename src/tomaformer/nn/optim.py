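"""Optimizers. Only Adadelta is provided: it is the training algorithm the
segmentation model is tuned for (learning rate 1.00, decay rho 0.95)."""

from __future__ import annotations

import numpy as np


class Adadelta:
    """Adadelta (Zeiler 2012): per-weight step sizes from running RMS of
    gradients and updates.

    Parameters
    ----------
    params : iterable of Parameter
    lr : global scale on the update, default 1.0
    rho : decay rate of the running averages, default 0.95
    eps : numerical floor inside the square roots
    """

    def __init__(self, params, lr: float = 1.0, rho: float = 0.95, eps: float = 1e-6):
        self.params = list(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._acc_grad = [np.zeros_like(p.data) for p in self.params]
        self._acc_delta = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        for p, eg, ed in zip(self.params, self._acc_grad, self._acc_delta):
            if p.grad is None:
                continue
            g = p.grad
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            delta = -np.sqrt(ed + self.eps) / np.sqrt(eg + self.eps) * g
            ed *= self.rho
            ed += (1 - self.rho) * delta * delta
            p.data = p.data + self.lr * delta
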