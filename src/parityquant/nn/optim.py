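"""Adam optimizer over (param, grad) array pairs updated in place."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params_grads, lr=5e-4, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=0.0):
        if lr < 0:
            raise ValueError("lr must be >= 0")
        self.pairs = list(params_grads)
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, beta1, beta2, eps, weight_decay
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.pairs):
            if self.wd:
                g = g + self.wd * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
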