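"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import math

import numpy as np


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float = 5e-4, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.04):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            if self.weight_decay and p.data.ndim > 1:  # decay only matrix/conv weights
                p.data = p.data * (1.0 - self.lr * self.weight_decay)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self):
        return {"t": self.t, "m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state):
        self.t = int(state["t"])
        self.m = [np.asarray(m, np.float32).copy() for m in state["m"]]
        self.v = [np.asarray(v, np.float32).copy() for v in state["v"]]


def cosine_lr(base_lr: float, step: int, total_steps: int, final_frac: float = 0.01) -> float:
    """Cosine decay from base_lr to final_frac * base_lr over total_steps."""
    if total_steps <= 1:
        return base_lr
    t = min(step, total_steps - 1) / (total_steps - 1)
    lo = base_lr * final_frac
    return lo + 0.5 * (base_lr - lo) * (1.0 + math.cos(math.pi * t))
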