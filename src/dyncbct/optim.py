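"""Adaptive-moment (Adam) optimizer over named parameter arrays."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Adam with per-parameter learning rates.

    ``lrs`` maps parameter names to learning rates; parameters without an
    entry use ``default_lr``.  State can be reset when the parameter set is
    rebuilt (e.g. after adaptive density control).
    """

    def __init__(self, lrs: dict[str, float] | None = None, default_lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lrs = dict(lrs or {})
        self.default_lr = default_lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def reset(self) -> None:
        self.m.clear()
        self.v.clear()
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for name, g in grads.items():
            p = params[name]
            if name not in self.m or self.m[name].shape != p.shape:
                self.m[name] = np.zeros_like(p)
                self.v[name] = np.zeros_like(p)
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            lr = self.lrs.get(name, self.default_lr)
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
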