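"""Optimizers operating on Sequential parameter dicts."""

from __future__ import annotations

import numpy as np

from hemoflow.nn.layers import Sequential


class Adam:
    """Adam with DCGAN-convention moments (beta1=0.5, beta2=0.999)."""

    def __init__(
        self,
        net: Sequential,
        lr: float = 2e-4,
        beta1: float = 0.5,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.net, self.lr, self.beta1, self.beta2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for full, layer, name, p in self.net.named_params():
            g = layer.grads[name]
            if full not in self.m:
                self.m[full] = np.zeros_like(p)
                self.v[full] = np.zeros_like(p)
            self.m[full] = self.beta1 * self.m[full] + (1 - self.beta1) * g
            self.v[full] = self.beta2 * self.v[full] + (1 - self.beta2) * g**2
            mhat = self.m[full] / (1 - self.beta1**self.t)
            vhat = self.v[full] / (1 - self.beta2**self.t)
            layer.params[name] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    """Plain gradient descent, optional momentum."""

    def __init__(self, net: Sequential, lr: float = 0.01, momentum: float = 0.0) -> None:
        self.net, self.lr, self.momentum = net, lr, momentum
        self.vel: dict[str, np.ndarray] = {}

    def step(self) -> None:
        for full, layer, name, p in self.net.named_params():
            g = layer.grads[name]
            if self.momentum > 0:
                self.vel[full] = self.momentum * self.vel.get(full, 0.0) - self.lr * g
                layer.params[name] = p + self.vel[full]
            else:
                layer.params[name] = p - self.lr * g
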