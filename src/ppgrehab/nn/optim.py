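"""Adam optimizer over a list of layers."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Adam:
    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()
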