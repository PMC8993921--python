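"""Minimal dense-network machinery: tanh MLPs with hand-written backprop
and an Adam optimizer.  Everything is plain numpy so that training is
bit-reproducible for a fixed seed on fixed hardware.
"""

from __future__ import annotations

import numpy as np


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


class MLP:
    """Fully connected network, tanh on hidden layers, linear output.

    Parameters are a flat list [W0, b0, W1, b1, ...].  `forward` returns the
    output and a cache; `backward` consumes the cache and the output gradient
    and returns (parameter gradients, input gradient).
    """

    def __init__(self, sizes, rng: np.random.Generator):
        self.sizes = list(sizes)
        self.params = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            self.params.append(glorot(rng, a, b))
            self.params.append(np.zeros(b))

    @property
    def n_layers(self) -> int:
        return len(self.sizes) - 1

    def forward(self, x: np.ndarray):
        acts = [x]
        h = x
        for k in range(self.n_layers):
            W, b = self.params[2 * k], self.params[2 * k + 1]
            h = h @ W + b
            if k < self.n_layers - 1:
                h = np.tanh(h)
            acts.append(h)
        return h, acts

    def backward(self, acts, grad_out: np.ndarray):
        grads = [None] * len(self.params)
        g = grad_out
        for k in range(self.n_layers - 1, -1, -1):
            W = self.params[2 * k]
            a_in = acts[k]
            grads[2 * k] = a_in.T @ g
            grads[2 * k + 1] = g.sum(axis=0)
            g = g @ W.T
            if k > 0:
                # acts[k] holds tanh output of the previous hidden layer
                g = g * (1.0 - acts[k] ** 2)
        return grads, g


class Adam:
    """Adam on a flat list of parameter arrays (updates in place)."""

    def __init__(self, params, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if g is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def softplus(x):
    return np.logaddexp(0.0, x)


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))
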