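"""Minimal dense-network machinery on NumPy: layers, activations, Adam.

The networks in this package are small (a few thousand parameters), so the
forward and backward passes are written out explicitly rather than pulled
from a deep-learning framework; tests check every analytic gradient against
central finite differences.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-8  # probability clamp inside logarithms


def tanh(x):
    return np.tanh(x)


def dtanh(y):
    """Derivative of tanh expressed via its output y = tanh(x)."""
    return 1.0 - y * y


def sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def dsigmoid(y):
    """Derivative of the logistic function via its output."""
    return y * (1.0 - y)


def clamp_prob(p):
    return np.clip(p, EPS, 1.0 - EPS)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Normal Glorot initialization (parameters drawn from a normal law)."""
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_out, fan_in))


class Dense:
    """Affine layer ``y = x @ W.T + b`` with cached input for backprop."""

    def __init__(self, rng, fan_in, fan_out):
        self.W = glorot(rng, fan_in, fan_out)
        self.b = np.zeros(fan_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad_out, accumulate=False):
        if not accumulate:
            self.gW.fill(0.0)
            self.gb.fill(0.0)
        self.gW += grad_out.T @ self._x
        self.gb += grad_out.sum(axis=0)
        return grad_out @ self.W

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class MLP:
    """Fully connected net with tanh hidden layers and a chosen head.

    ``head`` is ``'tanh'`` (bounded odd output in [-1, 1]) or ``'sigmoid'``
    (probabilities in (0, 1)).
    """

    def __init__(self, rng, sizes, head="tanh"):
        self.layers = [Dense(rng, a, b) for a, b in zip(sizes[:-1], sizes[1:])]
        self.head = head
        self._acts = None

    def forward(self, x):
        acts = []
        h = x
        for layer in self.layers[:-1]:
            h = tanh(layer.forward(h))
            acts.append(h)
        z = self.layers[-1].forward(h)
        out = tanh(z) if self.head == "tanh" else sigmoid(z)
        acts.append(out)
        self._acts = acts
        return out

    def backward(self, grad_out, accumulate=False):
        """Backprop ``dL/d(output)``; returns ``dL/d(input)``."""
        out = self._acts[-1]
        grad = grad_out * (dtanh(out) if self.head == "tanh" else dsigmoid(out))
        grad = self.layers[-1].backward(grad, accumulate)
        for layer, act in zip(self.layers[-2::-1], self._acts[-2::-1]):
            grad = grad * dtanh(act)
            grad = layer.backward(grad, accumulate)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Adam:
    """Adam optimizer over a list of ``(param, grad)`` array pairs."""

    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
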