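"""Minimal feedforward network with manual backpropagation.

Shared numerical core for the supervised, adversarial and policy-gradient
models: dense layers with ReLU hidden activations, Adam updates, and a
backward pass that also returns the gradient with respect to the *input*
of the network — required to couple the site adversary to the classifier
score through gradient reversal.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DenseNet", "Adam", "sigmoid", "softmax"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax."""
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


class DenseNet:
    """Fully-connected network: ReLU hidden layers, linear output head.

    The output nonlinearity (sigmoid for binary scores, softmax for the
    adversary / policy heads) is applied by the caller, which also supplies
    the gradient with respect to the output pre-activations.
    """

    def __init__(self, in_dim, hidden_sizes, out_dim, rng: np.random.Generator):
        hidden_sizes = tuple(int(h) for h in hidden_sizes)
        if not hidden_sizes or any(h < 1 for h in hidden_sizes):
            raise ValueError("hidden_sizes must contain at least one positive layer width")
        dims = (int(in_dim), *hidden_sizes, int(out_dim))
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            # He initialisation, suited to the ReLU hidden stack
            self.weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def parameters(self):
        return self.weights + self.biases

    def forward(self, X: np.ndarray):
        """Return (output pre-activations, activation cache for backward)."""
        h = np.asarray(X, dtype=float)
        acts = [h]
        last = self.n_layers - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            h = z if i == last else np.maximum(z, 0.0)
            acts.append(h)
        return h, acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def backward(self, acts, d_out: np.ndarray):
        """Backpropagate d(loss)/d(output pre-activation).

        Returns (gradients aligned with :meth:`parameters`, d(loss)/d(input)).
        """
        L = self.n_layers
        gW = [None] * L
        gb = [None] * L
        d = np.asarray(d_out, dtype=float)
        for i in reversed(range(L)):
            gW[i] = acts[i].T @ d
            gb[i] = d.sum(axis=0)
            d = d @ self.weights[i].T
            if i > 0:  # pass through the ReLU of the layer below
                d = d * (acts[i] > 0)
        return gW + gb, d


class Adam:
    """Adam optimiser over a fixed list of parameter arrays (in-place updates)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = float(lr)
        self.beta1 = float(beta1)
        self.beta2 = float(beta2)
        self.eps = float(eps)
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
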