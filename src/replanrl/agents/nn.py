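"""Minimal fully-connected networks with hand-written backprop and Adam.

The agents only need small multilayer perceptrons (two hidden layers by
default) over flattened DVH states, so the forward/backward passes are
implemented directly in numpy.  Determinism: all initialization comes from
the generator passed in, and updates are pure functions of the data.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "softmax", "flatten_obs"]


def flatten_obs(obs) -> np.ndarray:
    """Accept a DVHState-like object (with .flatten) or any array."""
    if hasattr(obs, "flatten") and not isinstance(obs, np.ndarray):
        return np.asarray(obs.flatten(), dtype=float)
    return np.asarray(obs, dtype=float).ravel()


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MLP:
    """ReLU MLP with a linear output layer; He-initialized."""

    def __init__(self, layer_sizes: list[int], rng: np.random.Generator):
        self.sizes = list(layer_sizes)
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    # -- parameter plumbing ------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        out = []
        for W, b in zip(self.W, self.b):
            out.extend([W, b])
        return out

    def get_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_params(self, params: list[np.ndarray]) -> None:
        for target, src in zip(self.parameters(), params):
            np.copyto(target, src)

    def clone(self) -> "MLP":
        other = MLP.__new__(MLP)
        other.sizes = list(self.sizes)
        other.W = [W.copy() for W in self.W]
        other.b = [b.copy() for b in self.b]
        return other

    # -- forward / backward ------------------------------------------------
    def forward(self, X: np.ndarray):
        """Return (output, cache); X is (batch, in_dim)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        activations = [X]
        h = X
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            h = z if i == n_layers - 1 else np.maximum(z, 0.0)
            activations.append(h)
        return h, activations

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def backward(self, activations: list[np.ndarray], grad_out: np.ndarray):
        """Gradients of sum(loss) given d loss / d output.

        Returns a flat list [dW0, db0, dW1, db1, ...] aligned with
        :meth:`parameters`.
        """
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        delta = np.atleast_2d(grad_out)
        for i in range(len(self.W) - 1, -1, -1):
            h_in = activations[i]
            grads_W[i] = h_in.T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (activations[i] > 0)
        out = []
        for gW, gb in zip(grads_W, grads_b):
            out.extend([gW, gb])
        return out


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
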