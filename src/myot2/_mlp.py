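"""Minimal fully connected regressor: ReLU hidden layers, linear output,
Adam optimizer, mean-absolute-error loss.

NumPy implementation kept deliberately small — the models used here are a
few hundred thousand parameters and train comfortably on one CPU core with
BLAS matmuls.  Deterministic given the seed.
"""

from __future__ import annotations

import numpy as np


class AdamMLP:
    """Feed-forward net with ReLU hidden activations and a linear output."""

    def __init__(self, layer_sizes, seed=0):
        # layer_sizes includes input and output widths
        self.layer_sizes = [int(s) for s in layer_sizes]
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least input and output layers")
        rng = np.random.default_rng(seed)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            # He initialization for ReLU layers
            w = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            self.weights.append(w)
            self.biases.append(np.zeros(fan_out))
        self._adam_m = [np.zeros_like(w) for w in self.weights] + [
            np.zeros_like(b) for b in self.biases
        ]
        self._adam_v = [np.zeros_like(w) for w in self.weights] + [
            np.zeros_like(b) for b in self.biases
        ]
        self._adam_t = 0

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            x = np.maximum(x @ w + b, 0.0)
        return x @ self.weights[-1] + self.biases[-1]

    def train_step(self, x, y, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        """One Adam step on MAE loss; returns the batch loss."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        acts = [x]
        z = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            z = np.maximum(z @ w + b, 0.0)
            acts.append(z)
        pred = z @ self.weights[-1] + self.biases[-1]
        diff = pred - y
        loss = float(np.mean(np.abs(diff)))

        grad_out = np.sign(diff) / diff.size
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = grad_out
        for li in range(len(self.weights) - 1, -1, -1):
            grads_w[li] = acts[li].T @ delta
            grads_b[li] = delta.sum(axis=0)
            if li > 0:
                delta = (delta @ self.weights[li].T) * (acts[li] > 0)

        self._adam_t += 1
        t = self._adam_t
        params = self.weights + self.biases
        grads = grads_w + grads_b
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    # -- serialization -----------------------------------------------------

    def state_dict(self) -> dict:
        out = {"layer_sizes": np.array(self.layer_sizes)}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"w{i}"] = w
            out[f"b{i}"] = b
        return out

    @classmethod
    def from_state_dict(cls, state: dict) -> "AdamMLP":
        net = cls(list(np.asarray(state["layer_sizes"]).astype(int)))
        for i in range(len(net.weights)):
            net.weights[i] = np.asarray(state[f"w{i}"], dtype=float)
            net.biases[i] = np.asarray(state[f"b{i}"], dtype=float)
        return net
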