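"""A small 1-D convolutional network, implemented directly on NumPy.

The classifier is deliberately minimal: a stack of same-padded 1-D
convolutions with ReLU, a global max-pool over sequence positions, and a
single sigmoid output unit, trained with Adam on binary cross-entropy.
Inputs are one-hot encoded sequences of fixed length L with C channels.

Everything is float64 and fully deterministic given the seed, so trained
models serialise and round-trip bit-exactly.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, L, C) -> (N, L, k*C) patches under same (zero) padding."""
    n, length, c = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    cols = np.empty((n, length, k, c), dtype=x.dtype)
    for j in range(k):
        cols[:, :, j, :] = xp[:, j : j + length, :]
    return cols.reshape(n, length, k * c)


def _col2im(dcols: np.ndarray, k: int, length: int, c: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: accumulate patch gradients back."""
    n = dcols.shape[0]
    pad = k // 2
    d = dcols.reshape(n, length, k, c)
    dxp = np.zeros((n, length + 2 * pad, c), dtype=dcols.dtype)
    for j in range(k):
        dxp[:, j : j + length, :] += d[:, :, j, :]
    return dxp[:, pad : pad + length, :]


class SmallCnn:
    """Three-conv-layer binary classifier over one-hot sequence matrices."""

    def __init__(
        self,
        input_len: int,
        input_channels: int,
        channels: tuple[int, ...] = (32, 64, 128),
        kernel: int = 3,
        seed: int = 0,
    ):
        self.input_len = input_len
        self.input_channels = input_channels
        self.channels = tuple(channels)
        self.kernel = kernel
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = input_channels
        for i, c_out in enumerate(self.channels):
            fan_in = kernel * c_in
            self.params[f"W{i}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out))
            self.params[f"b{i}"] = np.zeros(c_out)
            c_in = c_out
        self.params["Wd"] = rng.normal(0.0, np.sqrt(2.0 / c_in), (c_in, 1))
        self.params["bd"] = np.zeros(1)

    # -- forward / backward ------------------------------------------------

    def _forward(self, x: np.ndarray, cache: bool = False):
        caches = []
        h = x
        for i in range(len(self.channels)):
            cols = _im2col(h, self.kernel)
            z = cols @ self.params[f"W{i}"] + self.params[f"b{i}"]
            a = np.maximum(z, 0.0)
            if cache:
                caches.append((cols, z, h.shape[2]))
            h = a
        pooled = h.max(axis=1)
        if cache:
            argmax = h.argmax(axis=1)
            caches.append((argmax, h.shape))
        logit = pooled @ self.params["Wd"] + self.params["bd"]
        p = 1.0 / (1.0 + np.exp(-logit[:, 0]))
        if cache:
            return p, pooled, caches
        return p

    def _backward(self, x, y, p, pooled, caches) -> dict[str, np.ndarray]:
        n = x.shape[0]
        grads: dict[str, np.ndarray] = {}
        dlogit = (p - y)[:, None] / n  # BCE + sigmoid
        grads["Wd"] = pooled.T @ dlogit
        grads["bd"] = dlogit.sum(axis=0)
        dpooled = dlogit @ self.params["Wd"].T

        argmax, h_shape = caches[-1]
        dh = np.zeros(h_shape)
        nn, cc = np.meshgrid(np.arange(h_shape[0]), np.arange(h_shape[2]), indexing="ij")
        dh[nn, argmax, cc] = dpooled

        for i in range(len(self.channels) - 1, -1, -1):
            cols, z, c_in = caches[i]
            dz = dh * (z > 0)
            dz2 = dz.reshape(-1, dz.shape[2])
            grads[f"W{i}"] = cols.reshape(-1, cols.shape[2]).T @ dz2
            grads[f"b{i}"] = dz2.sum(axis=0)
            if i > 0:
                dcols = dz @ self.params[f"W{i}"].T
                dh = _col2im(dcols, self.kernel, self.input_len, c_in)
        return grads

    # -- training ----------------------------------------------------------

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 60,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ) -> dict[str, list[float]]:
        """Adam / binary cross-entropy; returns per-epoch loss and accuracy
        (averaged over minibatches)."""
        rng = np.random.default_rng(seed)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(w) for k, w in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        history: dict[str, list[float]] = {"loss": [], "accuracy": []}
        n = x.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            losses, accs = [], []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y[idx]
                p, pooled, caches = self._forward(xb, cache=True)
                pc = np.clip(p, 1e-12, 1 - 1e-12)
                losses.append(float(-(yb * np.log(pc) + (1 - yb) * np.log(1 - pc)).mean()))
                accs.append(float(((p > 0.5) == yb).mean()))
                grads = self._backward(xb, yb, p, pooled, caches)
                t += 1
                for k, g in grads.items():
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g * g
                    mhat = m[k] / (1 - beta1**t)
                    vhat = v[k] / (1 - beta2**t)
                    self.params[k] -= learning_rate * mhat / (np.sqrt(vhat) + eps)
            history["loss"].append(float(np.mean(losses)))
            history["accuracy"].append(float(np.mean(accs)))
        return history

    def predict_proba(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        out = np.empty(x.shape[0])
        for start in range(0, x.shape[0], batch_size):
            out[start : start + batch_size] = self._forward(x[start : start + batch_size])
        return out

    # -- (de)serialisation -------------------------------------------------

    def state(self) -> dict:
        return {
            "input_len": self.input_len,
            "input_channels": self.input_channels,
            "channels": self.channels,
            "kernel": self.kernel,
            "seed": self.seed,
        }

    @classmethod
    def from_state(cls, state: dict, params: dict[str, np.ndarray]) -> "SmallCnn":
        net = cls(
            input_len=int(state["input_len"]),
            input_channels=int(state["input_channels"]),
            channels=tuple(int(c) for c in state["channels"]),
            kernel=int(state["kernel"]),
            seed=int(state["seed"]),
        )
        net.params = {k: np.array(v) for k, v in params.items()}
        return net
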