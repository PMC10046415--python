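"""Minimal CNN engine in numpy: 3x3 same-padding convolutions, dense layers,
softmax cross-entropy, and the Adam optimizer.

The networks in this package are tiny (inputs are 5x5 or 6x6 two-channel
ROI images, ~50k parameters), so an im2col/matmul implementation on the CPU
is entirely adequate; forward+backward of a 16-sample batch takes well under
a millisecond.  Everything is deterministic given the initialization
generator.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["SmallCnn", "Adam", "softmax", "categorical_cross_entropy"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def categorical_cross_entropy(
    probs: np.ndarray, onehot: np.ndarray, per_class_normalized: bool = True
) -> float:
    """Mean categorical cross-entropy, -1/(N*Nc) sum_n sum_c C log C_hat.

    ``per_class_normalized=False`` drops the 1/Nc factor (the conventional
    per-sample mean); the gradient direction is identical up to scale.
    Predicted probabilities are clipped at 1e-12.
    """
    n, nc = onehot.shape
    scale = n * nc if per_class_normalized else n
    p = np.clip(probs, 1e-12, None)
    return float(-(onehot * np.log(p)).sum() / scale)


def _im2col(x_pad: np.ndarray, h: int, w: int) -> np.ndarray:
    """Gather 3x3 patches: (B, Hp, Wp, C) -> (B, h, w, 9*C)."""
    cols = [x_pad[:, di : di + h, dj : dj + w, :] for di in range(3) for dj in range(3)]
    return np.concatenate(cols, axis=-1)


class SmallCnn:
    """conv(3x3, K1) -> ReLU -> conv(3x3, K2) -> ReLU -> dense(D) -> ReLU -> dense(Nc).

    Same padding keeps the spatial size, so the flattened feature length is
    H*W*K2.  He-uniform initialization; weights live in ``self.params``.
    """

    def __init__(
        self,
        input_shape: tuple[int, int, int],
        n_classes: int,
        conv_channels: tuple[int, int] = (16, 32),
        dense_units: int = 64,
        rng: np.random.Generator | None = None,
    ):
        h, w, c = input_shape
        if h < 3 or w < 3:
            raise ValueError(f"input spatial size {h}x{w} too small for 3x3 kernels")
        if n_classes < 2:
            raise ValueError("need at least two classes")
        self.input_shape = (h, w, c)
        self.n_classes = n_classes
        k1, k2 = conv_channels
        rng = rng or np.random.default_rng()

        def he(shape, fan_in):
            lim = math.sqrt(6.0 / fan_in)
            return rng.uniform(-lim, lim, size=shape)

        flat = h * w * k2
        self.params: dict[str, np.ndarray] = {
            "Wc1": he((9 * c, k1), 9 * c),
            "bc1": np.zeros(k1),
            "Wc2": he((9 * k1, k2), 9 * k1),
            "bc2": np.zeros(k2),
            "Wd1": he((flat, dense_units), flat),
            "bd1": np.zeros(dense_units),
            "Wd2": he((dense_units, n_classes), dense_units),
            "bd2": np.zeros(n_classes),
        }

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def _conv(self, x: np.ndarray, w_key: str, b_key: str) -> tuple[np.ndarray, np.ndarray]:
        b, h, w, _ = x.shape
        x_pad = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = _im2col(x_pad, h, w)
        out = cols @ self.params[w_key] + self.params[b_key]
        return out, cols

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Logits for a batch (B, H, W, C); optionally the backprop cache."""
        z1, cols1 = self._conv(x, "Wc1", "bc1")
        a1 = np.maximum(z1, 0.0)
        z2, cols2 = self._conv(a1, "Wc2", "bc2")
        a2 = np.maximum(z2, 0.0)
        flat = a2.reshape(a2.shape[0], -1)
        z3 = flat @ self.params["Wd1"] + self.params["bd1"]
        a3 = np.maximum(z3, 0.0)
        logits = a3 @ self.params["Wd2"] + self.params["bd2"]
        if not want_cache:
            return logits
        return logits, (x, cols1, z1, a1, cols2, z2, a2, flat, z3, a3)

    def backward(self, cache, d_logits: np.ndarray) -> dict[str, np.ndarray]:
        x, cols1, z1, a1, cols2, z2, a2, flat, z3, a3 = cache
        g: dict[str, np.ndarray] = {}
        g["Wd2"] = a3.T @ d_logits
        g["bd2"] = d_logits.sum(axis=0)
        da3 = d_logits @ self.params["Wd2"].T
        dz3 = da3 * (z3 > 0)
        g["Wd1"] = flat.T @ dz3
        g["bd1"] = dz3.sum(axis=0)
        dflat = dz3 @ self.params["Wd1"].T
        da2 = dflat.reshape(a2.shape)
        dz2 = da2 * (z2 > 0)
        g["Wc2"] = cols2.reshape(-1, cols2.shape[-1]).T @ dz2.reshape(-1, dz2.shape[-1])
        g["bc2"] = dz2.sum(axis=(0, 1, 2))
        dcols2 = dz2 @ self.params["Wc2"].T
        da1 = self._col2im(dcols2, a1.shape)
        dz1 = da1 * (z1 > 0)
        g["Wc1"] = cols1.reshape(-1, cols1.shape[-1]).T @ dz1.reshape(-1, dz1.shape[-1])
        g["bc1"] = dz1.sum(axis=(0, 1, 2))
        return g

    @staticmethod
    def _col2im(dcols: np.ndarray, x_shape: tuple) -> np.ndarray:
        b, h, w, c = x_shape
        dx_pad = np.zeros((b, h + 2, w + 2, c))
        pieces = np.split(dcols, 9, axis=-1)
        for k, (di, dj) in enumerate((i, j) for i in range(3) for j in range(3)):
            dx_pad[:, di : di + h, dj : dj + w, :] += pieces[k]
        return dx_pad[:, 1 : 1 + h, 1 : 1 + w, :]

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8) over a param dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, gr in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * gr
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * gr**2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
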