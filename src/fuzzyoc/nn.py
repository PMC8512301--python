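"""Minimal numpy neural-network layers with manual backpropagation.

Just enough machinery for the framework's backbones and linear softmax heads:
strided 3x3 convolutions (im2col), ReLU, global average pooling, fully
connected layers and an Adam optimizer.  Data layout is NHWC float32, which
lets the im2col view and its inverse run without a single transpose.

Every layer caches what its backward pass needs during ``forward`` and
returns the input gradient from ``backward``; parameters and their gradients
are exposed through ``params()`` so the optimizer can step them in place.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_backward",
]


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[dict]:
        """List of {'value': array, 'grad': array} entries, stepped in place."""
        return []


class Conv2d(Layer):
    """3x3 (or kxk) convolution with 'same' padding and integer stride."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 2,
        rng: np.random.Generator | None = None,
        input_grad: bool = True,
    ) -> None:
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = in_channels * k * k
        # He initialization, appropriate for the ReLU nonlinearity
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, k, k)).astype(
            np.float32
        )
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.stride = stride
        self.pad = k // 2
        self.k = k
        self.input_grad = input_grad  # first layer can skip the dx pass
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x is NHWC; the layout avoids any transpose in forward or backward.

        im2col is built with k*k strided block copies (fast memcpy paths)
        instead of reshaping a 6-d window view, which numpy copies with a
        slow generic gather.
        """
        s, k, p = self.stride, self.k, self.pad
        n, h, w, c = x.shape
        xp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        xp[:, p : p + h, p : p + w] = x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols6 = np.empty((n, ho, wo, k, k, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                cols6[:, :, :, i, j, :] = xp[:, i : i + ho * s : s, j : j + wo * s : s]
        cols = cols6.reshape(n * ho * wo, k * k * c)
        # weight in (k, k, C, O) flat layout matching the column order
        Wt = np.ascontiguousarray(
            self.W.transpose(2, 3, 1, 0).reshape(k * k * c, -1)
        )
        out = cols @ Wt + self.b
        self._cache = (cols, x.shape, (ho, wo))
        return out.reshape(n, ho, wo, -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape, (ho, wo) = self._cache
        n, h, w, c = x_shape
        s, k, p = self.stride, self.k, self.pad
        g = grad.reshape(n * ho * wo, -1)
        dWt = cols.T @ g  # (k*k*C, O)
        self.dW += dWt.reshape(k, k, c, -1).transpose(3, 2, 0, 1)
        self.db += g.sum(axis=0)
        if not self.input_grad:
            return None
        Wt = self.W.transpose(2, 3, 1, 0).reshape(k * k * c, -1)
        dcols = (g @ Wt.T).reshape(n, ho, wo, k, k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        # scatter-add the k*k column slices back into the padded input
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + ho * s : s, j : j + wo * s : s, :] += dcols[
                    :, :, :, i, j, :
                ]
        return dxp[:, p : p + h, p : p + w, :]

    def params(self) -> list[dict]:
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        # x is conv output, freshly allocated: safe to clip in place
        self._mask = x > 0
        np.multiply(x, self._mask, out=x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        np.multiply(grad, self._mask, out=grad)
        return grad


class GlobalAvgPool(Layer):
    """(N, H, W, C) -> (N, C) by spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), self._shape).astype(
            np.float32, copy=False
        )


class Flatten(Layer):
    """(N, H, W, C) -> (N, H*W*C); keeps the spatial layout in the features."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(
        self, in_features: int, out_features: int, rng: np.random.Generator | None = None
    ) -> None:
        rng = rng or np.random.default_rng()
        bound = np.sqrt(1.0 / in_features)
        self.W = rng.uniform(-bound, bound, (out_features, in_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW += grad.T @ self._x
        self.db += grad.sum(axis=0)
        return grad @ self.W

    def params(self) -> list[dict]:
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[dict]:
        return [p for layer in self.layers for p in layer.params()]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_backward(probs: np.ndarray, grad_probs: np.ndarray) -> np.ndarray:
    """Gradient wrt logits given the gradient wrt softmax outputs."""
    dot = (grad_probs * probs).sum(axis=-1, keepdims=True)
    return probs * (grad_probs - dot)


def zero_grads(layer: Layer) -> None:
    for p in layer.params():
        p["grad"][...] = 0.0


class Adam:
    """Adam optimizer over a fixed list of parameter dicts."""

    def __init__(
        self,
        params: list[dict],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p["value"]) for p in params]
        self.v = [np.zeros_like(p["value"]) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p["grad"]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p["value"] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
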