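"""Minimal feed-forward neural-network core on numpy.

Layers cache what their backward pass needs during ``forward`` and return
input gradients from ``backward``; parameters and their gradients live in
``params`` / ``grads`` dicts keyed by name.  Convolutions are implemented
as im2col + BLAS matmul.  Everything is float32 and deterministic given a
seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

from ..errors import InvalidArgumentError


class Layer:
    """Base layer: parameter-free identity."""

    trainable = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


def he_init(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """3×3 (or k×k) stride-1 'same' convolution via im2col."""

    def __init__(self, rng: np.random.Generator, in_ch: int, out_ch: int,
                 ksize: int = 3) -> None:
        super().__init__()
        if ksize % 2 != 1:
            raise InvalidArgumentError("kernel size must be odd for same padding")
        self.in_ch, self.out_ch, self.ksize = in_ch, out_ch, ksize
        self.pad = ksize // 2
        fan_in = in_ch * ksize * ksize
        self.params = {
            "W": he_init(rng, (out_ch, fan_in), fan_in),
            "b": np.zeros(out_ch, dtype=np.float32),
        }
        self.zero_grads()

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.ksize, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n, h, w, c, k, k) -> (n*h*w, c*k*k)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        n, c, h, w = x.shape
        cols = self._im2col(x)
        self.cols = cols
        out = cols @ self.params["W"].T + self.params["b"]
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self.x_shape
        k, p = self.ksize, self.pad
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.grads["W"] += (g.T @ self.cols).astype(np.float32)
        self.grads["b"] += g.sum(axis=0).astype(np.float32)
        gcols = (g @ self.params["W"]).reshape(n, h, w, c, k, k)
        gpad = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                gpad[:, :, i:i + h, j:j + w] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return gpad[:, :, p:p + h, p:p + w]


class MaxPool2d(Layer):
    """2×2 max pooling with stride 2; trailing odd row/column is dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        hh, ww = h // 2, w // 2
        x = x[:, :, :2 * hh, :2 * ww]
        self.x_shape = x.shape
        tiles = x.reshape(n, c, hh, 2, ww, 2).transpose(0, 1, 2, 4, 3, 5)
        tiles = tiles.reshape(n, c, hh, ww, 4)
        self.arg = tiles.argmax(axis=-1)
        return np.take_along_axis(tiles, self.arg[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self.x_shape
        hh, ww = h // 2, w // 2
        gtiles = np.zeros((n, c, hh, ww, 4), dtype=np.float32)
        np.put_along_axis(gtiles, self.arg[..., None], grad[..., None], axis=-1)
        g = gtiles.reshape(n, c, hh, ww, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return g.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    """Average over the spatial dimensions: (n, c, h, w) → (n, c)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self.x_shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w),
                               self.x_shape).astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self.mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self.x_shape)


class Linear(Layer):
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int) -> None:
        super().__init__()
        self.params = {
            "W": he_init(rng, (in_dim, out_dim), in_dim),
            "b": np.zeros(out_dim, dtype=np.float32),
        }
        self.zero_grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] += (self.x.T @ grad).astype(np.float32)
        self.grads["b"] += grad.sum(axis=0).astype(np.float32)
        return grad @ self.params["W"].T


class GradientReversal(Layer):
    """Identity in the forward pass; scales gradients by −λ in the backward.

    The adversarial alignment trick: a domain discriminator trained through
    this layer pushes the feature extractor toward domain-invariant
    features.
    """

    def __init__(self, lambda_: float = 1.0) -> None:
        super().__init__()
        if not np.isfinite(lambda_):
            raise InvalidArgumentError("lambda_ must be finite")
        self.lambda_ = float(lambda_)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return -self.lambda_ * grad


def grad_reverse(features: np.ndarray, lambda_: float = 1.0) -> np.ndarray:
    """Functional view of :class:`GradientReversal`: forward identity.

    In this explicit-backprop framework the reversed-gradient contract is
    carried by the layer object; this helper validates λ and returns the
    features unchanged, matching the layer's forward pass.
    """
    GradientReversal(lambda_)  # validates lambda_
    return np.asarray(features)


class Sequential:
    """A forward/backward chain of layers."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.log(probs[np.arange(n), labels] + 1e-12).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


class SGD:
    """Stochastic gradient descent with classical momentum.

    Steps only the layers listed as trainable; learning rate is decayed
    ×0.1 at 60% and 80% of the scheduled epochs by the training loop.
    """

    def __init__(self, modules: list[Sequential], lr: float = 0.01,
                 momentum: float = 0.9) -> None:
        self.modules = modules
        self.lr = lr
        self.momentum = momentum
        self.velocity: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        for module in self.modules:
            for layer, name in module.parameters():
                if not layer.trainable:
                    continue
                key = (id(layer), name)
                v = self.velocity.get(key)
                if v is None:
                    v = np.zeros_like(layer.params[name])
                v = self.momentum * v - self.lr * layer.grads[name]
                self.velocity[key] = v
                layer.params[name] += v

    def zero_grads(self) -> None:
        for module in self.modules:
            module.zero_grads()
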