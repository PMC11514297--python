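"""Minimal convolutional-network building blocks on numpy.

Only what the dilated-convolution spectral networks need: valid (unpadded)
dilated 2D convolutions, ReLU, and a sequential container with explicit
forward/backward passes.  Arrays are laid out ``(batch, channels, rows,
cols)``; gradients are accumulated per layer into ``grads`` mirroring
``params``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "Sequential"]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Valid dilated 2D convolution (cross-correlation) with bias.

    Kernel taps are applied as strided slices, so the cost is one matrix
    contraction per tap — efficient for the small (2x2, 2x4) kernels used
    here regardless of dilation.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int], dilation: tuple[int, int] = (1, 1),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        scale = np.sqrt(2.0 / fan_in)  # He initialization (ReLU layers)
        self.kernel = (kh, kw)
        self.dilation = tuple(dilation)
        self.weight = rng.normal(0.0, scale, (out_channels, in_channels, kh, kw))
        self.bias = np.zeros(out_channels)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    def out_extent(self, h: int, w: int) -> tuple[int, int]:
        kh, kw = self.kernel
        dh, dw = self.dilation
        oh, ow = h - (kh - 1) * dh, w - (kw - 1) * dw
        if oh < 1 or ow < 1:
            raise ValueError(
                f"input extent ({h}, {w}) smaller than the receptive field of "
                f"kernel {self.kernel} with dilation {self.dilation}")
        return oh, ow

    def forward(self, x: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel
        dh, dw = self.dilation
        oh, ow = self.out_extent(x.shape[2], x.shape[3])
        self._x = x
        out = np.zeros((x.shape[0], self.weight.shape[0], oh, ow))
        for a in range(kh):
            for b in range(kw):
                patch = x[:, :, a * dh:a * dh + oh, b * dw:b * dw + ow]
                out += np.einsum("oc,bchw->bohw", self.weight[:, :, a, b],
                                 patch, optimize=True)
        return out + self.bias[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        kh, kw = self.kernel
        dh, dw = self.dilation
        oh, ow = grad.shape[2], grad.shape[3]
        dx = np.zeros_like(x)
        dW, db = self.grads
        db += grad.sum(axis=(0, 2, 3))
        for a in range(kh):
            for b in range(kw):
                patch = x[:, :, a * dh:a * dh + oh, b * dw:b * dw + ow]
                dW[:, :, a, b] += np.einsum("bohw,bchw->oc", grad, patch,
                                            optimize=True)
                dx[:, :, a * dh:a * dh + oh, b * dw:b * dw + ow] += np.einsum(
                    "oc,bohw->bchw", self.weight[:, :, a, b], grad,
                    optimize=True)
        return dx


class ReLU(Layer):
    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def zero_grads(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w
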