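"""Compact numpy neural-network engine.

Implements exactly what the classification backbones need — 3x3 same-padding
convolutions, ReLU, 2x2 max pooling, dense layers, softmax cross-entropy and
Adam — with explicit backward passes.  The engine exposes the two gradient
taps the rest of the package relies on: the flattened post-convolution
feature vector (for the MMD loss and t-SNE embeddings) and the final
convolutional activations (for Grad-CAM).

Layout is NCHW throughout; convolutions run via im2col so the heavy lifting
is matrix multiplication.  All randomness flows through an explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    def params(self):
        return []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (configurable) convolution with same padding, stride 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((c_out, fan_in))
                  * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        self._cols = np.ascontiguousarray(cols, dtype=DTYPE)
        self._shape = (n, c, h, w)
        out = self._cols @ self.W.T + self.b
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, c, h, w = self._shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        dflat = np.ascontiguousarray(dflat, dtype=DTYPE)
        self.dW[:] = dflat.T @ self._cols
        self.db[:] = dflat.sum(axis=0)
        dcols = dflat @ self.W
        dcols = dcols.reshape(n, h, w, c, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(dr, self._idx[..., None], dout[..., None], axis=-1)
        dr = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(n, c, h, w)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((n_in, n_out))
                  * np.sqrt(2.0 / n_in)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[:] = self._x.T @ dout
        self.db[:] = dout.sum(axis=0)
        return dout @ self.W.T


class SequentialNet:
    """Trunk (convolutions) -> neck (pool+flatten) -> classifier (dense head).

    The trunk output is the final convolutional activation map (Grad-CAM
    tap); the neck output is the flattened feature vector (MMD / t-SNE tap).
    """

    def __init__(self, trunk, neck, classifier):
        self.trunk = list(trunk)
        self.neck = list(neck)
        self.classifier = list(classifier)
        self.conv_act = None
        self.features = None

    # -- forward -----------------------------------------------------------
    def forward_features(self, x):
        h = np.ascontiguousarray(x, dtype=DTYPE)
        for layer in self.trunk:
            h = layer.forward(h)
        self.conv_act = h
        for layer in self.neck:
            h = layer.forward(h)
        self.features = h
        return h

    def forward(self, x):
        h = self.forward_features(x)
        for layer in self.classifier:
            h = layer.forward(h)
        return h

    # -- backward ----------------------------------------------------------
    def backward_head(self, dlogits):
        """Backprop through classifier and neck only; returns the gradient at
        the final convolutional activations (the Grad-CAM gradient)."""
        d = np.ascontiguousarray(dlogits, dtype=DTYPE)
        for layer in reversed(self.classifier):
            d = layer.backward(d)
        for layer in reversed(self.neck):
            d = layer.backward(d)
        return d

    def backward(self, dlogits, dfeatures_extra=None):
        """Full backprop.  ``dfeatures_extra`` is added at the flattened
        feature tap (used to inject the MMD gradient)."""
        d = np.ascontiguousarray(dlogits, dtype=DTYPE)
        for layer in reversed(self.classifier):
            d = layer.backward(d)
        if dfeatures_extra is not None:
            d = d + np.asarray(dfeatures_extra, dtype=DTYPE)
        for layer in reversed(self.neck):
            d = layer.backward(d)
        for layer in reversed(self.trunk):
            d = layer.backward(d)
        return d

    def backward_from_features(self, dfeatures):
        d = np.ascontiguousarray(dfeatures, dtype=DTYPE)
        for layer in reversed(self.neck):
            d = layer.backward(d)
        for layer in reversed(self.trunk):
            d = layer.backward(d)
        return d

    # -- parameters --------------------------------------------------------
    def layers(self):
        return self.trunk + self.neck + self.classifier

    def params(self):
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def get_weights(self):
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights):
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for (p, _), w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch {p.shape} vs {w.shape}")
            p[:] = w


class Adam:
    def __init__(self, net: SequentialNet, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.params()]
        self.v = [np.zeros_like(p) for p, _ in net.params()]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.net.params(), self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits, labels):
    """Mean cross-entropy and the gradient w.r.t. the logits."""
    n = len(labels)
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n), labels].mean()
    probs = np.exp(logp)
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n
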