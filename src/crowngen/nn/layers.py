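"""Trainable layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during forward, exposes
``parameters()`` as a list of (value, grad) array pairs (grads accumulate
until ``zero_grad``), and works in float32. ``train=False`` switches batch
norm to its running statistics and drops caches where possible.
"""

from __future__ import annotations

import numpy as np

from . import ops


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self):
        return []

    def zero_grad(self) -> None:
        for _, g in self.parameters():
            g[...] = 0.0

    def state(self) -> dict:
        return {f"p{i}": p for i, (p, _) in enumerate(self.parameters())}

    def load_state(self, st: dict) -> None:
        for i, (p, _) in enumerate(self.parameters()):
            p[...] = st[f"p{i}"]


class Conv2D(Layer):
    """k x k cross-correlation with stride/dilation and 'same'-style padding."""

    def __init__(self, in_ch, out_ch, k, stride=1, dilation=1, pad="same",
                 bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        if pad == "same":
            pad = ((k - 1) * dilation) // 2
        self.stride, self.dilation, self.pad = stride, dilation, pad
        fan_in = in_ch * k * k
        scale = np.sqrt(2.0 / fan_in)
        self.w = (rng.standard_normal((out_ch, in_ch, k, k)) * scale).astype(np.float32)
        self.gw = np.zeros_like(self.w)
        self.b = np.zeros(out_ch, dtype=np.float32) if bias else None
        self.gb = np.zeros_like(self.b) if bias else None
        self._cache = None

    def forward(self, x, train=True):
        y, cols = ops.conv2d(
            x, self.w, self.b, self.stride, self.dilation, self.pad, return_cols=True
        )
        self._cache = (cols, x.shape[2:]) if train else None
        return y

    def backward(self, dy):
        cols, x_hw = self._cache
        self.gw += ops.conv2d_weight_grad(dy, cols, self.w.shape)
        if self.b is not None:
            self.gb += dy.sum(axis=(0, 2, 3))
        return ops.conv2d_input_grad(
            dy, self.w, x_hw, self.stride, self.dilation, self.pad
        )

    def parameters(self):
        out = [(self.w, self.gw)]
        if self.b is not None:
            out.append((self.b, self.gb))
        return out


class ConvTranspose2D(Layer):
    """Learned upsampling; k=4, stride=2, pad=1 exactly doubles H and W."""

    def __init__(self, in_ch, out_ch, k=4, stride=2, pad=1, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        self.stride, self.pad = stride, pad
        fan_in = in_ch * k * k
        scale = np.sqrt(2.0 / fan_in)
        self.w = (rng.standard_normal((in_ch, out_ch, k, k)) * scale).astype(np.float32)
        self.gw = np.zeros_like(self.w)
        self.b = np.zeros(out_ch, dtype=np.float32) if bias else None
        self.gb = np.zeros_like(self.b) if bias else None
        self._cache = None

    def forward(self, x, train=True):
        y, cache = ops.conv_transpose2d(
            x, self.w, self.b, self.stride, self.pad, return_cache=True
        )
        self._cache = (cache[0], x.shape[2:]) if train else None
        return y

    def backward(self, dy):
        cols, x_hw = self._cache
        self.gw += ops.conv_transpose2d_weight_grad(dy, cols, self.w.shape)
        if self.b is not None:
            self.gb += dy.sum(axis=(0, 2, 3))
        return ops.conv_transpose2d_input_grad(dy, self.w, x_hw, self.stride, self.pad)

    def parameters(self):
        out = [(self.w, self.gw)]
        if self.b is not None:
            out.append((self.b, self.gb))
        return out


class BatchNorm2D(Layer):
    def __init__(self, ch, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(ch, dtype=np.float32)
        self.run_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.ggamma += (dy * xhat).sum(axis=(0, 2, 3))
        self.gbeta += dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        dxhat = dy * g
        # standard batch-norm backward over the (N, H, W) axes
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return dx.astype(np.float32)

    def parameters(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def state(self):
        st = super().state()
        st["run_mean"] = self.run_mean
        st["run_var"] = self.run_var
        return st

    def load_state(self, st):
        super().load_state(st)
        self.run_mean[...] = st["run_mean"]
        self.run_var[...] = st["run_var"]


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x, train=True):
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        self._y = y
        return y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_f, out_f, bias=True, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_f)
        self.w = (rng.standard_normal((in_f, out_f)) * scale).astype(np.float32)
        self.gw = np.zeros_like(self.w)
        self.b = np.zeros(out_f, dtype=np.float32) if bias else None
        self.gb = np.zeros_like(self.b) if bias else None

    def forward(self, x, train=True):
        self._x = x if train else None
        y = x @ self.w
        if self.b is not None:
            y = y + self.b
        return y

    def backward(self, dy):
        self.gw += self._x.T @ dy
        if self.b is not None:
            self.gb += dy.sum(axis=0)
        return dy @ self.w.T

    def parameters(self):
        out = [(self.w, self.gw)]
        if self.b is not None:
            out.append((self.b, self.gb))
        return out


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def state(self):
        return {
            f"layer{i}.{k}": v
            for i, layer in enumerate(self.layers)
            for k, v in layer.state().items()
        }

    def load_state(self, st):
        for i, layer in enumerate(self.layers):
            sub = {
                k.split(".", 1)[1]: v
                for k, v in st.items()
                if k.startswith(f"layer{i}.")
            }
            layer.load_state(sub)
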