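"""Minimal neural-network layers and the Adam optimizer.

Built on :mod:`moco4d._autodiff`.  Layers hold named parameters as Tensors
with ``requires_grad=True``; modules expose ``named_parameters()`` for
optimization and (de)serialization.  Initialization is fan-in scaled for
leaky-rectifier layers and fully deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

from . import _autodiff as ad

__all__ = ["Module", "Conv3d", "InstanceNorm3d", "ConvBlock", "ResBlock", "Adam"]


class Module:
    """Container tracking parameters and sub-modules by attribute name."""

    def __init__(self):
        self._params = {}
        self._modules = {}

    def __setattr__(self, name, value):
        if isinstance(value, ad.Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_parameters(self):
        return sum(p.data.size for p in self.parameters())

    def state_dict(self):
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state):
        for k, p in self.named_parameters():
            if k not in state:
                raise KeyError(f"missing parameter {k!r}")
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            p.data = arr.copy()


class Conv3d(Module):
    """3D convolution, stride 1, same zero padding.

    Fan-in initialization scaled for a leaky rectifier (slope 0.2) unless
    ``zero_init`` (identity-transform start for displacement heads).
    """

    def __init__(self, c_in, c_out, kernel=3, rng=None, zero_init=False,
                 slope=0.2, dtype=np.float32):
        super().__init__()
        if zero_init:
            w = np.zeros((c_out, c_in, kernel, kernel, kernel), dtype=dtype)
        else:
            rng = rng or np.random.default_rng(0)
            fan_in = c_in * kernel**3
            std = np.sqrt(2.0 / ((1.0 + slope**2) * fan_in))
            w = rng.normal(0.0, std,
                           size=(c_out, c_in, kernel, kernel, kernel)).astype(dtype)
        self.weight = ad.Tensor(w, requires_grad=True)
        self.bias = ad.Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x):
        return ad.conv3d(x, self.weight, self.bias)


class InstanceNorm3d(Module):
    def __init__(self, channels, dtype=np.float32):
        super().__init__()
        self.gamma = ad.Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = ad.Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)

    def __call__(self, x):
        return ad.instance_norm(x, self.gamma, self.beta)


class ConvBlock(Module):
    """conv -> instance norm -> leaky rectifier."""

    def __init__(self, c_in, c_out, rng, slope=0.2, dtype=np.float32):
        super().__init__()
        self.conv = Conv3d(c_in, c_out, rng=rng, slope=slope, dtype=dtype)
        self.norm = InstanceNorm3d(c_out, dtype=dtype)
        self.slope = slope

    def __call__(self, x):
        return ad.leaky_relu(self.norm(self.conv(x)), self.slope)


class ResBlock(Module):
    """Two conv/norm layers with an additive skip (1x1 projection if needed)."""

    def __init__(self, c_in, c_out, rng, slope=0.2, dtype=np.float32):
        super().__init__()
        self.conv1 = Conv3d(c_in, c_out, rng=rng, slope=slope, dtype=dtype)
        self.norm1 = InstanceNorm3d(c_out, dtype=dtype)
        self.conv2 = Conv3d(c_out, c_out, rng=rng, slope=slope, dtype=dtype)
        self.norm2 = InstanceNorm3d(c_out, dtype=dtype)
        self.slope = slope
        if c_in != c_out:
            self.proj = Conv3d(c_in, c_out, kernel=1, rng=rng, slope=slope,
                               dtype=dtype)
        else:
            self.proj = None

    def __call__(self, x):
        h = ad.leaky_relu(self.norm1(self.conv1(x)), self.slope)
        h = self.norm2(self.conv2(h))
        skip = self.proj(x) if self.proj is not None else x
        return ad.leaky_relu(h + skip, self.slope)


class Adam:
    """Adam optimizer; ``step`` consumes and clears accumulated gradients."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.grad = None

    def zero_grad(self):
        for p in self.params:
            p.grad = None
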