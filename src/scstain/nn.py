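"""Layers, parameter containers and the Adam optimizer.

Everything here is a thin composition of :mod:`scstain.autodiff`
primitives; backward passes come for free from the graph.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class holding named parameters (possibly nested)."""

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self):
        return sum(p.data.size for p in self.parameters())

    def state_dict(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data = np.asarray(s, dtype=np.float64).reshape(p.data.shape)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def _kaiming(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """3x3-style convolution with reflection (default) or zero padding."""

    def __init__(self, rng, c_in, c_out, k=3, pad_mode="reflect", zero_init=False):
        self.k = k
        self.pad_mode = pad_mode
        if zero_init:
            w = np.zeros((c_out, c_in, k, k))
        else:
            w = _kaiming(rng, (c_out, c_in, k, k), c_in * k * k)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x):
        p = self.k // 2
        if p:
            x = ad.pad2d(x, p, mode=self.pad_mode)
        return ad.conv2d(x, self.w, self.b)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization with learnable affine."""

    def __init__(self, c, eps=1e-5):
        self.eps = eps
        self.g = Tensor(np.ones((1, c, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1, 1)), requires_grad=True)

    def __call__(self, x):
        m = ad.tmean(x, axis=(2, 3), keepdims=True)
        xc = x - m
        var = ad.tmean(xc * xc, axis=(2, 3), keepdims=True)
        xn = xc * ad.power(var + self.eps, -0.5)
        return xn * self.g + self.beta


class Linear(Module):
    def __init__(self, rng, d_in, d_out):
        self.w = Tensor(_kaiming(rng, (d_in, d_out), d_in), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x):
        return ad.matmul(x, self.w) + self.b


class ResBlock(Module):
    def __init__(self, rng, c):
        self.conv1 = Conv2d(rng, c, c)
        self.norm1 = InstanceNorm2d(c)
        self.conv2 = Conv2d(rng, c, c)
        self.norm2 = InstanceNorm2d(c)

    def __call__(self, x):
        h = ad.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        return x + h


class Adam:
    def __init__(self, params, lr=2e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def l2_normalize(z, axis=-1, eps=1e-12):
    """Unit-normalize embeddings along ``axis`` (graph-tracked)."""
    n2 = ad.tsum(z * z, axis=axis, keepdims=True)
    return z * ad.power(n2 + eps, -0.5)
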