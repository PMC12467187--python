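"""Small neural-network layer library over the autodiff engine.

Modules own :class:`Parameter` tensors, expose ``named_parameters`` by
recursive attribute walk, and report multiply-accumulate counts for the
model-complexity metrics.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data, dtype=None):
        super().__init__(np.array(data, dtype=dtype), requires_grad=True)


class Module:
    """Base class: parameter discovery, grad reset, state (de)serialisation."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Conv2d(Module):
    """Dense conv with bias; He-normal init; 'same' padding when stride==1."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 padding: int | None = None, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        std = float(np.sqrt(2.0 / (cin * k * k)))
        self.w = Parameter(rng.normal(0.0, std, size=(cout, cin, k, k)), dtype=dtype)
        self.b = Parameter(np.zeros(cout), dtype=dtype)
        self.stride = stride
        self.padding = (k - 1) // 2 if padding is None else padding

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.conv2d(x, self.w, stride=self.stride, padding=self.padding)
        return ad.add(y, ad.reshape(self.b, (1, -1, 1, 1)))

    def macs(self, hin: int, win: int) -> tuple[int, int, int]:
        cout, cin, kh, kw = self.w.shape
        hout = (hin + 2 * self.padding - kh) // self.stride + 1
        wout = (win + 2 * self.padding - kw) // self.stride + 1
        return cout * cin * kh * kw * hout * wout + cout * hout * wout, hout, wout


class DWConv2d(Module):
    """Depthwise conv with bias, stride 1, 'same' padding, optional dilation."""

    def __init__(self, c: int, kh: int, kw: int, dilation: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 init: str = "delta"):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, 0.01, size=(c, kh, kw))
        if init == "delta":  # centred-delta + noise: near-identity at start
            w[:, (kh - 1) // 2, (kw - 1) // 2] += 1.0
        self.w = Parameter(w, dtype=dtype)
        self.b = Parameter(np.zeros(c), dtype=dtype)
        self.dilation = dilation
        self.padding = (dilation * (kh - 1) // 2, dilation * (kw - 1) // 2)

    def __call__(self, x: Tensor) -> Tensor:
        y = ad.dwconv2d(x, self.w, padding=self.padding,
                        dilation=(self.dilation, self.dilation))
        return ad.add(y, ad.reshape(self.b, (1, -1, 1, 1)))

    def macs(self, hin: int, win: int) -> tuple[int, int, int]:
        c, kh, kw = self.w.shape
        return c * kh * kw * hin * win + c * hin * win, hin, win


class GroupNorm2d(Module):
    """Group normalization over (B,C,H,W); neutralises activation-scale
    differences ahead of the prediction layers."""

    def __init__(self, c: int, groups: int = 8, eps: float = 1e-5, dtype=np.float32):
        while c % groups != 0:
            groups -= 1
        self.scale = Parameter(np.ones(c), dtype=dtype)
        self.shift = Parameter(np.zeros(c), dtype=dtype)
        self.groups = groups
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        g = self.groups
        xg = ad.reshape(x, (b, g, (c // g) * h * w))
        mu = ad.tmean(xg, axis=2, keepdims=True)
        cent = ad.sub(xg, mu)
        var = ad.tmean(ad.mul(cent, cent), axis=2, keepdims=True)
        inv = ad.exp(ad.mul(ad.log(ad.add(var, self.eps)), -0.5))
        xn = ad.reshape(ad.mul(cent, inv), (b, c, h, w))
        return ad.add(ad.mul(xn, ad.reshape(self.scale, (1, c, 1, 1))),
                      ad.reshape(self.shift, (1, c, 1, 1)))

    def macs(self, h: int, w: int) -> tuple[int, int, int]:
        c = self.scale.shape[0]
        return 2 * c * h * w, h, w


class AdamW:
    """Decoupled weight-decay Adam."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)
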