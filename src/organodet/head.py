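"""Interactive dual-perception detection head.

Two parallel enhancement branches run on every pyramid level:

* **LGPM** (large-kernel global perception): a chain of four depthwise
  convolutions — horizontal 1xK, vertical Kx1, then the same pair dilated
  with rate r=2 — approximates a large receptive field at separable cost
  (per-axis effective span 3K-2 taps). A 1x1 convolution and an activation
  turn the result into a spatial attention map A that gates the input
  elementwise: ``Z_lgpm = X * A``.

* **PCSM** (pooled channel-attention): global average pooling produces a
  per-channel descriptor, group-normalised, projected per-channel into
  query/key/value vectors, reshaped into ``h`` heads of width ``d = C/h``,
  run through scaled dot-product attention across heads, and squashed by a
  sigmoid into channel weights W that gate the input: ``Z_pcsm = X * W``.

The two branch outputs are fused by elementwise addition and fed to
parallel classification and box-regression branches producing maps of
``A*num_classes`` and ``A*4`` channels per location.

The activation producing the spatial map defaults to ``sigmoid`` (keeps the
gate in (0,1) and the gated output bounded by the input); ``silu`` is
selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv2d, DWConv2d, GroupNorm2d, Module, Parameter
from .types import ParameterError, ShapeError

CLASS_NAMES = ("cyst", "early_organoid", "late_organoid", "spheroid")

__all__ = [
    "LGPMParams",
    "PCSMParams",
    "HeadOutputs",
    "lgpm_forward",
    "lgpm_stages",
    "pcsm_forward",
    "pcsm_attention",
    "fuse",
    "idp_head_forward",
    "LGPM",
    "PCSM",
    "IDPHead",
    "PlainHead",
    "lgpm_param_count",
    "pcsm_param_count",
]


# ---------------------------------------------------------------------------
# parameter containers (functional interface)
# ---------------------------------------------------------------------------


@dataclass
class LGPMParams:
    """Weights of the spatial branch.

    The four depthwise banks are stored as (C, K) arrays: ``dw_h*`` slide
    along width, ``dw_v*`` along height; stages 2 use dilation ``r``.
    ``pointwise`` is (C, C) for the full channel fan or (1, C) for the
    broadcast variant.
    """

    dw_h1: np.ndarray
    dw_v1: np.ndarray
    dw_h2: np.ndarray
    dw_v2: np.ndarray
    bias_h1: np.ndarray
    bias_v1: np.ndarray
    bias_h2: np.ndarray
    bias_v2: np.ndarray
    pointwise: np.ndarray
    pointwise_bias: np.ndarray
    activation: str = "sigmoid"
    dilation: int = 2

    def __post_init__(self):
        if self.activation not in ("sigmoid", "silu"):
            raise ParameterError(f"unknown activation {self.activation!r}")
        if self.dilation != 2:
            raise ParameterError("dilation rate is fixed at 2")
        c, k = np.shape(self.dw_h1)
        if k % 2 == 0 or k < 3:
            raise ParameterError(f"kernel length K must be odd and >= 3, got {k}")
        for bank in (self.dw_v1, self.dw_h2, self.dw_v2):
            if np.shape(bank) != (c, k):
                raise ParameterError("all depthwise banks must share shape (C, K)")
        if np.shape(self.pointwise) not in ((c, c), (1, c)):
            raise ParameterError("pointwise must be (C, C) or (1, C)")

    @property
    def channels(self) -> int:
        return self.dw_h1.shape[0]

    @property
    def kernel_size(self) -> int:
        return self.dw_h1.shape[1]


@dataclass
class PCSMParams:
    """Weights of the channel branch (per-channel scale+shift projections)."""

    heads: int
    gn_groups: int
    gn_scale: np.ndarray
    gn_shift: np.ndarray
    q_scale: np.ndarray
    q_shift: np.ndarray
    k_scale: np.ndarray
    k_shift: np.ndarray
    v_scale: np.ndarray
    v_shift: np.ndarray
    eps: float = 1e-5

    def __post_init__(self):
        c = np.shape(self.gn_scale)[0]
        if c % self.heads != 0:
            raise ParameterError(f"C={c} not divisible by heads={self.heads}")
        if c % self.gn_groups != 0:
            raise ParameterError(f"C={c} not divisible by gn_groups={self.gn_groups}")
        if not self.eps > 0:
            raise ParameterError("eps must be positive")

    @property
    def channels(self) -> int:
        return self.gn_scale.shape[0]

    @property
    def head_dim(self) -> int:
        return self.channels // self.heads


@dataclass
class HeadOutputs:
    """Per-level prediction maps: cls (B, A*C_cls, H, W), reg (B, A*4, H, W)."""

    cls: np.ndarray
    reg: np.ndarray


# ---------------------------------------------------------------------------
# cores (operate on Tensors so the same code path trains and predicts)
# ---------------------------------------------------------------------------


def _activate(x: Tensor, kind: str) -> Tensor:
    return ad.sigmoid(x) if kind == "sigmoid" else ad.silu(x)


def _lgpm_core(x: Tensor, wh1, bh1, wv1, bv1, wh2, bh2, wv2, bv2,
               pw, pb, activation: str, dilation: int = 2):
    c = x.shape[1]
    k = wh1.shape[-1]
    # The input is zero-padded ONCE by the composite margin and the four
    # stages then run unpadded, so the chain is exactly one correlation
    # with the full-convolution-composed kernel (no cascade truncation at
    # the boundary). U1..U4 shrink back to the input's H x W by U4.
    margin = (1 + dilation) * (k - 1) // 2
    _, _, h, w = x.shape
    xp = ad.pad2d(x, margin)

    def _bias(t, bb):
        return ad.add(t, ad.reshape(bb, (1, -1, 1, 1)))

    u1 = _bias(ad.dwconv2d(xp, ad.reshape(wh1, (c, 1, k))), bh1)
    u2 = _bias(ad.dwconv2d(u1, ad.reshape(wv1, (c, k, 1))), bv1)
    u3 = _bias(ad.dwconv2d(u2, ad.reshape(wh2, (c, 1, k)),
                           dilation=(1, dilation)), bh2)
    u4 = _bias(ad.dwconv2d(u3, ad.reshape(wv2, (c, k, 1)),
                           dilation=(dilation, 1)), bv2)
    cout = pw.shape[0]
    a_pre = ad.conv2d(u4, ad.reshape(pw, (cout, c, 1, 1)))
    a_pre = _bias(a_pre, pb)
    a = _activate(a_pre, activation)
    z = ad.mul(x, a)  # broadcasts when the pointwise fan is C->1

    def _crop(u):
        _, _, uh, uw = u.shape
        oy, ox = (uh - h) // 2, (uw - w) // 2
        return u.data[:, :, oy: oy + h, ox: ox + w]

    return z, a, tuple(_crop(u) for u in (u1, u2, u3, u4))


def _sqrt(t: Tensor) -> Tensor:
    return ad.exp(ad.mul(ad.log(t), 0.5))


def _pcsm_core(x: Tensor, gn_scale, gn_shift, qs, qh, ks, kh, vs, vh,
               heads: int, gn_groups: int, eps: float):
    b, c, hh, ww = x.shape
    if hh * ww == 0:
        raise ShapeError("feature map has empty spatial extent")
    pooled = ad.tmean(x, axis=(2, 3))                     # (B, C) global average pool
    pg = ad.reshape(pooled, (b, gn_groups, c // gn_groups))
    mu = ad.tmean(pg, axis=2, keepdims=True)
    cent = ad.sub(pg, mu)
    var = ad.tmean(ad.mul(cent, cent), axis=2, keepdims=True)
    xn = ad.div(cent, _sqrt(ad.add(var, eps)))
    xn = ad.reshape(xn, (b, c))
    xn = ad.add(ad.mul(xn, gn_scale), gn_shift)
    q = ad.add(ad.mul(xn, qs), qh)
    kk = ad.add(ad.mul(xn, ks), kh)
    v = ad.add(ad.mul(xn, vs), vh)
    d = c // heads
    q2 = ad.reshape(q, (b, heads, d))
    k2 = ad.reshape(kk, (b, heads, d))
    v2 = ad.reshape(v, (b, heads, d))
    logits = ad.mul(ad.matmul(q2, ad.transpose(k2, (0, 2, 1))), 1.0 / float(np.sqrt(d)))
    att = ad.softmax(logits, axis=-1)                     # (B, h, h)
    o = ad.matmul(att, v2)                                # (B, h, d)
    # rearrange back to a (B, C, 1, 1) map; the spatial mean is then the
    # identity but is taken explicitly so the code mirrors the formula
    o_map = ad.reshape(o, (b, c, 1, 1))
    o_vec = ad.tmean(o_map, axis=(2, 3))
    w = ad.sigmoid(o_vec)                                 # (B, C)
    z = ad.mul(x, ad.reshape(w, (b, c, 1, 1)))
    return z, w, att


# ---------------------------------------------------------------------------
# functional interface (ndarray in / ndarray out)
# ---------------------------------------------------------------------------


def _check_featuremap(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 4:
        raise ShapeError(f"feature map must be 4-D (B,C,H,W), got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite values")
    return x


def lgpm_forward(x: np.ndarray, p: LGPMParams) -> tuple[np.ndarray, np.ndarray]:
    """Spatial branch: returns the gated feature Z and the attention map A."""
    x = _check_featuremap(x)
    if x.shape[1] != p.channels:
        raise ShapeError(f"input has {x.shape[1]} channels, params expect {p.channels}")
    t = Tensor(x)
    z, a, _ = _lgpm_core(
        t, Tensor(p.dw_h1), Tensor(p.bias_h1), Tensor(p.dw_v1), Tensor(p.bias_v1),
        Tensor(p.dw_h2), Tensor(p.bias_h2), Tensor(p.dw_v2), Tensor(p.bias_v2),
        Tensor(p.pointwise), Tensor(p.pointwise_bias), p.activation, p.dilation)
    return z.data, a.data


def lgpm_stages(x: np.ndarray, p: LGPMParams) -> tuple[np.ndarray, ...]:
    """The four depthwise stage outputs U1..U4 (for inspection and oracles)."""
    x = _check_featuremap(x)
    if x.shape[1] != p.channels:
        raise ShapeError(f"input has {x.shape[1]} channels, params expect {p.channels}")
    t = Tensor(x)
    _, _, us = _lgpm_core(
        t, Tensor(p.dw_h1), Tensor(p.bias_h1), Tensor(p.dw_v1), Tensor(p.bias_v1),
        Tensor(p.dw_h2), Tensor(p.bias_h2), Tensor(p.dw_v2), Tensor(p.bias_v2),
        Tensor(p.pointwise), Tensor(p.pointwise_bias), p.activation, p.dilation)
    return us


def pcsm_forward(x: np.ndarray, p: PCSMParams) -> tuple[np.ndarray, np.ndarray]:
    """Channel branch: returns the gated feature Z and channel weights W (B, C)."""
    x = _check_featuremap(x)
    if x.shape[1] != p.channels:
        raise ShapeError(f"input has {x.shape[1]} channels, params expect {p.channels}")
    z, w, _ = _pcsm_core(Tensor(x), Tensor(p.gn_scale), Tensor(p.gn_shift),
                         Tensor(p.q_scale), Tensor(p.q_shift), Tensor(p.k_scale),
                         Tensor(p.k_shift), Tensor(p.v_scale), Tensor(p.v_shift),
                         p.heads, p.gn_groups, p.eps)
    return z.data, w.data


def pcsm_attention(x: np.ndarray, p: PCSMParams) -> np.ndarray:
    """The (B, h, h) head-attention matrix A1 (rows sum to one)."""
    x = _check_featuremap(x)
    _, _, att = _pcsm_core(Tensor(x), Tensor(p.gn_scale), Tensor(p.gn_shift),
                           Tensor(p.q_scale), Tensor(p.q_shift), Tensor(p.k_scale),
                           Tensor(p.k_shift), Tensor(p.v_scale), Tensor(p.v_shift),
                           p.heads, p.gn_groups, p.eps)
    return att.data


def fuse(z_lgpm: np.ndarray, z_pcsm: np.ndarray) -> np.ndarray:
    """Elementwise additive fusion of the two branch outputs."""
    a, b = np.asarray(z_lgpm), np.asarray(z_pcsm)
    if a.shape != b.shape:
        raise ShapeError(f"fuse shape mismatch: {a.shape} vs {b.shape}")
    return a + b


# ---------------------------------------------------------------------------
# trainable modules
# ---------------------------------------------------------------------------


class LGPM(Module):
    """Trainable spatial branch; near-identity at init (centred-delta kernels)."""

    def __init__(self, c: int, kernel_size: int = 11, activation: str = "sigmoid",
                 pointwise_fan: str = "full", rng: np.random.Generator | None = None,
                 dtype=np.float32):
        if kernel_size % 2 == 0 or kernel_size < 3:
            raise ParameterError(f"kernel_size must be odd and >= 3, got {kernel_size}")
        if activation not in ("sigmoid", "silu"):
            raise ParameterError(f"unknown activation {activation!r}")
        rng = rng or np.random.default_rng(0)
        k = kernel_size

        def _bank():
            w = rng.normal(0.0, 0.01, size=(c, k))
            w[:, (k - 1) // 2] += 1.0
            return w

        self.dw_h1 = Parameter(_bank(), dtype=dtype)
        self.bias_h1 = Parameter(np.zeros(c), dtype=dtype)
        self.dw_v1 = Parameter(_bank(), dtype=dtype)
        self.bias_v1 = Parameter(np.zeros(c), dtype=dtype)
        self.dw_h2 = Parameter(_bank(), dtype=dtype)
        self.bias_h2 = Parameter(np.zeros(c), dtype=dtype)
        self.dw_v2 = Parameter(_bank(), dtype=dtype)
        self.bias_v2 = Parameter(np.zeros(c), dtype=dtype)
        fan_out = c if pointwise_fan == "full" else 1
        pw = rng.normal(0.0, 0.01, size=(fan_out, c))
        if fan_out == c:
            pw += np.eye(c)
        self.pointwise = Parameter(pw, dtype=dtype)
        self.pointwise_bias = Parameter(np.zeros(fan_out), dtype=dtype)
        self.kernel_size = k
        self.activation = activation
        self.dilation = 2

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        z, a, _ = _lgpm_core(x, self.dw_h1, self.bias_h1, self.dw_v1, self.bias_v1,
                             self.dw_h2, self.bias_h2, self.dw_v2, self.bias_v2,
                             self.pointwise, self.pointwise_bias,
                             self.activation, self.dilation)
        return z, a

    def to_params(self) -> LGPMParams:
        return LGPMParams(
            dw_h1=self.dw_h1.data.copy(), dw_v1=self.dw_v1.data.copy(),
            dw_h2=self.dw_h2.data.copy(), dw_v2=self.dw_v2.data.copy(),
            bias_h1=self.bias_h1.data.copy(), bias_v1=self.bias_v1.data.copy(),
            bias_h2=self.bias_h2.data.copy(), bias_v2=self.bias_v2.data.copy(),
            pointwise=self.pointwise.data.copy(),
            pointwise_bias=self.pointwise_bias.data.copy(),
            activation=self.activation, dilation=self.dilation)

    def macs(self, h: int, w: int) -> int:
        c, k = self.dw_h1.shape
        dw = 4 * (c * k * h * w + c * h * w)
        pw = self.pointwise.shape[0] * c * h * w + self.pointwise.shape[0] * h * w
        return dw + pw + c * h * w  # + gating product


class PCSM(Module):
    """Trainable channel branch (identity-ish at init: scale 1, shift 0)."""

    def __init__(self, c: int, heads: int = 4, gn_groups: int | None = None,
                 eps: float = 1e-5, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        if gn_groups is None:
            # default: groups of >= 4 channels (a group of size 1 would
            # normalise the pooled descriptor to identically zero)
            gn_groups = max(1, min(c // 4, 16))
            while c % gn_groups != 0:
                gn_groups -= 1
        if c % heads != 0:
            raise ParameterError(f"C={c} not divisible by heads={heads}")
        if c % gn_groups != 0:
            raise ParameterError(f"C={c} not divisible by gn_groups={gn_groups}")
        self.gn_scale = Parameter(np.ones(c), dtype=dtype)
        self.gn_shift = Parameter(np.zeros(c), dtype=dtype)
        self.q_scale = Parameter(np.ones(c), dtype=dtype)
        self.q_shift = Parameter(np.zeros(c), dtype=dtype)
        self.k_scale = Parameter(np.ones(c), dtype=dtype)
        self.k_shift = Parameter(np.zeros(c), dtype=dtype)
        self.v_scale = Parameter(np.ones(c), dtype=dtype)
        self.v_shift = Parameter(np.zeros(c), dtype=dtype)
        self.heads = heads
        self.gn_groups = gn_groups
        self.eps = eps

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        z, w, _ = _pcsm_core(x, self.gn_scale, self.gn_shift, self.q_scale,
                             self.q_shift, self.k_scale, self.k_shift,
                             self.v_scale, self.v_shift, self.heads,
                             self.gn_groups, self.eps)
        return z, w

    def to_params(self) -> PCSMParams:
        return PCSMParams(
            heads=self.heads, gn_groups=self.gn_groups,
            gn_scale=self.gn_scale.data.copy(), gn_shift=self.gn_shift.data.copy(),
            q_scale=self.q_scale.data.copy(), q_shift=self.q_shift.data.copy(),
            k_scale=self.k_scale.data.copy(), k_shift=self.k_shift.data.copy(),
            v_scale=self.v_scale.data.copy(), v_shift=self.v_shift.data.copy(),
            eps=self.eps)

    def macs(self, h: int, w: int) -> int:
        c = self.gn_scale.shape[0]
        d = c // self.heads
        return c * h * w + 8 * c + 2 * self.heads * self.heads * d + c * h * w


class IDPHead(Module):
    """Dual-branch head shared across pyramid levels."""

    def __init__(self, c: int, num_classes: int, anchors: int = 1,
                 kernel_size: int = 11, activation: str = "sigmoid",
                 heads: int = 4, gn_groups: int | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        if anchors < 1 or num_classes < 1:
            raise ParameterError("anchors and num_classes must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.lgpm = LGPM(c, kernel_size, activation, rng=rng, dtype=dtype)
        self.pcsm = PCSM(c, heads=heads, gn_groups=gn_groups, rng=rng, dtype=dtype)
        self.cls_conv = Conv2d(c, c, 3, rng=rng, dtype=dtype)
        self.cls_norm = GroupNorm2d(c, dtype=dtype)
        self.cls_pred = Conv2d(c, anchors * num_classes, 1, rng=rng, dtype=dtype)
        self.cls_pred.b.data[:] = -3.0  # low-score prior stabilises early BCE
        self.reg_conv = Conv2d(c, c, 3, rng=rng, dtype=dtype)
        self.reg_norm = GroupNorm2d(c, dtype=dtype)
        self.reg_pred = Conv2d(c, anchors * 4, 1, rng=rng, dtype=dtype)
        self.anchors = anchors
        self.num_classes = num_classes
        self.channels = c

    def forward_level(self, x: Tensor) -> tuple[Tensor, Tensor]:
        z1, _ = self.lgpm(x)
        z2, _ = self.pcsm(x)
        f = ad.add(z1, z2)
        cls = self.cls_pred(ad.silu(self.cls_norm(self.cls_conv(f))))
        reg = self.reg_pred(ad.silu(self.reg_norm(self.reg_conv(f))))
        return cls, reg

    def __call__(self, pyramid: Sequence[Tensor]) -> list[tuple[Tensor, Tensor]]:
        _check_pyramid_channels(pyramid, self.channels)
        return [self.forward_level(x) for x in pyramid]

    def macs(self, level_hw: Sequence[tuple[int, int]]) -> int:
        total = 0
        for h, w in level_hw:
            total += self.lgpm.macs(h, w) + self.pcsm.macs(h, w)
            for layer in (self.cls_conv, self.cls_norm, self.cls_pred,
                          self.reg_conv, self.reg_norm, self.reg_pred):
                m, _, _ = layer.macs(h, w)
                total += m
        return total


class PlainHead(Module):
    """Ablation baseline: identical prediction branches, no attention."""

    def __init__(self, c: int, num_classes: int, anchors: int = 1,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        if anchors < 1 or num_classes < 1:
            raise ParameterError("anchors and num_classes must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.cls_conv = Conv2d(c, c, 3, rng=rng, dtype=dtype)
        self.cls_norm = GroupNorm2d(c, dtype=dtype)
        self.cls_pred = Conv2d(c, anchors * num_classes, 1, rng=rng, dtype=dtype)
        self.cls_pred.b.data[:] = -3.0
        self.reg_conv = Conv2d(c, c, 3, rng=rng, dtype=dtype)
        self.reg_norm = GroupNorm2d(c, dtype=dtype)
        self.reg_pred = Conv2d(c, anchors * 4, 1, rng=rng, dtype=dtype)
        self.anchors = anchors
        self.num_classes = num_classes
        self.channels = c

    def forward_level(self, x: Tensor) -> tuple[Tensor, Tensor]:
        cls = self.cls_pred(ad.silu(self.cls_norm(self.cls_conv(x))))
        reg = self.reg_pred(ad.silu(self.reg_norm(self.reg_conv(x))))
        return cls, reg

    def __call__(self, pyramid: Sequence[Tensor]) -> list[tuple[Tensor, Tensor]]:
        _check_pyramid_channels(pyramid, self.channels)
        return [self.forward_level(x) for x in pyramid]

    def macs(self, level_hw: Sequence[tuple[int, int]]) -> int:
        total = 0
        for h, w in level_hw:
            for layer in (self.cls_conv, self.cls_norm, self.cls_pred,
                          self.reg_conv, self.reg_norm, self.reg_pred):
                m, _, _ = layer.macs(h, w)
                total += m
        return total


def _check_pyramid_channels(pyramid, c: int) -> None:
    chans = {int(np.shape(x.data if isinstance(x, Tensor) else x)[1]) for x in pyramid}
    if len(chans) > 1 or (chans and chans != {c}):
        raise ShapeError(f"pyramid channel counts {sorted(chans)} do not all equal {c}")


def idp_head_forward(pyramid: Sequence[np.ndarray], head) -> list[HeadOutputs]:
    """Run a head module over a multi-level pyramid of ndarray feature maps."""
    maps = [_check_featuremap(x) for x in pyramid]
    _check_pyramid_channels(maps, head.channels)
    outs = head([Tensor(x) for x in maps])
    return [HeadOutputs(cls=c.data, reg=r.data) for c, r in outs]


# ---------------------------------------------------------------------------
# closed-form parameter counts
# ---------------------------------------------------------------------------


def lgpm_param_count(c: int, k: int) -> int:
    """4 depthwise banks (+biases) and the full-fan pointwise mix: 4CK+4C+C^2+C."""
    return 4 * c * k + 4 * c + c * c + c


def pcsm_param_count(c: int) -> int:
    """Group-norm affines plus three scale+shift projections: 2C + 3*(C+C)."""
    return 2 * c + 3 * (c + c)
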