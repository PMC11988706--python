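"""Building blocks of the attention residual U-Net.

All blocks are shape-preserving NHWC tensor operators (except the stride-2
residual block, which halves the spatial size exactly):

* **Channel attention** — global average pooling to a per-channel descriptor
  ``z_c``, a two-layer bottleneck MLP with LeakyReLU between the layers, and a
  logistic gate ``s`` multiplied back onto the feature map.
* **Spatial attention** — two 7x7 convolutions on the channel-gated map; the
  first reduces channels by a divisor and passes through LeakyReLU, the
  second produces a single-channel logistic map ``M_s``.
* **CBAM** — channel gating followed by spatial gating,
  ``F = (U ⊙ s) ⊙ M_s``.  Note this variant uses *only* the average-pooled
  channel descriptor and a plain two-convolution spatial branch — there is no
  max-pooling path and no channel-wise avg/max concatenation.
* **ASPP** — four parallel 3x3 convolutions at dilation rates 1, 6, 12, 18,
  each batch-normalized, summed elementwise and fused by a 1x1 convolution.
* **Residual block** — twice (BN → 3x3 depthwise-separable convolution →
  LeakyReLU) on the main path, a 1x1 convolution + BN shortcut; stride 2 in
  the leading convolutions downsamples.
* **Attention gate** — an additive gate on encoder skip features computed
  from the coarser decoder features through 1x1 projections, evaluated at the
  decoder resolution and bilinearly upsampled.
* **Stem** — two concurrent paths on the network input (3x3 conv → BN →
  LeakyReLU → 3x3 conv; and 1x1 conv → 2x2 max-pool → bilinear upsample),
  merged by addition, then BN → LeakyReLU → CBAM.

Each block is a :class:`~carunet.autograd.Module`; the module-level functions
(`channel_attention`, `cbam`, ...) are thin functional aliases that apply an
already-constructed block, matching the operator view of the architecture.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import (
    BatchNorm2d,
    Conv2d,
    Linear,
    Module,
    SeparableConv2d,
    Tensor,
    as_tensor,
)
from .errors import ShapeError

__all__ = [
    "ChannelAttention", "SpatialAttention", "CBAM", "ASPP",
    "ResidualBlock", "AttentionGate", "StemBlock",
    "channel_attention", "spatial_attention", "cbam", "aspp",
    "residual_block", "attention_gate", "stem_block",
]

LEAKY_SLOPE = 0.01  # negative slope used throughout (hyperparameter table)


def _act(x, slope: float):
    return ag.leaky_relu(x, negative_slope=slope)


class ChannelAttention(Module):
    """Squeeze (global average pool) + two fully connected layers + sigmoid.

    ``z_c`` is the spatial mean of channel ``c``; the gate is
    ``s = σ(W2 · LeakyReLU(W1 · z))`` and the output is ``U ⊙ s`` with ``s``
    broadcast over the spatial grid.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator,
                 hidden: int | None = None, act_slope: float = LEAKY_SLOPE):
        super().__init__()
        self.channels = channels
        self.act_slope = act_slope
        self.hidden = hidden if hidden is not None else max(channels // reduction, 1)
        self.fc1 = Linear(channels, self.hidden, rng)
        self.fc2 = Linear(self.hidden, channels, rng)

    def forward(self, u):
        u = as_tensor(u)
        if u.shape[-1] != self.channels:
            raise ShapeError(
                f"channel_attention: expected {self.channels} channels, got {u.shape[-1]}")
        z = ag.reduce_mean(u, axis=(1, 2))            # (N, C) pooled descriptor
        s = ag.sigmoid(self.fc2(_act(self.fc1(z), self.act_slope)))
        s4 = ag.reshape(s, (s.shape[0], 1, 1, self.channels))
        return ag.mul(u, s4)


class SpatialAttention(Module):
    """Two-convolution spatial gate producing an HxWx1 logistic map."""

    def __init__(self, channels: int, divisor: int, rng: np.random.Generator,
                 kernel: int = 7, act_slope: float = LEAKY_SLOPE):
        super().__init__()
        self.act_slope = act_slope
        mid = max(channels // divisor, 1)
        self.conv1 = Conv2d(channels, mid, kernel, rng)
        self.conv2 = Conv2d(mid, 1, kernel, rng)

    def forward(self, u_channel):
        v1 = _act(self.conv1(u_channel), self.act_slope)
        return ag.sigmoid(self.conv2(v1))


class CBAM(Module):
    """Channel attention then spatial attention, applied multiplicatively."""

    def __init__(self, channels: int, reduction: int, spatial_divisor: int,
                 rng: np.random.Generator, act_slope: float = LEAKY_SLOPE):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng, act_slope=act_slope)
        self.spatial = SpatialAttention(channels, spatial_divisor, rng, act_slope=act_slope)

    def forward(self, u):
        u_channel = self.channel(u)
        m_s = self.spatial(u_channel)
        return ag.mul(u_channel, m_s)


class ASPP(Module):
    """Atrous spatial pyramid pooling bridge.

    Parallel same-padded 3x3 convolutions at the configured dilation rates,
    each followed by batch normalization; the branch outputs are summed and
    fused by a 1x1 convolution.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 rates: tuple[int, ...] = (1, 6, 12, 18)):
        super().__init__()
        if any(r <= 0 for r in rates):
            raise ValueError(f"aspp: dilation rates must be positive, got {rates}")
        self.rates = tuple(rates)
        self.branches = [Conv2d(channels, channels, 3, rng, dilation=r) for r in rates]
        self.norms = [BatchNorm2d(channels) for _ in rates]
        self.fuse = Conv2d(channels, channels, 1, rng)

    def forward(self, x):
        acc = None
        for conv, bn in zip(self.branches, self.norms):
            xi = bn(conv(x))
            acc = xi if acc is None else ag.add(acc, xi)
        return self.fuse(acc)


class ResidualBlock(Module):
    """Pre-activation residual block with depthwise-separable convolutions.

    Main path: BN → 3x3 separable conv (stride s) → LeakyReLU → BN → 3x3
    separable conv → LeakyReLU.  Shortcut: 1x1 conv (stride s) → BN.  With
    stride 2 the spatial size halves exactly; odd inputs are rejected.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 stride: int = 1, act_slope: float = LEAKY_SLOPE):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError(f"residual_block: stride must be 1 or 2, got {stride}")
        self.stride = stride
        self.act_slope = act_slope
        self.bn1 = BatchNorm2d(cin)
        self.conv1 = SeparableConv2d(cin, cout, 3, rng, stride=stride)
        self.bn2 = BatchNorm2d(cout)
        self.conv2 = SeparableConv2d(cout, cout, 3, rng)
        self.shortcut = Conv2d(cin, cout, 1, rng, stride=stride)
        self.bn_short = BatchNorm2d(cout)

    def forward(self, x):
        x = as_tensor(x)
        if self.stride == 2 and (x.shape[1] % 2 or x.shape[2] % 2):
            raise ShapeError(
                f"residual_block: stride-2 block needs even spatial size, got {x.shape[1:3]}")
        h = _act(self.conv1(self.bn1(x)), self.act_slope)
        h = _act(self.conv2(self.bn2(h)), self.act_slope)
        return ag.add(h, self.bn_short(self.shortcut(x)))


class AttentionGate(Module):
    """Additive attention gate on an encoder skip connection.

    ``g = σ(ψ ∗ LeakyReLU(θe ∗ enc' + θd ∗ dec))`` where ``enc'`` is the
    encoder map brought to the decoder resolution by a stride-2 1x1
    projection; the single-channel gate is bilinearly upsampled back and
    multiplies the skip features.
    """

    def __init__(self, enc_channels: int, dec_channels: int,
                 rng: np.random.Generator, inter_channels: int | None = None,
                 act_slope: float = LEAKY_SLOPE):
        super().__init__()
        self.act_slope = act_slope
        ci = inter_channels if inter_channels is not None else max(enc_channels // 2, 1)
        self.theta_enc = Conv2d(enc_channels, ci, 1, rng, stride=2)
        self.theta_dec = Conv2d(dec_channels, ci, 1, rng)
        self.psi = Conv2d(ci, 1, 1, rng)

    def forward(self, enc, dec):
        enc, dec = as_tensor(enc), as_tensor(dec)
        if enc.shape[1] != 2 * dec.shape[1] or enc.shape[2] != 2 * dec.shape[2]:
            raise ShapeError(
                f"attention_gate: encoder {enc.shape[1:3]} must be 2x the "
                f"decoder {dec.shape[1:3]}")
        q = _act(ag.add(self.theta_enc(enc), self.theta_dec(dec)), self.act_slope)
        gate = ag.sigmoid(self.psi(q))
        return ag.mul(enc, ag.upsample_bilinear2x(gate))


class StemBlock(Module):
    """Entry block: two concurrent paths merged additively, then CBAM."""

    def __init__(self, cin: int, cout: int, reduction: int, spatial_divisor: int,
                 rng: np.random.Generator, act_slope: float = LEAKY_SLOPE):
        super().__init__()
        self.act_slope = act_slope
        self.conv_a1 = Conv2d(cin, cout, 3, rng)
        self.bn_a = BatchNorm2d(cout)
        self.conv_a2 = Conv2d(cout, cout, 3, rng)
        self.conv_b = Conv2d(cin, cout, 1, rng)
        self.bn_merge = BatchNorm2d(cout)
        self.cbam = CBAM(cout, reduction, spatial_divisor, rng, act_slope=act_slope)

    def forward(self, x):
        x = as_tensor(x)
        if x.ndim != 4:
            raise ShapeError(f"stem_block: expected NHWC input, got ndim={x.ndim}")
        a = self.conv_a2(_act(self.bn_a(self.conv_a1(x)), self.act_slope))
        b = ag.upsample_bilinear2x(ag.max_pool2x2(self.conv_b(x)))
        merged = _act(self.bn_merge(ag.add(a, b)), self.act_slope)
        return self.cbam(merged)


# Functional aliases -------------------------------------------------------

def channel_attention(u, params: ChannelAttention) -> Tensor:
    """Apply a channel-attention block to ``u``."""
    return params(u)


def spatial_attention(u_channel, params: SpatialAttention) -> Tensor:
    """Compute the HxWx1 spatial attention map of ``u_channel``."""
    return params(u_channel)


def cbam(u, params: CBAM) -> Tensor:
    """Apply channel-then-spatial attention to ``u``."""
    return params(u)


def aspp(x, params: ASPP) -> Tensor:
    """Apply the atrous spatial pyramid pooling bridge."""
    return params(x)


def residual_block(x, params: ResidualBlock) -> Tensor:
    """Apply a residual block."""
    return params(x)


def attention_gate(enc, dec, params: AttentionGate) -> Tensor:
    """Gate encoder skip features with decoder context."""
    return params(enc, dec)


def stem_block(x, params: StemBlock) -> Tensor:
    """Apply the stem block."""
    return params(x)
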