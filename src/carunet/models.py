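"""Model assembly, analytic parameter counting, and width calibration.

Four architectures form the ablation ladder:

* ``unet`` — the classical double-convolution U-Net benchmark (3x3 conv
  pairs, 2x2 max-pooling, 2x2 transposed-convolution upsampling, no batch
  normalization).
* ``res_unet`` — the same U shape with every double convolution replaced by
  a pre-activation residual block built from depthwise-separable
  convolutions; downsampling by stride-2 blocks.
* ``res_unet_attn`` — ``res_unet`` plus additive attention gates on the
  skip connections.
* ``proposed`` — the lightweight attention residual U-Net: a stem block with
  CBAM, CBAM after every residual block, an ASPP bridge between encoder and
  decoder, attention-gated skips, and bilinear-plus-3x3-convolution
  upsampling in the decoder.  With ReLU instead of LeakyReLU activations
  this is the ablation variant IV; the parameter count is unchanged because
  activations are parameter-free.

The published architecture is specified only up to its parameter budget: the
per-level channel widths were never printed, so the shipped defaults are
*calibrated* — a deterministic search over width ladders (and the attention
hyper-parameters) for configurations whose analytic parameter count lands in
the budget windows implied by the printed "millions" (truncated to two
decimals) and megabyte (total x 4 bytes / 2^20, rounded to two decimals)
figures.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Conv2d, ConvTranspose2x2, Module, as_tensor
from .blocks import ASPP, CBAM, AttentionGate, ResidualBlock, StemBlock
from .errors import CalibrationError, ConfigurationError, ShapeError

__all__ = [
    "ModelConfig", "ParamCount", "ARCHITECTURES", "TABLE7_WINDOWS",
    "DEFAULT_CONFIGS", "default_config", "build_model", "count_parameters",
    "analytic_param_count", "calibrate_widths", "model_summary",
    "save_checkpoint", "load_checkpoint",
]

ARCHITECTURES = ("unet", "res_unet", "res_unet_attn", "proposed")

#: Parameter-count windows implied by the printed budget table: the total in
#: "millions" is truncated to two decimals and the size in MB is
#: total*4/2^20 rounded to two decimals; the window is the intersection of
#: the two preimages (inclusive bounds).
TABLE7_WINDOWS: dict[str, tuple[int, int]] = {
    "unet": (3_275_490, 3_278_110),           # 3.27 M / 12.50 MB
    "res_unet": (5_063_312, 5_065_932),       # 5.06 M / 19.32 MB
    "res_unet_attn": (5_860_000, 5_860_229),  # 5.86 M / 22.35 MB
    "proposed": (3_241_411, 3_244_031),       # 3.24 M / 12.37 MB
}

#: Trainable-count windows from the same table (truncated millions).
TABLE7_TRAINABLE_WINDOWS: dict[str, tuple[int, int]] = {
    "unet": (3_270_000, 3_279_999),
    "res_unet": (5_050_000, 5_059_999),
    "res_unet_attn": (5_850_000, 5_859_999),
    "proposed": (3_230_000, 3_239_999),
}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``widths`` are the channel counts of encoder levels 1-4 plus the
    bottleneck, strictly increasing.  ``gate_channels`` optionally overrides
    the intermediate channel count of the attention gate at each decoder
    level (shallowest first); ``None`` entries default to half the encoder
    width at that level.
    """

    arch: str
    widths: tuple[int, int, int, int, int]
    reduction_ratio: int = 8
    spatial_divisor: int = 8
    gate_channels: tuple[int | None, int | None, int | None, int | None] = (
        None, None, None, None)
    input_size: int = 256
    in_channels: int = 1
    activation: str = "leaky_relu"

    def __post_init__(self):
        if self.arch not in ARCHITECTURES:
            raise ConfigurationError(
                f"arch: unknown architecture {self.arch!r}; expected one of {ARCHITECTURES}")
        w = tuple(int(x) for x in self.widths)
        if len(w) != 5 or any(x < 1 for x in w):
            raise ConfigurationError("widths: need 5 positive channel counts")
        if any(a >= b for a, b in zip(w, w[1:])):
            raise ConfigurationError(f"widths: must be strictly increasing, got {w}")
        object.__setattr__(self, "widths", w)
        if self.input_size < 16 or self.input_size % 16:
            raise ConfigurationError(
                f"input_size: must be a multiple of 16 and >= 16, got {self.input_size}")
        if self.reduction_ratio < 1 or self.spatial_divisor < 1:
            raise ConfigurationError("reduction_ratio/spatial_divisor: must be >= 1")
        if self.activation not in ("leaky_relu", "relu"):
            raise ConfigurationError(
                f"activation: expected 'leaky_relu' or 'relu', got {self.activation!r}")
        gc = tuple(self.gate_channels)
        if len(gc) != 4 or any(g is not None and g < 1 for g in gc):
            raise ConfigurationError("gate_channels: need 4 entries (int >= 1 or None)")
        object.__setattr__(self, "gate_channels", gc)

    @property
    def act_slope(self) -> float:
        return 0.01 if self.activation == "leaky_relu" else 0.0

    def gate_inter(self, level: int) -> int:
        """Intermediate channels of the attention gate at decoder level
        ``level`` (0 = shallowest)."""
        g = self.gate_channels[level]
        return g if g is not None else max(self.widths[level] // 2, 1)

    def to_dict(self) -> dict:
        return {
            "arch": self.arch,
            "widths": list(self.widths),
            "reduction_ratio": self.reduction_ratio,
            "spatial_divisor": self.spatial_divisor,
            "gate_channels": list(self.gate_channels),
            "input_size": self.input_size,
            "in_channels": self.in_channels,
            "activation": self.activation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown model config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("widths", "gate_channels"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class ParamCount:
    """Total/trainable parameter counts and the derived checkpoint size."""

    total: int
    trainable: int

    @property
    def non_trainable(self) -> int:
        return self.total - self.trainable

    @property
    def size_mb(self) -> float:
        """Float32 storage of all parameters in binary megabytes."""
        return self.total * 4 / 2**20

    def millions(self) -> tuple[float, float]:
        """(total, trainable) in millions, truncated to two decimals."""
        return (int(self.total / 10_000) / 100, int(self.trainable / 10_000) / 100)


# --------------------------------------------------------------------------
# Architectures
# --------------------------------------------------------------------------

class _DoubleConv(Module):
    """Two 3x3 convolutions with activations (classical U-Net unit)."""

    def __init__(self, cin, cout, rng, act_slope):
        super().__init__()
        self.act_slope = act_slope
        self.c1 = Conv2d(cin, cout, 3, rng)
        self.c2 = Conv2d(cout, cout, 3, rng)

    def forward(self, x):
        h = ag.leaky_relu(self.c1(x), self.act_slope)
        return ag.leaky_relu(self.c2(h), self.act_slope)


class UNet(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        w1, w2, w3, w4, wb = cfg.widths
        s = cfg.act_slope
        self.enc = [
            _DoubleConv(cfg.in_channels, w1, rng, s),
            _DoubleConv(w1, w2, rng, s),
            _DoubleConv(w2, w3, rng, s),
            _DoubleConv(w3, w4, rng, s),
        ]
        self.bottleneck = _DoubleConv(w4, wb, rng, s)
        self.ups = [
            ConvTranspose2x2(wb, w4, rng),
            ConvTranspose2x2(w4, w3, rng),
            ConvTranspose2x2(w3, w2, rng),
            ConvTranspose2x2(w2, w1, rng),
        ]
        self.dec = [
            _DoubleConv(2 * w4, w4, rng, s),
            _DoubleConv(2 * w3, w3, rng, s),
            _DoubleConv(2 * w2, w2, rng, s),
            _DoubleConv(2 * w1, w1, rng, s),
        ]
        self.head = Conv2d(w1, 1, 1, rng)

    def forward(self, x):
        x = _check_input(x, self.cfg)
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = ag.max_pool2x2(x)
        x = self.bottleneck(x)
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = block(ag.concat([skip, up(x)], axis=-1))
        return ag.sigmoid(self.head(x))


class ResUNet(Module):
    """Residual U-Net; with ``attn=True`` the skips are attention-gated."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, attn: bool):
        super().__init__()
        self.cfg = cfg
        self.attn = attn
        w1, w2, w3, w4, wb = cfg.widths
        s = cfg.act_slope
        self.entry = ResidualBlock(cfg.in_channels, w1, rng, act_slope=s)
        self.down = [
            ResidualBlock(w1, w2, rng, stride=2, act_slope=s),
            ResidualBlock(w2, w3, rng, stride=2, act_slope=s),
            ResidualBlock(w3, w4, rng, stride=2, act_slope=s),
            ResidualBlock(w4, wb, rng, stride=2, act_slope=s),
        ]
        dec_in = (wb, w4, w3, w2)
        skip_w = (w4, w3, w2, w1)
        if attn:
            self.gates = [
                AttentionGate(skip_w[i], dec_in[i], rng,
                              inter_channels=cfg.gate_inter(3 - i), act_slope=s)
                for i in range(4)
            ]
        self.ups = [ConvTranspose2x2(dec_in[i], skip_w[i], rng) for i in range(4)]
        self.dec = [ResidualBlock(2 * skip_w[i], skip_w[i], rng, act_slope=s)
                    for i in range(4)]
        self.head = Conv2d(w1, 1, 1, rng)

    def forward(self, x):
        x = _check_input(x, self.cfg)
        x = self.entry(x)
        skips = [x]
        for block in self.down[:-1]:
            x = block(x)
            skips.append(x)
        x = self.down[-1](x)
        for i in range(4):
            skip = skips[3 - i]
            if self.attn:
                skip = self.gates[i](skip, x)
            x = self.dec[i](ag.concat([skip, self.ups[i](x)], axis=-1))
        return ag.sigmoid(self.head(x))


class _UpConv(Module):
    """Bilinear 2x upsampling followed by a 3x3 convolution."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.conv = Conv2d(cin, cout, 3, rng)

    def forward(self, x):
        return self.conv(ag.upsample_bilinear2x(x))


class ProposedNet(Module):
    """Stem+CBAM -> 4 stride-2 residual blocks with CBAM -> ASPP bridge ->
    attention-gated decoder with bilinear upsampling, residual blocks and
    CBAM -> 1x1 convolution + sigmoid."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        w1, w2, w3, w4, wb = cfg.widths
        r, dv, s = cfg.reduction_ratio, cfg.spatial_divisor, cfg.act_slope
        self.stem = StemBlock(cfg.in_channels, w1, r, dv, rng, act_slope=s)
        enc_w = (w1, w2, w3, w4, wb)
        self.down = [ResidualBlock(enc_w[i], enc_w[i + 1], rng, stride=2, act_slope=s)
                     for i in range(4)]
        self.down_cbam = [CBAM(enc_w[i + 1], r, dv, rng, act_slope=s) for i in range(4)]
        self.aspp = ASPP(wb, rng)
        dec_in = (wb, w4, w3, w2)
        skip_w = (w4, w3, w2, w1)
        self.gates = [
            AttentionGate(skip_w[i], dec_in[i], rng,
                          inter_channels=cfg.gate_inter(3 - i), act_slope=s)
            for i in range(4)
        ]
        self.ups = [_UpConv(dec_in[i], skip_w[i], rng) for i in range(4)]
        self.dec = [ResidualBlock(2 * skip_w[i], skip_w[i], rng, act_slope=s)
                    for i in range(4)]
        self.dec_cbam = [CBAM(skip_w[i], r, dv, rng, act_slope=s) for i in range(4)]
        self.head = Conv2d(w1, 1, 1, rng)

    def forward(self, x):
        x = _check_input(x, self.cfg)
        x = self.stem(x)
        skips = [x]
        for i in range(4):
            x = self.down_cbam[i](self.down[i](x))
            if i < 3:
                skips.append(x)
        x = self.aspp(x)
        for i in range(4):
            skip = self.gates[i](skips[3 - i], x)
            x = self.dec[i](ag.concat([skip, self.ups[i](x)], axis=-1))
            x = self.dec_cbam[i](x)
        return ag.sigmoid(self.head(x))


def _check_input(x, cfg: ModelConfig):
    x = as_tensor(x)
    if x.ndim != 4 or x.shape[-1] != cfg.in_channels:
        raise ShapeError(
            f"model input must be (N, H, W, {cfg.in_channels}), got {x.shape}")
    if x.shape[1] % 16 or x.shape[2] % 16:
        raise ShapeError(f"spatial size must be divisible by 16, got {x.shape[1:3]}")
    return x


def build_model(config: ModelConfig, seed: int = 0) -> Module:
    """Instantiate an architecture with seeded weight initialization."""
    rng = np.random.default_rng(seed)
    if config.arch == "unet":
        return UNet(config, rng)
    if config.arch == "res_unet":
        return ResUNet(config, rng, attn=False)
    if config.arch == "res_unet_attn":
        return ResUNet(config, rng, attn=True)
    return ProposedNet(config, rng)


# --------------------------------------------------------------------------
# Parameter counting
# --------------------------------------------------------------------------

def count_parameters(model: Module) -> ParamCount:
    """Count parameters by traversing the model's actual weight arrays."""
    trainable = sum(p.data.size for _, p in model.named_parameters())
    buffers = sum(b.size for _, b in model.named_buffers())
    return ParamCount(total=trainable + buffers, trainable=trainable)


class _Count:
    """Accumulator for the analytic (closed-form) layer counts."""

    def __init__(self):
        self.trainable = 0
        self.non_trainable = 0

    def conv(self, k, cin, cout):
        self.trainable += k * k * cin * cout + cout

    def sep(self, cin, cout, k=3):
        self.trainable += k * k * cin + cin            # depthwise + bias
        self.trainable += cin * cout + cout            # pointwise + bias

    def bn(self, c):
        self.trainable += 2 * c
        self.non_trainable += 2 * c                    # running mean + var

    def linear(self, cin, cout):
        self.trainable += cin * cout + cout

    def ct2(self, cin, cout):
        self.trainable += 4 * cin * cout + cout

    def channel_attention(self, c, r):
        h = max(c // r, 1)
        self.linear(c, h)
        self.linear(h, c)

    def spatial_attention(self, c, dv, k=7):
        mid = max(c // dv, 1)
        self.conv(k, c, mid)
        self.conv(k, mid, 1)

    def cbam(self, c, r, dv):
        self.channel_attention(c, r)
        self.spatial_attention(c, dv)

    def residual_block(self, cin, cout):
        self.bn(cin)
        self.sep(cin, cout)
        self.bn(cout)
        self.sep(cout, cout)
        self.conv(1, cin, cout)
        self.bn(cout)

    def attention_gate(self, ce, cd, ci):
        self.conv(1, ce, ci)
        self.conv(1, cd, ci)
        self.conv(1, ci, 1)

    def aspp(self, c, n_rates=4):
        for _ in range(n_rates):
            self.conv(3, c, c)
            self.bn(c)
        self.conv(1, c, c)

    def stem(self, cin, cout, r, dv):
        self.conv(3, cin, cout)
        self.bn(cout)
        self.conv(3, cout, cout)
        self.conv(1, cin, cout)
        self.bn(cout)
        self.cbam(cout, r, dv)

    def double_conv(self, cin, cout):
        self.conv(3, cin, cout)
        self.conv(3, cout, cout)


def analytic_param_count(config: ModelConfig) -> ParamCount:
    """Closed-form per-layer parameter count derived from the config alone.

    Mirrors the architecture definitions layer by layer without building any
    weight arrays; serves as the independent oracle for
    :func:`count_parameters` and as the objective of the width calibration.
    """
    w1, w2, w3, w4, wb = config.widths
    cin = config.in_channels
    r, dv = config.reduction_ratio, config.spatial_divisor
    acc = _Count()
    dec_in = (wb, w4, w3, w2)
    skip_w = (w4, w3, w2, w1)

    if config.arch == "unet":
        for a, b in ((cin, w1), (w1, w2), (w2, w3), (w3, w4), (w4, wb)):
            acc.double_conv(a, b)
        for i in range(4):
            acc.ct2(dec_in[i], skip_w[i])
            acc.double_conv(2 * skip_w[i], skip_w[i])
        acc.conv(1, w1, 1)
    elif config.arch in ("res_unet", "res_unet_attn"):
        for a, b in ((cin, w1), (w1, w2), (w2, w3), (w3, w4), (w4, wb)):
            acc.residual_block(a, b)
        for i in range(4):
            if config.arch == "res_unet_attn":
                acc.attention_gate(skip_w[i], dec_in[i], config.gate_inter(3 - i))
            acc.ct2(dec_in[i], skip_w[i])
            acc.residual_block(2 * skip_w[i], skip_w[i])
        acc.conv(1, w1, 1)
    else:  # proposed
        acc.stem(cin, w1, r, dv)
        enc_w = (w1, w2, w3, w4, wb)
        for i in range(4):
            acc.residual_block(enc_w[i], enc_w[i + 1])
            acc.cbam(enc_w[i + 1], r, dv)
        acc.aspp(wb)
        for i in range(4):
            acc.attention_gate(skip_w[i], dec_in[i], config.gate_inter(3 - i))
            acc.conv(3, dec_in[i], skip_w[i])        # upsample conv
            acc.residual_block(2 * skip_w[i], skip_w[i])
            acc.cbam(skip_w[i], r, dv)
        acc.conv(1, w1, 1)

    return ParamCount(total=acc.trainable + acc.non_trainable,
                      trainable=acc.trainable)


# --------------------------------------------------------------------------
# Width calibration
# --------------------------------------------------------------------------

def _total(cfg: ModelConfig) -> int:
    return analytic_param_count(cfg).total


def _interval_dist(value: int, window: tuple[int, int] | None) -> int:
    if window is None:
        return 0
    lo, hi = window
    if value < lo:
        return lo - value
    if value > hi:
        return value - hi
    return 0


def calibrate_widths(arch: str, window: tuple[int, int],
                     trainable_window: tuple[int, int] | None = None,
                     input_size: int = 256, min_width: int = 8) -> ModelConfig:
    """Find a configuration whose total parameter count lies in ``window``.

    The search is deterministic: a coarse pass over geometric width ladders
    (base width 8..40, x2 growth, attention reduction and spatial divisor in
    {4, 8, 16}), then coordinate descent on the five level widths, then — for
    gated architectures — unit adjustments of the attention-gate intermediate
    channels, which provide the finest granularity.  ``trainable_window``
    optionally constrains the trainable count as well (the total/trainable
    gap is exactly the batch-normalization running statistics, so it pins
    down the aggregate channel budget).  Raises :class:`CalibrationError`
    with the nearest achievable count if the window cannot be reached.
    """
    if arch not in ARCHITECTURES:
        raise ConfigurationError(f"arch: unknown architecture {arch!r}")
    lo, hi = int(window[0]), int(window[1])
    if lo > hi:
        raise ConfigurationError(f"window: empty interval ({lo}, {hi})")
    window = (lo, hi)

    def make(widths, r=8, dv=8, gates=(None, None, None, None)):
        if widths[0] < min_width:
            return None
        try:
            return ModelConfig(arch=arch, widths=widths, reduction_ratio=r,
                               spatial_divisor=dv, gate_channels=gates,
                               input_size=input_size)
        except ConfigurationError:
            return None

    def score(cfg: ModelConfig) -> int:
        pc = analytic_param_count(cfg)
        return (_interval_dist(pc.total, window)
                + _interval_dist(pc.trainable, trainable_window))

    uses_cbam = arch == "proposed"
    r_grid = (4, 8, 16) if uses_cbam else (8,)
    dv_grid = (4, 8, 16) if uses_cbam else (8,)

    def cand_key(cfg: ModelConfig):
        gates = tuple(g if g is not None else -1 for g in cfg.gate_channels)
        return (cfg.widths, cfg.reduction_ratio, cfg.spatial_divisor, gates)

    # Stage 1: coarse grid over geometric ladders; keep the closest few as
    # beam seeds.  Growth ratios other than x2 diversify the channel-sum /
    # parameter-product trade-off (the trainable gap is linear in the widths
    # while the total is quadratic).
    seeds: dict[tuple, tuple[int, ModelConfig]] = {}
    for base in range(8, 41):
        for growth in (2.0, 1.8, 2.2, 2.5):
            widths = tuple(max(int(round(base * growth ** i)), 1) for i in range(5))
            for r in r_grid:
                for dv in dv_grid:
                    cfg = make(widths, r, dv)
                    if cfg is None:
                        continue
                    d = score(cfg)
                    if d == 0:
                        return cfg
                    seeds.setdefault(cand_key(cfg), (d, cfg))

    # Stage 2: deterministic beam search.  Neighbours adjust one level width
    # (coarse to fine steps) or, for gated architectures, one attention-gate
    # intermediate channel count (the finest knob: a unit step moves the
    # total by enc+dec+3 parameters).
    gated = arch in ("res_unet_attn", "proposed")
    width_steps = (-64, -16, -8, -4, -2, -1, 1, 2, 4, 8, 16, 64)
    gate_steps = (-8, -4, -2, -1, 1, 2, 4, 8)

    def neighbours(cfg: ModelConfig):
        for level in range(5):
            for step in width_steps:
                w = list(cfg.widths)
                w[level] += step
                cand = make(tuple(w), cfg.reduction_ratio, cfg.spatial_divisor,
                            cfg.gate_channels)
                if cand is not None:
                    yield cand
        if gated:
            for level in range(4):
                for step in gate_steps:
                    gates = list(cfg.gate_channels)
                    gates[level] = cfg.gate_inter(level) + step
                    if gates[level] >= 1:
                        cand = make(cfg.widths, cfg.reduction_ratio,
                                    cfg.spatial_divisor, tuple(gates))
                        if cand is not None:
                            yield cand

    beam_width = 24
    ranked = sorted(seeds.values(), key=lambda t: (t[0], cand_key(t[1])))
    beam = ranked[:beam_width]
    seen = {cand_key(c) for _, c in beam}
    best_d, best = beam[0]
    for _round in range(80):
        frontier: list[tuple[int, ModelConfig]] = []
        for _, cfg in beam:
            for cand in neighbours(cfg):
                key = cand_key(cand)
                if key in seen:
                    continue
                seen.add(key)
                d = score(cand)
                if d == 0:
                    return cand
                frontier.append((d, cand))
        if not frontier:
            break
        merged = sorted(beam + frontier, key=lambda t: (t[0], cand_key(t[1])))
        beam = merged[:beam_width]
        if beam[0][0] < best_d:
            best_d, best = beam[0]
        elif merged == beam:
            break

    raise CalibrationError(
        f"{arch}: no configuration found inside [{lo}, {hi}]; "
        f"nearest achievable total is {_total(best)} (widths={best.widths})")


# Shipped defaults, frozen outputs of the calibration search so model
# construction does not re-run it.  unet/res_unet/proposed satisfy both the
# total and the trainable budget windows; for res_unet_attn only the total
# window is attainable with non-degenerate widths (matching its trainable
# figure as well would force a >2000-channel bottleneck), so it is calibrated
# on the total alone.  The test suite re-derives these from the windows.
DEFAULT_CONFIGS: dict[str, ModelConfig] = {
    "unet": ModelConfig("unet", (33, 52, 94, 169, 304), activation="relu"),
    "res_unet": ModelConfig("res_unet", (39, 86, 189, 415, 910)),
    "res_unet_attn": ModelConfig("res_unet_attn", (26, 57, 162, 406, 1080)),
    "proposed": ModelConfig("proposed", (20, 36, 65, 117, 208),
                            reduction_ratio=8, spatial_divisor=4),
}


def default_config(arch: str) -> ModelConfig:
    """The shipped, budget-calibrated configuration for ``arch``."""
    if arch not in ARCHITECTURES:
        raise ConfigurationError(f"arch: unknown architecture {arch!r}")
    return DEFAULT_CONFIGS[arch]


# --------------------------------------------------------------------------
# Summary and checkpointing
# --------------------------------------------------------------------------

def model_summary(model: Module) -> list[tuple[str, int]]:
    """Per-module trainable parameter counts, depth-first, leaf modules only."""
    rows = []
    for prefix, mod in model._named_modules():
        own = sum(v.data.size for k, v in mod.__dict__.items()
                  if isinstance(v, ag.Tensor) and v.requires_grad)
        if own:
            rows.append((prefix.rstrip(".") or "<root>", own))
    return rows


def save_checkpoint(path, model: Module, config: ModelConfig,
                    extra: dict | None = None) -> None:
    """Write a checkpoint archive: JSON config + raw weight arrays."""
    state = model.state_dict()
    meta = {"config": config.to_dict(), "extra": extra or {}}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        buf = io.BytesIO()
        np.savez(buf, **state)
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path, seed: int = 0):
    """Load a checkpoint archive; returns ``(model, config, extra)``."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        with zf.open("weights.npz") as fh:
            state = dict(np.load(io.BytesIO(fh.read())))
    config = ModelConfig.from_dict(meta["config"])
    model = build_model(config, seed=seed)
    model.load_state_dict(state)
    model.eval()
    return model, config, meta.get("extra", {})
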