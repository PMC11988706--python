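"""Brute-force oracle checks for the attention and pyramid-pooling blocks.

Every oracle below re-evaluates the block's defining equations with plain
Python loops over scalar entries, independently of the vectorized layers.
"""

import numpy as np
import pytest

from carunet import autograd as ag
from carunet.autograd import Tensor
from carunet.blocks import (
    ASPP,
    CBAM,
    AttentionGate,
    ChannelAttention,
    ResidualBlock,
    SpatialAttention,
    StemBlock,
    aspp,
    attention_gate,
    cbam,
    channel_attention,
    residual_block,
    spatial_attention,
    stem_block,
)
from carunet.errors import ShapeError


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def leaky(x, s=0.01):
    return np.where(x >= 0, x, s * x)


def zero_params(module):
    for _, p in module.named_parameters():
        p.data[...] = 0.0
    return module


def conv_loop(x, w, b, dilation=1, stride=1):
    """Scalar sliding-window convolution oracle (same padding, NHWC)."""
    kh, kw, cin, cout = w.shape
    n, h, wd, _ = x.shape
    ph, pw = dilation * (kh - 1) // 2, dilation * (kw - 1) // 2
    ho = (h + 2 * ph - dilation * (kh - 1) - 1) // stride + 1
    wo = (wd + 2 * pw - dilation * (kw - 1) - 1) // stride + 1
    out = np.zeros((n, ho, wo, cout))
    for nn in range(n):
        for oi in range(ho):
            for oj in range(wo):
                for co in range(cout):
                    acc = b[co] if b is not None else 0.0
                    for ki in range(kh):
                        for kj in range(kw):
                            ri = oi * stride + ki * dilation - ph
                            rj = oj * stride + kj * dilation - pw
                            if 0 <= ri < h and 0 <= rj < wd:
                                for ci in range(cin):
                                    acc += x[nn, ri, rj, ci] * w[ki, kj, ci, co]
                    out[nn, oi, oj, co] = acc
    return out


# --------------------------------------------------------------------------
# channel attention (pooled descriptor -> bottleneck MLP -> sigmoid gate)
# --------------------------------------------------------------------------

def test_channel_descriptor_is_spatial_mean():
    rng = np.random.default_rng(0)
    ca = ChannelAttention(2, reduction=2, rng=rng)
    u = np.zeros((1, 4, 4, 2), np.float64)
    u[..., 0] = 3.0
    u[..., 1] = rng.normal(size=(1, 4, 4))
    z = ag.reduce_mean(Tensor(u), axis=(1, 2)).data
    assert z[0, 0] == 3.0
    assert np.isclose(z[0, 1], u[..., 1].mean())
    out = channel_attention(u, ca)
    assert out.shape == u.shape


def test_channel_attention_zero_weights_half_gate():
    rng = np.random.default_rng(1)
    ca = zero_params(ChannelAttention(3, reduction=1, rng=rng))
    u = np.random.default_rng(2).normal(size=(2, 4, 4, 3))
    out = channel_attention(u, ca).data
    assert np.allclose(out, 0.5 * u)


def test_channel_attention_matches_loop_oracle():
    rng = np.random.default_rng(3)
    ca = ChannelAttention(2, reduction=2, rng=rng)
    u = np.random.default_rng(4).normal(size=(1, 2, 2, 2))
    out = channel_attention(u, ca).data

    w1, b1 = ca.fc1.w.data, ca.fc1.b.data
    w2, b2 = ca.fc2.w.data, ca.fc2.b.data
    expect = np.zeros_like(u)
    for n in range(1):
        z = [np.mean([u[n, i, j, c] for i in range(2) for j in range(2)])
             for c in range(2)]
        hid = [leaky(sum(z[c] * w1[c, k] for c in range(2)) + b1[k])
               for k in range(w1.shape[1])]
        s = [sigmoid(sum(hid[k] * w2[k, c] for k in range(len(hid))) + b2[c])
             for c in range(2)]
        for i in range(2):
            for j in range(2):
                for c in range(2):
                    expect[n, i, j, c] = u[n, i, j, c] * s[c]
    assert np.allclose(out, expect, atol=1e-5)


# --------------------------------------------------------------------------
# spatial attention
# --------------------------------------------------------------------------

def test_spatial_attention_zero_weights_is_half_everywhere():
    rng = np.random.default_rng(5)
    sa = zero_params(SpatialAttention(2, divisor=2, rng=rng))
    u = np.zeros((1, 4, 4, 2))
    m = spatial_attention(u, sa).data
    assert m.shape == (1, 4, 4, 1)
    assert np.allclose(m, 0.5)


def test_spatial_attention_range_and_loop_oracle():
    rng = np.random.default_rng(6)
    sa = SpatialAttention(1, divisor=1, rng=rng, kernel=3)
    u = np.random.default_rng(7).normal(size=(1, 5, 5, 1))
    m = spatial_attention(u, sa).data
    assert m.min() > 0 and m.max() < 1

    v1 = leaky(conv_loop(u, sa.conv1.w.data, sa.conv1.b.data))
    expect = sigmoid(conv_loop(v1, sa.conv2.w.data, sa.conv2.b.data))
    assert np.allclose(m, expect, atol=1e-5)


# --------------------------------------------------------------------------
# CBAM
# --------------------------------------------------------------------------

def test_cbam_zero_weights_quarter_gate_and_magnitude_bound():
    rng = np.random.default_rng(8)
    block = zero_params(CBAM(4, reduction=2, spatial_divisor=2, rng=rng))
    u = np.random.default_rng(9).normal(size=(1, 4, 4, 4))
    out = cbam(u, block).data
    assert np.allclose(out, 0.25 * u, atol=1e-7)

    block2 = CBAM(4, reduction=2, spatial_divisor=2, rng=np.random.default_rng(10))
    out2 = cbam(u, block2).data
    assert np.all(np.abs(out2) <= np.abs(u) + 1e-12)


def test_cbam_equals_composed_oracles():
    rng = np.random.default_rng(11)
    block = CBAM(4, reduction=2, spatial_divisor=2, rng=rng)
    u = np.random.default_rng(12).normal(size=(1, 3, 3, 4))
    out = cbam(u, block).data
    uc = channel_attention(u, block.channel).data
    ms = spatial_attention(uc, block.spatial).data
    assert np.allclose(out, uc * ms, atol=1e-6)


def test_cbam_channel_mismatch_raises():
    block = CBAM(4, reduction=2, spatial_divisor=2, rng=np.random.default_rng(0))
    with pytest.raises(ShapeError):
        cbam(np.zeros((1, 4, 4, 3)), block)


# --------------------------------------------------------------------------
# ASPP
# --------------------------------------------------------------------------

def test_aspp_rate1_branch_is_standard_conv():
    rng = np.random.default_rng(13)
    block = ASPP(2, rng=rng, rates=(1,))
    block.eval()  # use identity-initialized running statistics
    x = np.random.default_rng(14).normal(size=(1, 5, 5, 2))
    y = aspp(x, block).data
    branch = conv_loop(x, block.branches[0].w.data, block.branches[0].b.data)
    branch = branch / np.sqrt(1 + block.norms[0].eps)  # BN with mean 0, var 1
    expect = conv_loop(branch, block.fuse.w.data, block.fuse.b.data)
    assert np.allclose(y, expect, atol=1e-5)


def test_aspp_dilated_branch_taps_spaced_pixels():
    rng = np.random.default_rng(15)
    x = np.random.default_rng(16).normal(size=(1, 9, 9, 1))
    w = rng.normal(size=(3, 3, 1, 1))
    out = ag.conv2d(Tensor(x), Tensor(w), dilation=2).data
    centre = sum(x[0, 4 + 2 * (ki - 1), 4 + 2 * (kj - 1), 0] * w[ki, kj, 0, 0]
                 for ki in range(3) for kj in range(3))
    assert np.isclose(out[0, 4, 4, 0], centre)
    assert np.allclose(out, conv_loop(x, w, None, dilation=2), atol=1e-6)


def test_aspp_zero_input_zero_output_and_branch_permutation():
    rng = np.random.default_rng(17)
    block = ASPP(2, rng=rng)
    for b in block.branches + [block.fuse]:
        b.b.data[...] = 0.0
    x = np.zeros((1, 8, 8, 2))
    assert np.allclose(aspp(x, block).data, 0.0)

    x = np.random.default_rng(18).normal(size=(1, 8, 8, 2))
    block.eval()
    y1 = aspp(x, block).data
    order = [2, 0, 3, 1]
    block.branches = [block.branches[i] for i in order]
    block.norms = [block.norms[i] for i in order]
    y2 = aspp(x, block).data
    assert np.allclose(y1, y2, atol=1e-6)  # sum fusion commutes


def test_aspp_rejects_nonpositive_rate():
    with pytest.raises(ValueError):
        ASPP(2, rng=np.random.default_rng(0), rates=(1, 0))


# --------------------------------------------------------------------------
# residual block
# --------------------------------------------------------------------------

def test_residual_block_shapes_and_stride():
    rng = np.random.default_rng(19)
    rb = ResidualBlock(3, 6, rng=rng, stride=2)
    x = np.random.default_rng(20).normal(size=(1, 8, 8, 3)).astype(np.float32)
    assert residual_block(x, rb).shape == (1, 4, 4, 6)
    rb1 = ResidualBlock(3, 6, rng=rng, stride=1)
    assert residual_block(x, rb1).shape == (1, 8, 8, 6)
    with pytest.raises(ShapeError):
        residual_block(np.zeros((1, 7, 7, 3), np.float32), rb)


def test_residual_block_matches_layerwise_oracle():
    rng = np.random.default_rng(21)
    rb = ResidualBlock(2, 3, rng=rng)
    rb.eval()
    x = np.random.default_rng(22).normal(size=(1, 4, 4, 2))

    def bn_eval(v, bn):
        return (v - bn.running_mean) / np.sqrt(bn.running_var + bn.eps) \
            * bn.gamma.data + bn.beta.data

    def sep_loop(v, layer):
        kh, kw, c = layer.dw.data.shape
        n, h, wd, _ = v.shape
        mid = np.zeros_like(v)
        for nn in range(n):
            for i in range(h):
                for j in range(wd):
                    for ci in range(c):
                        acc = layer.db.data[ci]
                        for ki in range(kh):
                            for kj in range(kw):
                                ri, rj = i + ki - 1, j + kj - 1
                                if 0 <= ri < h and 0 <= rj < wd:
                                    acc += v[nn, ri, rj, ci] * layer.dw.data[ki, kj, ci]
                        mid[nn, i, j, ci] = acc
        return conv_loop(mid, layer.pw.data, layer.pb.data)

    h = leaky(sep_loop(bn_eval(x, rb.bn1), rb.conv1))
    h = leaky(sep_loop(bn_eval(h, rb.bn2), rb.conv2))
    short = bn_eval(conv_loop(x, rb.shortcut.w.data, rb.shortcut.b.data), rb.bn_short)
    assert np.allclose(residual_block(x, rb).data, h + short, atol=1e-5)


def test_zero_input_residual_block_depends_only_on_offsets():
    rng = np.random.default_rng(23)
    rb = zero_params(ResidualBlock(2, 2, rng=rng))
    rb.eval()
    out = residual_block(np.zeros((1, 4, 4, 2)), rb).data
    assert np.allclose(out, 0.0)  # all biases/shifts zero -> exactly zero


# --------------------------------------------------------------------------
# attention gate
# --------------------------------------------------------------------------

def test_attention_gate_zero_params_halves_encoder():
    rng = np.random.default_rng(24)
    gate = zero_params(AttentionGate(3, 5, rng=rng))
    enc = np.random.default_rng(25).normal(size=(1, 8, 8, 3))
    dec = np.random.default_rng(26).normal(size=(1, 4, 4, 5))
    out = attention_gate(enc, dec, gate).data
    assert np.allclose(out, 0.5 * enc)


def test_attention_gate_loop_oracle_and_range():
    rng = np.random.default_rng(27)
    gate = AttentionGate(2, 3, rng=rng, inter_channels=2)
    enc = np.random.default_rng(28).normal(size=(1, 4, 4, 2))
    dec = np.random.default_rng(29).normal(size=(1, 2, 2, 3))
    out = attention_gate(enc, dec, gate).data

    enc_proj = conv_loop(enc, gate.theta_enc.w.data, gate.theta_enc.b.data,
                         stride=2)
    dec_proj = conv_loop(dec, gate.theta_dec.w.data, gate.theta_dec.b.data)
    q = leaky(enc_proj + dec_proj)
    g = sigmoid(conv_loop(q, gate.psi.w.data, gate.psi.b.data))
    g_up = ag.upsample_bilinear2x(Tensor(g)).data
    assert g.min() > 0 and g.max() < 1
    assert np.allclose(out, enc * g_up, atol=1e-5)


def test_attention_gate_rejects_mismatched_sizes():
    gate = AttentionGate(2, 3, rng=np.random.default_rng(0))
    with pytest.raises(ShapeError):
        attention_gate(np.zeros((1, 4, 4, 2)), np.zeros((1, 3, 3, 3)), gate)


# --------------------------------------------------------------------------
# stem block
# --------------------------------------------------------------------------

def test_stem_preserves_spatial_size_and_zero_case():
    rng = np.random.default_rng(30)
    stem = StemBlock(1, 4, reduction=2, spatial_divisor=2, rng=rng)
    x = np.random.default_rng(31).normal(size=(1, 8, 8, 1)).astype(np.float32)
    assert stem_block(x, stem).shape == (1, 8, 8, 4)

    zero_params(stem)
    stem.eval()
    out = stem_block(np.zeros((1, 8, 8, 1), np.float32), stem).data
    assert np.allclose(out, 0.0)  # zero merge, quarter-gated zero is zero
    with pytest.raises(ShapeError):
        stem_block(np.zeros((8, 8)), stem)


def test_stem_matches_pathwise_oracle():
    rng = np.random.default_rng(32)
    stem = StemBlock(1, 2, reduction=2, spatial_divisor=2, rng=rng)
    stem.eval()
    x = np.random.default_rng(33).normal(size=(1, 8, 8, 1))

    def bn_eval(v, bn):
        return (v - bn.running_mean) / np.sqrt(bn.running_var + bn.eps) \
            * bn.gamma.data + bn.beta.data

    a = conv_loop(x, stem.conv_a1.w.data, stem.conv_a1.b.data)
    a = conv_loop(leaky(bn_eval(a, stem.bn_a)), stem.conv_a2.w.data,
                  stem.conv_a2.b.data)
    b = conv_loop(x, stem.conv_b.w.data, stem.conv_b.b.data)
    b = ag.max_pool2x2(Tensor(b)).data
    b = ag.upsample_bilinear2x(Tensor(b)).data
    merged = leaky(bn_eval(a + b, stem.bn_merge))
    expect = cbam(merged, stem.cbam).data
    assert np.allclose(stem_block(x, stem).data, expect, atol=1e-5)


def test_blocks_finite_on_extreme_inputs():
    rng = np.random.default_rng(34)
    block = CBAM(3, reduction=1, spatial_divisor=1, rng=rng)
    x = np.random.default_rng(35).uniform(-10, 10, size=(1, 6, 6, 3))
    assert np.isfinite(cbam(x, block).data).all()
    rb = ResidualBlock(3, 4, rng=rng)
    assert np.isfinite(residual_block(x.astype(np.float32), rb).data).all()
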