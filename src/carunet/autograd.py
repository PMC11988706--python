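"""Reverse-mode automatic differentiation and neural-network layers on numpy.

This is the numerical substrate of the package: a small, explicit tape-based
autodiff engine operating on ``numpy`` arrays, plus the handful of layer types
the segmentation architectures need (2-D convolution with dilation and stride,
depthwise-separable convolution, 2x2 transposed convolution, batch
normalization, pooling, and bilinear/nearest upsampling) and the three
optimizers of the training grid (Adam, RMSprop, SGD with momentum).

Feature maps use the NHWC layout: ``(batch, height, width, channels)``.
"Same" padding is used throughout so spatial sizes stay powers of two along
the U-shaped network; a stride-2 convolution on an even-sized input halves it
exactly.

Only the operations the package needs are implemented; the engine is not a
general framework.  Gradient correctness is established by finite-difference
checks in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "as_tensor",
    "add", "sub", "mul", "div", "neg", "power", "log", "sigmoid",
    "leaky_relu", "relu", "clip", "matmul", "reduce_sum", "reduce_mean",
    "reshape", "concat", "conv2d", "depthwise_conv2d", "conv_transpose2x2",
    "max_pool2x2", "upsample_nearest2x", "upsample_bilinear2x",
    "Module", "Conv2d", "SeparableConv2d", "ConvTranspose2x2", "Linear",
    "BatchNorm2d", "SGD", "Adam", "RMSprop",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = _accum(self.grad, np.asarray(grad))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, k):
        return power(self, k)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(acc, g):
    return g.copy() if acc is None else acc + g


def _node(data, parents, backward) -> Tensor:
    """Create a graph node; drops the tape if no parent needs gradients."""
    req = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# --------------------------------------------------------------------------
# Elementwise and reduction primitives
# --------------------------------------------------------------------------

def _operand(x):
    """Split an operand into (tensor-or-None, raw value).

    Python scalars stay scalars so numpy's weak promotion keeps float32
    graphs in float32.
    """
    if isinstance(x, Tensor):
        return x, x.data
    if isinstance(x, (int, float, np.integer, np.floating)):
        return None, x
    t = Tensor(x)
    return t, t.data


def _binary(a, b, fwd, grad_a, grad_b):
    ta, va = _operand(a)
    tb, vb = _operand(b)
    out_data = fwd(va, vb)
    parents = tuple(t for t in (ta, tb) if t is not None)

    def backward(g):
        if ta is not None and ta.requires_grad:
            ta.grad = _accum(ta.grad, _unbroadcast(grad_a(g, va, vb), ta.shape))
        if tb is not None and tb.requires_grad:
            tb.grad = _accum(tb.grad, _unbroadcast(grad_b(g, va, vb), tb.shape))

    return _node(out_data, parents, backward)


def add(a, b):
    return _binary(a, b, lambda x, y: x + y,
                   lambda g, x, y: g, lambda g, x, y: g)


def sub(a, b):
    return _binary(a, b, lambda x, y: x - y,
                   lambda g, x, y: g, lambda g, x, y: -g)


def neg(a):
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, -g)

    return _node(-a.data, (a,), backward)


def mul(a, b):
    return _binary(a, b, lambda x, y: x * y,
                   lambda g, x, y: g * y, lambda g, x, y: g * x)


def div(a, b):
    return _binary(a, b, lambda x, y: x / y,
                   lambda g, x, y: g / y, lambda g, x, y: -g * x / (y * y))


def power(a, k: float):
    """Elementwise power with a constant exponent."""
    a = as_tensor(a)
    out_data = a.data ** k

    def backward(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, g * k * a.data ** (k - 1))

    return _node(out_data, (a,), backward)


def log(a):
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, g / a.data)

    return _node(np.log(a.data), (a,), backward)


def sigmoid(a):
    a = as_tensor(a)
    s = expit(a.data)

    def backward(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, g * s * (1.0 - s))

    return _node(s, (a,), backward)


def leaky_relu(a, negative_slope: float = 0.01):
    a = as_tensor(a)
    pos = a.data >= 0
    out_data = np.where(pos, a.data, negative_slope * a.data)

    def backward(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, np.where(pos, g, negative_slope * g))

    return _node(out_data, (a,), backward)


def relu(a):
    return leaky_relu(a, negative_slope=0.0)


def clip(a, lo: float, hi: float):
    """Clip values; gradient is zero outside the interval (straight-through
    inside)."""
    a = as_tensor(a)
    inside = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, np.where(inside, g, 0.0))

    return _node(np.clip(a.data, lo, hi), (a,), backward)


def matmul(a, b):
    """Matrix product on the last two axes (numpy semantics, 2-D use here)."""
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
        if b.requires_grad:
            b.grad = _accum(b.grad, _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

    return _node(out_data, (a, b), backward)


def reduce_sum(a, axis=None, keepdims: bool = False):
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if a.requires_grad:
            gg = g
            if not keepdims and axis is not None:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                for ax in sorted(ax % a.ndim for ax in axes):
                    gg = np.expand_dims(gg, ax)
            a.grad = _accum(a.grad, np.broadcast_to(gg, a.shape).copy())

    return _node(out_data, (a,), backward)


def reduce_mean(a, axis=None, keepdims: bool = False):
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(reduce_sum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape):
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a.grad = _accum(a.grad, g.reshape(a.shape))

    return _node(a.data.reshape(shape), (a,), backward)


def concat(tensors, axis: int = -1):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    def backward(g):
        pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t.grad = _accum(t.grad, piece)

    return _node(out_data, tuple(tensors), backward)


# --------------------------------------------------------------------------
# Spatial primitives (NHWC)
# --------------------------------------------------------------------------

def _same_pad(k: int, dilation: int) -> int:
    # odd kernels only; symmetric padding keeps "same" semantics for
    # stride 1 and exact halving for stride 2 on even inputs
    return dilation * (k - 1) // 2


def _out_len(n: int, k: int, stride: int, dilation: int, pad: int) -> int:
    return (n + 2 * pad - dilation * (k - 1) - 1) // stride + 1


def conv2d(x, w, b=None, stride: int = 1, dilation: int = 1):
    """2-D convolution, NHWC input, ``(kh, kw, Cin, Cout)`` kernel, same
    padding.

    Implemented as a sum over kernel taps, each tap a strided slice followed
    by a channel-mixing matmul; the backward pass scatters gradients back tap
    by tap.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    kh, kw, cin, cout = w.shape
    if x.shape[-1] != cin:
        raise ValueError(f"conv2d: input has {x.shape[-1]} channels, kernel expects {cin}")
    n, h, wd = x.shape[0], x.shape[1], x.shape[2]
    ph, pw = _same_pad(kh, dilation), _same_pad(kw, dilation)
    ho = _out_len(h, kh, stride, dilation, ph)
    wo = _out_len(wd, kw, stride, dilation, pw)
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))

    def tap_slices(i, j):
        return (slice(None),
                slice(i * dilation, i * dilation + stride * (ho - 1) + 1, stride),
                slice(j * dilation, j * dilation + stride * (wo - 1) + 1, stride),
                slice(None))

    out_data = np.zeros((n, ho, wo, cout), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            out_data += xp[tap_slices(i, j)] @ w.data[i, j]
    if b is not None:
        out_data = out_data + b.data

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[tap_slices(i, j)] += g @ w.data[i, j].T
            gx = gxp[:, ph:ph + h, pw:pw + wd, :] if (ph or pw) else gxp
            x.grad = _accum(x.grad, gx)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    gw[i, j] = np.tensordot(xp[tap_slices(i, j)], g,
                                            axes=([0, 1, 2], [0, 1, 2]))
            w.grad = _accum(w.grad, gw)
        if b is not None and b.requires_grad:
            b.grad = _accum(b.grad, g.sum(axis=(0, 1, 2)))

    return _node(out_data, parents, backward)


def depthwise_conv2d(x, w, b=None, stride: int = 1, dilation: int = 1):
    """Depthwise 2-D convolution: one ``(kh, kw)`` filter per channel.

    Kernel shape is ``(kh, kw, C)``; each channel is convolved independently.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    kh, kw, c = w.shape
    if x.shape[-1] != c:
        raise ValueError(f"depthwise_conv2d: input has {x.shape[-1]} channels, kernel expects {c}")
    n, h, wd = x.shape[0], x.shape[1], x.shape[2]
    ph, pw = _same_pad(kh, dilation), _same_pad(kw, dilation)
    ho = _out_len(h, kh, stride, dilation, ph)
    wo = _out_len(wd, kw, stride, dilation, pw)
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))

    def tap_slices(i, j):
        return (slice(None),
                slice(i * dilation, i * dilation + stride * (ho - 1) + 1, stride),
                slice(j * dilation, j * dilation + stride * (wo - 1) + 1, stride),
                slice(None))

    out_data = np.zeros((n, ho, wo, c), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            out_data += xp[tap_slices(i, j)] * w.data[i, j]
    if b is not None:
        out_data = out_data + b.data

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[tap_slices(i, j)] += g * w.data[i, j]
            gx = gxp[:, ph:ph + h, pw:pw + wd, :] if (ph or pw) else gxp
            x.grad = _accum(x.grad, gx)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    gw[i, j] = (xp[tap_slices(i, j)] * g).sum(axis=(0, 1, 2))
            w.grad = _accum(w.grad, gw)
        if b is not None and b.requires_grad:
            b.grad = _accum(b.grad, g.sum(axis=(0, 1, 2)))

    return _node(out_data, parents, backward)


def conv_transpose2x2(x, w, b=None):
    """2x2 stride-2 transposed convolution (exact spatial doubling).

    Kernel shape ``(2, 2, Cin, Cout)``; every input pixel paints a 2x2 output
    patch.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    n, h, wd, cin = x.shape
    cout = w.shape[-1]
    y6 = np.einsum("nhwc,abco->nhawbo", x.data, w.data)
    out_data = y6.reshape(n, 2 * h, 2 * wd, cout)
    if b is not None:
        out_data = out_data + b.data

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g6 = g.reshape(n, h, 2, wd, 2, cout)
        if x.requires_grad:
            x.grad = _accum(x.grad, np.einsum("nhawbo,abco->nhwc", g6, w.data))
        if w.requires_grad:
            w.grad = _accum(w.grad, np.einsum("nhwc,nhawbo->abco", x.data, g6))
        if b is not None and b.requires_grad:
            b.grad = _accum(b.grad, g.sum(axis=(0, 1, 2)))

    return _node(out_data, parents, backward)


def max_pool2x2(x):
    """2x2 max pooling with stride 2 (even spatial sizes required)."""
    x = as_tensor(x)
    n, h, wd, c = x.shape
    if h % 2 or wd % 2:
        raise ValueError(f"max_pool2x2: spatial size ({h}, {wd}) must be even")
    xr = x.data.reshape(n, h // 2, 2, wd // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    flat = xr.reshape(n, h // 2, wd // 2, c, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gx = gflat.reshape(n, h // 2, wd // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
            x.grad = _accum(x.grad, gx.reshape(n, h, wd, c))

    return _node(out_data, (x,), backward)


def upsample_nearest2x(x):
    x = as_tensor(x)
    out_data = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def backward(g):
        if x.requires_grad:
            n, h2, w2, c = g.shape
            gs = g.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))
            x.grad = _accum(x.grad, gs)

    return _node(out_data, (x,), backward)


def _bilinear_up_axis(a: np.ndarray, axis: int) -> np.ndarray:
    """Double one spatial axis with half-pixel-centre bilinear weights.

    Output sample 2i sits at input coordinate i - 1/4 (weights 3/4, 1/4 on
    neighbours i, i-1), sample 2i+1 at i + 1/4 (weights 3/4, 1/4 on i, i+1);
    edges clamp.
    """
    a = np.moveaxis(a, axis, 0)
    prev = np.concatenate([a[:1], a[:-1]], axis=0)
    nxt = np.concatenate([a[1:], a[-1:]], axis=0)
    even = 0.75 * a + 0.25 * prev
    odd = 0.75 * a + 0.25 * nxt
    out = np.empty((2 * a.shape[0],) + a.shape[1:], dtype=a.dtype)
    out[0::2] = even
    out[1::2] = odd
    return np.moveaxis(out, 0, axis)


def _bilinear_up_axis_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, 0)
    ge, go = g[0::2], g[1::2]
    ga = 0.75 * ge + 0.75 * go
    # 0.25 weight of even sample 2i on input i-1
    ga[:-1] += 0.25 * ge[1:]
    ga[0] += 0.25 * ge[0]
    # 0.25 weight of odd sample 2i+1 on input i+1
    ga[1:] += 0.25 * go[:-1]
    ga[-1] += 0.25 * go[-1]
    return np.moveaxis(ga, 0, axis)


def upsample_bilinear2x(x):
    """Bilinear 2x upsampling with half-pixel centre alignment."""
    x = as_tensor(x)
    out_data = _bilinear_up_axis(_bilinear_up_axis(x.data, 1), 2)

    def backward(g):
        if x.requires_grad:
            gx = _bilinear_up_axis_adjoint(_bilinear_up_axis_adjoint(g, 2), 1)
            x.grad = _accum(x.grad, gx)

    return _node(out_data, (x,), backward)


# --------------------------------------------------------------------------
# Layers
# --------------------------------------------------------------------------

class Module:
    """Base class with recursive parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self):
        """Yield self and all sub-modules depth-first."""
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self):
        """Yield ``(name, Tensor)`` for every trainable parameter."""
        for prefix, mod in self._named_modules():
            for k, v in mod.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    yield (f"{prefix}{k}", v)

    def _named_modules(self, prefix=""):
        yield prefix, self
        for k, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{k}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self):
        """Yield ``(name, ndarray)`` for non-trainable state (BN statistics)."""
        for prefix, mod in self._named_modules():
            for k in getattr(mod, "_buffers", ()):
                yield (f"{prefix}{k}", getattr(mod, k))

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # Checkpoint support ---------------------------------------------------
    def state_dict(self) -> dict:
        out = {}
        for name, p in self.named_parameters():
            out[name] = p.data.copy()
        for name, b in self.named_buffers():
            out[f"buffer:{name}"] = b.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        buffers = {f"buffer:{name}": (mod, attr)
                   for name, mod, attr in self._buffer_owners()}
        for name, value in state.items():
            if name.startswith("buffer:"):
                mod, attr = buffers[name]
                getattr(mod, attr)[...] = value
            else:
                params[name].data[...] = value

    def _buffer_owners(self):
        for prefix, mod in self._named_modules():
            for k in getattr(mod, "_buffers", ()):
                yield (f"{prefix}{k}", mod, k)


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    std = math.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(dtype), requires_grad=True)


class Conv2d(Module):
    """Standard 2-D convolution layer with bias, same padding."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, dilation: int = 1):
        super().__init__()
        self.stride = stride
        self.dilation = dilation
        self.w = _he_init(rng, (kernel, kernel, cin, cout), kernel * kernel * cin)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def forward(self, x):
        return conv2d(x, self.w, self.b, stride=self.stride, dilation=self.dilation)


class SeparableConv2d(Module):
    """Depthwise 3x3 (or kxk) convolution followed by a pointwise 1x1 mix.

    Parameter cost is ``k*k*Cin`` (depthwise, no bias) + ``Cin*Cout + Cout``
    (pointwise with bias), matching the Keras ``SeparableConv2D`` convention
    with ``use_bias=True`` on the pointwise stage only... both biases are kept
    here: depthwise bias + pointwise bias gives ``k*k*Cin + Cin`` +
    ``Cin*Cout + Cout``.
    """

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1):
        super().__init__()
        self.stride = stride
        self.dw = _he_init(rng, (kernel, kernel, cin), kernel * kernel)
        self.db = Tensor(np.zeros(cin, dtype=np.float32), requires_grad=True)
        self.pw = _he_init(rng, (1, 1, cin, cout), cin)
        self.pb = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def forward(self, x):
        h = depthwise_conv2d(x, self.dw, self.db, stride=self.stride)
        return conv2d(h, self.pw, self.pb)


class ConvTranspose2x2(Module):
    """2x2 stride-2 transposed convolution (classical U-Net upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.w = _he_init(rng, (2, 2, cin, cout), 4 * cin)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def forward(self, x):
        return conv_transpose2x2(x, self.w, self.b)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.w = _he_init(rng, (cin, cout), cin)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        y = matmul(x, self.w)
        return y if self.b is None else add(y, self.b)


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel.

    Trainable affine (gamma, beta); running mean/variance kept as
    non-trainable buffers and used in eval mode.
    """

    _buffers = ("running_mean", "running_var")

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        x = as_tensor(x)
        if self.training:
            m = reduce_mean(x, axis=(0, 1, 2), keepdims=True)
            centered = sub(x, m)
            v = reduce_mean(mul(centered, centered), axis=(0, 1, 2), keepdims=True)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * m.data.ravel()).astype(np.float32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * v.data.ravel()).astype(np.float32)
            inv = power(add(v, self.eps), -0.5)
            xhat = mul(centered, inv)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = mul(sub(x, self.running_mean), inv)
        return add(mul(xhat, self.gamma), self.beta)


# --------------------------------------------------------------------------
# Optimizers
# --------------------------------------------------------------------------

class Optimizer:
    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(Optimizer):
    """SGD with heavy-ball momentum (default 0.9)."""

    def __init__(self, params, lr: float = 0.001, momentum: float = 0.9):
        super().__init__(params, lr)
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v


class Adam(Optimizer):
    def __init__(self, params, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, params, lr: float = 0.001, rho: float = 0.9,
                 eps: float = 1e-7):
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.sq = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, s in zip(self.params, self.sq):
            if p.grad is None:
                continue
            g = p.grad
            s *= self.rho
            s += (1 - self.rho) * g * g
            p.data -= self.lr * g / (np.sqrt(s) + self.eps)
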