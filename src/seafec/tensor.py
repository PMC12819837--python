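"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the primitives the package's convolutional operators
need: broadcasting arithmetic, matmul, 2-D (grouped, strided, dilated)
convolution, count-normalised average pooling, max pooling, adaptive
average pooling, bilinear resampling, batch normalisation, softmax,
sigmoid/ReLU and a fused softmax cross-entropy.  All floating point data
is float32.

Gradients flow through a dynamically built tape: every op records a
closure that scatters the output gradient back to its parents, and
``Tensor.backward`` walks the tape in reverse topological order.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "conv2d",
    "avg_pool2d",
    "max_pool2d",
    "adaptive_avg_pool2d",
    "upsample_bilinear",
    "batch_norm2d",
    "softmax",
    "sigmoid",
    "relu",
    "linear",
    "cross_entropy",
]

_GRAD_ENABLED = True


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference / counting passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_f32(a) -> np.ndarray:
    arr = np.asarray(a, dtype=np.float32)
    return arr


class Tensor:
    """A NumPy array with an optional gradient and tape pointer."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = _accum(self.grad, np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free intermediate activations eagerly
            if node is not self and node._backward is not None and not node.requires_grad:
                node.grad = None

    # -- arithmetic sugar ----------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(cur: np.ndarray | None, new: np.ndarray) -> np.ndarray:
    if cur is None:
        # always own the buffer: the incoming array may be aliased by
        # another node's gradient (e.g. both parents of an add)
        return new.copy()
    cur += new
    return cur


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._backward is not None for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ----------------------------------------------------------------------
# elementwise / shape ops
# ----------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data + b.data

    def backward(g):
        a.grad = _accum(a.grad, _unbroadcast(g, a.data.shape))
        b.grad = _accum(b.grad, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data * b.data

    def backward(g):
        a.grad = _accum(a.grad, _unbroadcast(g * b.data, a.data.shape))
        b.grad = _accum(b.grad, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def reshape(a: Tensor, shape) -> Tensor:
    a = _wrap(a)
    old = a.data.shape
    data = a.data.reshape(shape)

    def backward(g):
        a.grad = _accum(a.grad, g.reshape(old))

    return _make(data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    a = _wrap(a)
    inv = np.argsort(axes)
    data = a.data.transpose(axes)

    def backward(g):
        a.grad = _accum(a.grad, g.transpose(inv))

    return _make(data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t.grad = _accum(t.grad, g[tuple(sl)])

    return _make(data, ts, backward)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            ga = np.broadcast_to(g, a.data.shape)
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            ga = np.broadcast_to(gg, a.data.shape)
        a.grad = _accum(a.grad, ga.astype(np.float32).copy())

    return _make(data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def relu(a: Tensor) -> Tensor:
    a = _wrap(a)
    data = np.maximum(a.data, 0.0)

    def backward(g):
        a.grad = _accum(a.grad, np.where(a.data > 0, g, 0.0).astype(np.float32))

    return _make(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    a = _wrap(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a.grad = _accum(a.grad, (g * data * (1.0 - data)).astype(np.float32))

    return _make(data, (a,), backward)


def softmax(a: Tensor, axis: int) -> Tensor:
    a = _wrap(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        a.grad = _accum(a.grad, (data * (g - dot)).astype(np.float32))

    return _make(data, (a,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    x, w = _wrap(x), _wrap(w)
    data = x.data @ w.data.T
    if b is not None:
        data = data + b.data

    def backward(g):
        x.grad = _accum(x.grad, g @ w.data)
        w.grad = _accum(w.grad, g.T @ x.data)
        if b is not None:
            b.grad = _accum(b.grad, g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a (B, K) batch of logits."""
    logits = _wrap(logits)
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    B = logits.data.shape[0]
    nll = -np.log(np.maximum(p[np.arange(B), labels], 1e-12))
    data = np.float32(nll.mean())

    def backward(g):
        gp = p.copy()
        gp[np.arange(B), labels] -= 1.0
        logits.grad = _accum(logits.grad, (float(g) / B) * gp.astype(np.float32))

    return _make(data, (logits,), backward)


# ----------------------------------------------------------------------
# spatial ops
# ----------------------------------------------------------------------

def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def _pad_input(x: np.ndarray, p: tuple[int, int], mode: str) -> np.ndarray:
    ph, pw = p
    if ph == 0 and pw == 0:
        return x
    if mode == "zeros":
        return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    if mode == "replicate":
        return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)), mode="edge")
    raise ValueError(f"unknown padding mode {mode!r}")


def _unpad_grad(gp: np.ndarray, p: tuple[int, int], shape, mode: str) -> np.ndarray:
    ph, pw = p
    H, W = shape
    if ph == 0 and pw == 0:
        return gp
    if mode == "zeros":
        return gp[:, :, ph : ph + H, pw : pw + W]
    # replicate: fold the padded borders back onto the edge cells
    g = gp[:, :, ph : ph + H, :].copy()
    if ph:
        g[:, :, 0, :] += gp[:, :, :ph, :].sum(axis=2)
        g[:, :, -1, :] += gp[:, :, ph + H :, :].sum(axis=2)
    g2 = g[:, :, :, pw : pw + W].copy()
    if pw:
        g2[:, :, :, 0] += g[:, :, :, :pw].sum(axis=3)
        g2[:, :, :, -1] += g[:, :, :, pw + W :].sum(axis=3)
    return g2


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int | tuple[int, int] = 1,
    padding: int | tuple[int, int] = 0,
    dilation: int | tuple[int, int] = 1,
    groups: int = 1,
    padding_mode: str = "zeros",
) -> Tensor:
    """Grouped, strided, dilated 2-D cross-correlation.

    Computed as k_h*k_w batched GEMMs (one per kernel offset), which keeps
    the peak memory at one feature map instead of a full im2col buffer.
    """
    x, weight = _wrap(x), _wrap(weight)
    B, Cin, H, W = x.data.shape
    Cout, Cin_g, kh, kw = weight.data.shape
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    g = groups
    if Cin_g * g != Cin:
        raise ValueError(f"channel/group mismatch: Cin={Cin}, groups={g}, weight expects {Cin_g * g}")
    Cout_g = Cout // g
    xp = _pad_input(x.data, (ph, pw), padding_mode)
    Hp, Wp = xp.shape[2:]
    Hout = (Hp - dh * (kh - 1) - 1) // sh + 1
    Wout = (Wp - dw * (kw - 1) - 1) // sw + 1
    if Hout < 1 or Wout < 1:
        raise ValueError(f"conv2d: input {H}x{W} too small for kernel {kh}x{kw} d={dh}")
    L = Hout * Wout
    BL = B * L
    wk = weight.data.reshape(g, Cout_g, Cin_g, kh, kw)

    def _slab(arr, rs, cs, cg):
        # (B, C, Hout, Wout) window -> (g, cg, B*L) with batch folded into the GEMM
        s = arr[:, :, rs, cs].reshape(B, g, cg, L)
        return np.ascontiguousarray(s.transpose(1, 2, 0, 3)).reshape(g, cg, BL)

    y = np.zeros((g, Cout_g, BL), dtype=np.float32)
    for u in range(kh):
        rs = slice(u * dh, u * dh + sh * (Hout - 1) + 1, sh)
        for v in range(kw):
            cs = slice(v * dw, v * dw + sw * (Wout - 1) + 1, sw)
            y += wk[:, :, :, u, v] @ _slab(xp, rs, cs, Cin_g)
    y = np.ascontiguousarray(
        y.reshape(g, Cout_g, B, L).transpose(2, 0, 1, 3)
    ).reshape(B, Cout, Hout, Wout)
    if bias is not None:
        y += bias.data.reshape(1, Cout, 1, 1)

    def backward(gy):
        gy_g = np.ascontiguousarray(
            gy.reshape(B, g, Cout_g, L).transpose(1, 2, 0, 3)
        ).reshape(g, Cout_g, BL)
        need_x = x.requires_grad or x._backward is not None
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(wk)
        for u in range(kh):
            rs = slice(u * dh, u * dh + sh * (Hout - 1) + 1, sh)
            for v in range(kw):
                cs = slice(v * dw, v * dw + sw * (Wout - 1) + 1, sw)
                xs = _slab(xp, rs, cs, Cin_g)
                gw[:, :, :, u, v] += gy_g @ xs.transpose(0, 2, 1)
                if need_x:
                    gxs = wk[:, :, :, u, v].transpose(0, 2, 1) @ gy_g
                    gxs = gxs.reshape(g, Cin_g, B, L).transpose(2, 0, 1, 3).reshape(B, Cin, Hout, Wout)
                    gxp[:, :, rs, cs] += gxs
        weight.grad = _accum(weight.grad, gw.reshape(Cout, Cin_g, kh, kw))
        if need_x:
            x.grad = _accum(x.grad, _unpad_grad(gxp, (ph, pw), (H, W), padding_mode))
        if bias is not None:
            bias.grad = _accum(bias.grad, gy.sum(axis=(0, 2, 3)))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(y, parents, backward)


def avg_pool2d(
    x: Tensor,
    kernel: int | tuple[int, int],
    stride: int | tuple[int, int] | None = None,
    padding: int | tuple[int, int] = 0,
    count_include_pad: bool = False,
) -> Tensor:
    """Average pooling; with ``count_include_pad=False`` border windows are
    normalised by the number of valid taps, so constants pool to themselves."""
    x = _wrap(x)
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride if stride is not None else kernel)
    ph, pw = _pair(padding)
    B, C, H, W = x.data.shape
    xp = _pad_input(x.data, (ph, pw), "zeros")
    Hp, Wp = xp.shape[2:]
    Hout = (Hp - kh) // sh + 1
    Wout = (Wp - kw) // sw + 1
    acc = np.zeros((B, C, Hout, Wout), dtype=np.float32)
    for u in range(kh):
        rs = slice(u, u + sh * (Hout - 1) + 1, sh)
        for v in range(kw):
            cs = slice(v, v + sw * (Wout - 1) + 1, sw)
            acc += xp[:, :, rs, cs]
    if count_include_pad or (ph == 0 and pw == 0):
        cnt = np.full((1, 1, Hout, Wout), float(kh * kw), dtype=np.float32)
    else:
        ones = np.zeros((1, 1, Hp, Wp), dtype=np.float32)
        ones[:, :, ph : ph + H, pw : pw + W] = 1.0
        cnt = np.zeros((1, 1, Hout, Wout), dtype=np.float32)
        for u in range(kh):
            rs = slice(u, u + sh * (Hout - 1) + 1, sh)
            for v in range(kw):
                cs = slice(v, v + sw * (Wout - 1) + 1, sw)
                cnt += ones[:, :, rs, cs]
    y = acc / cnt

    def backward(gy):
        gn = gy / cnt
        gxp = np.zeros_like(xp)
        for u in range(kh):
            rs = slice(u, u + sh * (Hout - 1) + 1, sh)
            for v in range(kw):
                cs = slice(v, v + sw * (Wout - 1) + 1, sw)
                gxp[:, :, rs, cs] += gn
        x.grad = _accum(x.grad, gxp[:, :, ph : ph + H, pw : pw + W])

    return _make(y, (x,), backward)


def max_pool2d(x: Tensor, kernel=3, stride=2, padding=1) -> Tensor:
    x = _wrap(x)
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    B, C, H, W = x.data.shape
    xp = np.pad(
        x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)), constant_values=-np.inf
    ).astype(np.float32)
    Hp, Wp = xp.shape[2:]
    Hout = (Hp - kh) // sh + 1
    Wout = (Wp - kw) // sw + 1
    y = np.full((B, C, Hout, Wout), -np.inf, dtype=np.float32)
    arg = np.zeros((B, C, Hout, Wout), dtype=np.int8)
    for idx, (u, v) in enumerate((u, v) for u in range(kh) for v in range(kw)):
        rs = slice(u, u + sh * (Hout - 1) + 1, sh)
        cs = slice(v, v + sw * (Wout - 1) + 1, sw)
        cand = xp[:, :, rs, cs]
        better = cand > y
        y = np.where(better, cand, y)
        arg = np.where(better, np.int8(idx), arg)

    def backward(gy):
        gxp = np.zeros((B, C, Hp, Wp), dtype=np.float32)
        for idx, (u, v) in enumerate((u, v) for u in range(kh) for v in range(kw)):
            rs = slice(u, u + sh * (Hout - 1) + 1, sh)
            cs = slice(v, v + sw * (Wout - 1) + 1, sw)
            gxp[:, :, rs, cs] += np.where(arg == idx, gy, 0.0)
        x.grad = _accum(x.grad, gxp[:, :, ph : ph + H, pw : pw + W])

    return _make(y, (x,), backward)


def adaptive_avg_pool2d(x: Tensor, out_size: int | tuple[int, int]) -> Tensor:
    """Adaptive average pooling with floor/ceil bin edges (torch-compatible)."""
    x = _wrap(x)
    oh, ow = _pair(out_size)
    B, C, H, W = x.data.shape
    if H % oh == 0 and W % ow == 0:
        fh, fw = H // oh, W // ow
        y = x.data.reshape(B, C, oh, fh, ow, fw).mean(axis=(3, 5))

        def backward(gy):
            g = np.broadcast_to(
                gy[:, :, :, None, :, None] / (fh * fw), (B, C, oh, fh, ow, fw)
            ).reshape(B, C, H, W)
            x.grad = _accum(x.grad, g.astype(np.float32).copy())

        return _make(y, (x,), backward)

    hs = [(int(np.floor(i * H / oh)), int(np.ceil((i + 1) * H / oh))) for i in range(oh)]
    ws = [(int(np.floor(j * W / ow)), int(np.ceil((j + 1) * W / ow))) for j in range(ow)]
    y = np.empty((B, C, oh, ow), dtype=np.float32)
    for i, (h0, h1) in enumerate(hs):
        for j, (w0, w1) in enumerate(ws):
            y[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def backward(gy):
        gx = np.zeros((B, C, H, W), dtype=np.float32)
        for i, (h0, h1) in enumerate(hs):
            for j, (w0, w1) in enumerate(ws):
                gx[:, :, h0:h1, w0:w1] += gy[:, :, i, j, None, None] / ((h1 - h0) * (w1 - w0))
        x.grad = _accum(x.grad, gx)

    return _make(y, (x,), backward)


def _bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) interpolation weights, half-pixel centres."""
    M = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    t = (src - lo).astype(np.float32)
    M[np.arange(n_out), lo] += 1.0 - t
    M[np.arange(n_out), hi] += t
    return M


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    x = _wrap(x)
    B, C, H, W = x.data.shape
    oh, ow = size
    if (oh, ow) == (H, W):
        return x
    R = _bilinear_matrix(H, oh)
    Cm = _bilinear_matrix(W, ow)
    xf = x.data.reshape(B * C, H, W)
    y = (R @ xf @ Cm.T).reshape(B, C, oh, ow)

    def backward(gy):
        gf = gy.reshape(B * C, oh, ow)
        gx = (R.T @ gf @ Cm).reshape(B, C, H, W)
        x.grad = _accum(x.grad, gx.astype(np.float32))

    return _make(y, (x,), backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    x = _wrap(x)
    B, C, H, W = x.data.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = B * H * W
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, C, 1, 1)) * inv_std.reshape(1, C, 1, 1)
    y = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

    def backward(gy):
        gamma.grad = _accum(gamma.grad, (gy * xhat).sum(axis=(0, 2, 3)))
        beta.grad = _accum(beta.grad, gy.sum(axis=(0, 2, 3)))
        gh = gy * gamma.data.reshape(1, C, 1, 1)
        if training:
            n = B * H * W
            s1 = gh.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gh * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = (inv_std.reshape(1, C, 1, 1) / n) * (n * gh - s1 - xhat * s2)
        else:
            gx = gh * inv_std.reshape(1, C, 1, 1)
        x.grad = _accum(x.grad, gx.astype(np.float32))

    return _make(y, (x, gamma, beta), backward)
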