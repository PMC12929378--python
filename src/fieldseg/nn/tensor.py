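"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients.  Only the operations needed by the
segmentation network are provided: elementwise arithmetic with broadcasting,
batched matmul, shape manipulation, 2-D (grouped) convolution, max pooling
and nearest-neighbour upsampling.

The engine is CPU-only and favours clarity over generality; convolutions are
lowered to batched matrix multiplies via a strided ``im2col`` view so the
heavy lifting lands in BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "matmul",
    "maxpool2d",
    "upsample_nearest",
    "flop_counter",
]


class _FlopCounter:
    """Global multiply-accumulate counter toggled by :func:`flop_counter`."""

    def __init__(self) -> None:
        self.active = False
        self.macs = 0

    def add(self, macs: int) -> None:
        if self.active:
            self.macs += int(macs)


_FLOPS = _FlopCounter()


class flop_counter:
    """Context manager that counts MACs of conv/matmul ops executed inside."""

    def __enter__(self) -> "flop_counter":
        _FLOPS.active = True
        _FLOPS.macs = 0
        return self

    def __exit__(self, *exc) -> None:
        _FLOPS.active = False

    @property
    def macs(self) -> int:
        return _FLOPS.macs

    @property
    def flops(self) -> int:
        # convention: 1 MAC = 2 FLOPs
        return 2 * _FLOPS.macs


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- plumbing ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=grad.dtype)
        self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other._pow_const(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def _pow_const(self, p: float) -> "Tensor":
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return self._make(out_data, (self,), backward)

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents supported")
        return self._pow_const(float(p))

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = _stable_sigmoid(self.data)

        def backward(g):
            self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def silu(self) -> "Tensor":
        """x * sigmoid(x), the YOLO-family default activation."""
        s = _stable_sigmoid(self.data)
        out_data = self.data * s

        def backward(g):
            self._accum(g * (s + self.data * s * (1.0 - s)))

        return self._make(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def clip(self, lo, hi) -> "Tensor":
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            self._accum(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max_const(self, axis, keepdims: bool = True) -> np.ndarray:
        """Detached max (for numerically stable softmax)."""
        return self.data.max(axis=axis, keepdims=keepdims)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - Tensor(self.max_const(axis=axis))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(out_data, (self,), backward)

    def pad2d(self, ph: int, pw: int, value: float = 0.0) -> "Tensor":
        """Pad the last two axes symmetrically."""
        if ph == 0 and pw == 0:
            return self
        pads = [(0, 0)] * (self.data.ndim - 2) + [(ph, ph), (pw, pw)]
        out_data = np.pad(self.data, pads, constant_values=value)

        def backward(g):
            sl = [slice(None)] * (self.data.ndim - 2)
            sl += [slice(ph, g.shape[-2] - ph), slice(pw, g.shape[-1] - pw)]
            self._accum(g[tuple(sl)])

        return self._make(out_data, (self,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._lift(a), Tensor._lift(b)
    out_data = np.matmul(a.data, b.data)
    _FLOPS.add(out_data.size * a.data.shape[-1])

    def backward(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accum(_unbroadcast(gb, b.data.shape))

    return a._make(out_data, (a, b), backward)


def _im2col_view(x: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    """Strided view (B, C, kh, kw, Ho, Wo) of an already-padded input."""
    B, C, H, W = x.shape
    Ho = (H - kh) // sh + 1
    Wo = (W - kw) // sw + 1
    s = x.strides
    shape = (B, C, kh, kw, Ho, Wo)
    strides = (s[0], s[1], s[2], s[3], s[2] * sh, s[3] * sw)
    return np.lib.stride_tricks.as_strided(x, shape, strides), Ho, Wo


def _col2im(cols: np.ndarray, padded_shape, kh, kw, sh, sw) -> np.ndarray:
    """Scatter-add the inverse of :func:`_im2col_view`."""
    out = np.zeros(padded_shape, dtype=cols.dtype)
    Ho, Wo = cols.shape[-2:]
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += cols[:, :, i, j]
    return out


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """Grouped 2-D cross-correlation. weight: (O, Cin/groups, kh, kw)."""
    x, weight = Tensor._lift(x), Tensor._lift(weight)
    B, C, H, W = x.shape
    O, Cg, kh, kw = weight.shape
    g = groups
    if C != Cg * g or O % g:
        raise ValueError(f"channel mismatch: x has {C}, weight {weight.shape}, groups {g}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    cols, Ho, Wo = _im2col_view(xp, kh, kw, stride, stride)
    # (B, g, Cg*kh*kw, L)
    colsg = np.ascontiguousarray(cols).reshape(B, g, Cg * kh * kw, Ho * Wo)
    wg = weight.data.reshape(g, O // g, Cg * kh * kw)
    out = np.matmul(wg[None], colsg)  # (B, g, O/g, L)
    out = out.reshape(B, O, Ho, Wo)
    _FLOPS.add(B * O * Ho * Wo * Cg * kh * kw)
    if bias is not None:
        out = out + bias.data.reshape(1, O, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(gout):
        gg = gout.reshape(B, g, O // g, Ho * Wo)
        if bias is not None and bias.requires_grad:
            bias._accum(gout.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.matmul(gg, colsg.transpose(0, 1, 3, 2)).sum(axis=0)
            weight._accum(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gcols = np.matmul(wg.transpose(0, 2, 1)[None], gg)  # (B,g,Cg*kh*kw,L)
            gcols = gcols.reshape(B, C, kh, kw, Ho, Wo)
            gx = _col2im(gcols, xp.shape, kh, kw, stride, stride)
            if padding:
                gx = gx[:, :, padding:-padding or None, padding:-padding or None]
            x._accum(gx)

    return x._make(out, parents, backward)


def maxpool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    x = Tensor._lift(x)
    B, C, H, W = x.shape
    if padding:
        xp = np.pad(
            x.data,
            ((0, 0), (0, 0), (padding, padding), (padding, padding)),
            constant_values=-np.inf,
        )
    else:
        xp = x.data
    cols, Ho, Wo = _im2col_view(xp, kernel, kernel, stride, stride)
    colsr = np.ascontiguousarray(cols).reshape(B, C, kernel * kernel, Ho, Wo)
    idx = colsr.argmax(axis=2)
    out = np.take_along_axis(colsr, idx[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        gcols = np.zeros_like(colsr)
        np.put_along_axis(gcols, idx[:, :, None], g[:, :, None], axis=2)
        gcols = gcols.reshape(B, C, kernel, kernel, Ho, Wo)
        gx = _col2im(gcols, xp.shape, kernel, kernel, stride, stride)
        if padding:
            gx = gx[:, :, padding:-padding or None, padding:-padding or None]
        x._accum(gx)

    return x._make(out, (x,), backward)


def upsample_nearest(x: Tensor, scale: int = 2) -> Tensor:
    x = Tensor._lift(x)
    out_data = x.data.repeat(scale, axis=-2).repeat(scale, axis=-1)

    def backward(g):
        B, C, H, W = x.shape
        gx = g.reshape(B, C, H, scale, W, scale).sum(axis=(3, 5))
        x._accum(gx)

    return x._make(out_data, (x,), backward)
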