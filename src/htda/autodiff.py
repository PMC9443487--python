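"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package trains an unrolled spiking network end-to-end (backpropagation
through time with surrogate spike gradients) and differentiates the
classification loss with respect to the *input* for projected-gradient
attacks.  Both need a tape: every operation records its parents and a
closure that accumulates vector-Jacobian products.  The op set is exactly
what the model requires — elementwise arithmetic with broadcasting,
matmul, 2-D (transposed) convolution via im2col/col2im, average pooling,
replicate padding, and a Heaviside step with a rectangular surrogate
window as its backward rule.

Arrays are kept in float64 throughout; gradient-correctness tests rely on
finite differences at ~1e-6 step sizes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "avg_pool2d",
    "pad_replicate1",
    "heaviside_surrogate",
    "relu",
    "sigmoid",
    "exp",
    "log",
    "sqrt",
    "absolute",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array plus the tape bookkeeping for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    # -- graph machinery ------------------------------------------------------

    def _make(self, data, parents, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(p for p in parents if p.requires_grad) if out.requires_grad else ()
        out._backward = backward if out.requires_grad else None
        return out

    def backward(self, grad: np.ndarray | None = None):
        """Accumulate gradients of `self` (a scalar unless `grad` given) into leaves."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order by DFS
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free non-leaf intermediate grads lazily? keep: cheap, clear.

    def _accum(self, g: np.ndarray):
        self.grad = np.asarray(g) if self.grad is None else self.grad + g

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            a._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g, a=self):
            a._accum(g * p * a.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

        return self._make(out_data, (self, other), backward)

    # -- reductions / shaping -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, axis=axis, keepdims=keepdims):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(g, a=self):
            a._accum(g.reshape(a.data.shape))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g, a=self, inv=tuple(inv)):
            a._accum(g.transpose(inv))

        return self._make(out_data, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise nonlinearities ----------------------------------------------


def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)

    def backward(g, a=x, od=out_data):
        a._accum(g * od)

    return x._make(out_data, (x,), backward)


def log(x: Tensor) -> Tensor:
    out_data = np.log(x.data)

    def backward(g, a=x):
        a._accum(g / a.data)

    return x._make(out_data, (x,), backward)


def sqrt(x: Tensor) -> Tensor:
    out_data = np.sqrt(x.data)

    def backward(g, a=x, od=out_data):
        a._accum(g * (0.5 / od))

    return x._make(out_data, (x,), backward)


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)

    def backward(g, a=x):
        a._accum(g * (a.data > 0.0))

    return x._make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # stable in both tails
    out_data = np.empty_like(x.data)
    pos = x.data >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    out_data[~pos] = ex / (1.0 + ex)

    def backward(g, a=x, od=out_data):
        a._accum(g * od * (1.0 - od))

    return x._make(out_data, (x,), backward)


def absolute(x: Tensor) -> Tensor:
    out_data = np.abs(x.data)

    def backward(g, a=x):
        a._accum(g * np.sign(a.data))

    return x._make(out_data, (x,), backward)


def heaviside_surrogate(x: Tensor, window: float) -> Tensor:
    """Spike nonlinearity: forward H(x) with H(0)=1, backward a rectangular window.

    The backward rule is (1/(2a))·1[|x| < a] with half-width ``a = window``,
    the standard surrogate for the threshold-crossing derivative.
    """
    if window <= 0:
        raise ValueError("surrogate window half-width must be positive")
    out_data = (x.data >= 0.0).astype(np.float64)

    def backward(g, a=x, w=float(window)):
        a._accum(g * ((np.abs(a.data) < w) / (2.0 * w)))

    return x._make(out_data, (x,), backward)


def spike_ramp(x: Tensor, window: float) -> Tensor:
    """The integrated surrogate: clip((x + a) / (2a), 0, 1).

    Its exact derivative is the rectangular window (1/(2a))·1[|x| < a], i.e.
    the backward rule of `heaviside_surrogate`.  Swapping this forward in for
    the hard step makes the unrolled objective genuinely differentiable, so
    end-to-end gradients can be validated against finite differences.
    """
    if window <= 0:
        raise ValueError("surrogate window half-width must be positive")
    out_data = np.clip((x.data + window) / (2.0 * window), 0.0, 1.0)

    def backward(g, a=x, w=float(window)):
        a._accum(g * ((np.abs(a.data) < w) / (2.0 * w)))

    return x._make(out_data, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, offs=offsets, axis=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out = tensors[0]._make(out_data, tuple(tensors), backward)
    return out


# -- convolution machinery ----------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int, s: int):
    """xp: padded (N, C, Hp, Wp) -> cols (N, C*kh*kw, Ho*Wo)."""
    n, c, hp, wp = xp.shape
    ho = (hp - kh) // s + 1
    wo = (wp - kw) // s + 1
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(cols: np.ndarray, n: int, c: int, hp: int, wp: int, kh: int, kw: int, s: int, ho: int, wo: int):
    """Adjoint of _im2col: scatter-add cols back onto the padded canvas."""
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    c6 = cols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + s * ho : s, j : j + s * wo : s] += c6[:, :, i, j]
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout; w is (C_out, C_in, kh, kw)."""
    n, cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    p, s = int(padding), int(stride)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    cols, ho, wo = _im2col(xp, kh, kw, s)
    w2 = w.data.reshape(cout, cin * kh * kw)
    y = np.matmul(w2, cols)  # (N, C_out, Ho*Wo)
    if b is not None:
        y = y + b.data.reshape(1, cout, 1)
    y = y.reshape(n, cout, ho, wo)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g, x=x, w=w, b=b, cols=cols, w2=w2, dims=(n, cin, h, wd, kh, kw, p, s, ho, wo, cout)):
        n, cin, h, wd, kh, kw, p, s, ho, wo, cout = dims
        gy = g.reshape(n, cout, ho * wo)
        if b is not None and b.requires_grad:
            b._accum(gy.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.matmul(gy, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = np.matmul(w2.T, gy)  # (N, C*kh*kw, Ho*Wo)
            gxp = _col2im(gcols, n, cin, h + 2 * p, wd + 2 * p, kh, kw, s, ho, wo)
            gx = gxp[:, :, p : p + h, p : p + wd] if p else gxp
            x._accum(gx)

    return x._make(y, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 2, padding: int = 1) -> Tensor:
    """Transposed 2-D convolution (adjoint of conv2d); w is (C_in, C_out, kh, kw).

    Output spatial size: (H - 1)*stride - 2*padding + kh.
    """
    n, cin, h, wd = x.data.shape
    cin_w, cout, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv_transpose2d channel mismatch: input {cin}, weight {cin_w}")
    p, s = int(padding), int(stride)
    hc = (h - 1) * s + kh  # canvas before crop
    wc = (wd - 1) * s + kw
    ho = hc - 2 * p
    wo = wc - 2 * p
    x_flat = x.data.reshape(n, cin, h * wd)
    w2 = w.data.reshape(cin, cout * kh * kw)
    cols = np.matmul(w2.T, x_flat)  # (N, C_out*kh*kw, H*W)
    canvas = _col2im(cols, n, cout, hc, wc, kh, kw, s, h, wd)
    y = canvas[:, :, p : p + ho, p : p + wo] if p else canvas
    if b is not None:
        y = y + b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g, x=x, w=w, b=b, x_flat=x_flat, w2=w2, dims=(n, cin, h, wd, kh, kw, p, s, cout)):
        n, cin, h, wd, kh, kw, p, s, cout = dims
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p))) if p else g
        gcols, hh, ww = _im2col(gp, kh, kw, s)  # (N, C_out*kh*kw, H*W)
        if w.requires_grad:
            gw = np.matmul(x_flat, gcols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gx = np.matmul(w2, gcols)  # (N, C_in, H*W)
            x._accum(gx.reshape(n, cin, h, wd))

    return x._make(y, parents, backward)


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"avg_pool2d: spatial size ({h},{w}) not divisible by {k}")
    out_data = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(g, a=x, k=k):
        gg = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        a._accum(gg)

    return x._make(out_data, (x,), backward)


def pad_replicate1(x: Tensor) -> Tensor:
    """Replicate (edge) padding by one pixel on the two trailing axes."""
    out_data = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="edge")

    def backward(g, a=x):
        gx = g[:, :, 1:-1, 1:-1].copy()
        gx[:, :, 0, :] += g[:, :, 0, 1:-1]
        gx[:, :, -1, :] += g[:, :, -1, 1:-1]
        gx[:, :, :, 0] += g[:, :, 1:-1, 0]
        gx[:, :, :, -1] += g[:, :, 1:-1, -1]
        gx[:, :, 0, 0] += g[:, :, 0, 0]
        gx[:, :, 0, -1] += g[:, :, 0, -1]
        gx[:, :, -1, 0] += g[:, :, -1, 0]
        gx[:, :, -1, -1] += g[:, :, -1, -1]
        a._accum(gx)

    return x._make(out_data, (x,), backward)
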