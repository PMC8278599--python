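"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to train the small convolutional autoencoder in
:mod:`hahnfusion.network`: a :class:`Tensor` wrapping an ndarray, a handful of
elementwise and reduction ops, and a GEMM-based 2-D convolution with an
efficient col2im backward.  Graphs are built eagerly; :meth:`Tensor.backward`
runs a topological sweep.  Everything is deterministic — no op introduces
randomness, so identical seeds give bit-identical training runs.

dtype follows the data you put in: float32 for the network (BLAS sgemm
speed), float64 wherever the loss formulas are checked against hand values.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "avg_pool2x2", "as_tensor"]


class Tensor:
    """An ndarray with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(),
                 _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward(t.grad)

    # -- elementwise arithmetic ------------------------------------------

    def __add__(self, other):
        other = as_tensor(other, like=self)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)
        return Tensor(-self.data, _parents=(self,), _backward=bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other, like=self))

    def __rsub__(self, other):
        return as_tensor(other, like=self) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, like=self)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, like=self)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2,
                                          other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    def __rtruediv__(self, other):
        return as_tensor(other, like=self) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data**(p - 1))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    # -- nonlinearities ---------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def clamp(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(np.clip(self.data, lo, hi), _parents=(self,),
                      _backward=bwd)

    # -- reductions / shape ----------------------------------------------

    def sum(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.shape))

        return Tensor(self.data.sum(), _parents=(self,), _backward=bwd)

    def mean(self):
        n = self.data.size

        def bwd(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g / n, self.shape))

        return Tensor(self.data.mean(), _parents=(self,), _backward=bwd)

    def reshape(self, *shape):
        old = self.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor(self.data.reshape(*shape), _parents=(self,),
                      _backward=bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor(self.data.transpose(axes), _parents=(self,),
                      _backward=bwd)

    def __getitem__(self, idx):
        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accum(full)

        return Tensor(self.data[idx], _parents=(self,), _backward=bwd)


def as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if like is not None else None
    return Tensor(np.asarray(x, dtype=dtype))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient over broadcast dimensions back to `shape`."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


#: reusable scratch buffers keyed by (tag, shape, dtype).  Convolutions in a
#: training loop hit the same shapes every step; recycling the big im2col /
#: col2im buffers avoids ~100 ms of page faults per fresh 100-MB allocation.
#: Tags are per-call-site, so two layers of identical shape never alias.
_WORKSPACE: dict = {}


def _scratch(tag, shape, dtype, zero: bool = False) -> np.ndarray:
    if tag is None:
        return np.zeros(shape, dtype) if zero else np.empty(shape, dtype)
    key = (tag, shape, str(dtype))
    buf = _WORKSPACE.get(key)
    if buf is None:
        buf = np.zeros(shape, dtype)
        _WORKSPACE[key] = buf
    elif zero:
        buf[...] = 0
    return buf


def clear_workspace() -> None:
    _WORKSPACE.clear()


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, tag):
    """(B, Hp, Wp, C) -> (B*Ho*Wo, kh*kw*C) patch matrix.

    Built with kh*kw contiguous shifted copies (channels innermost), which is
    far faster than a transposed sliding-window gather and leaves the GEMM in
    the BLAS-friendly tall-by-skinny shape.
    """
    B, Hp, Wp, C = xp.shape
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    cols = _scratch(tag, (B, Ho, Wo, kh, kw, C), xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, i, j] = xp[:, i:i + Ho * stride:stride,
                                     j:j + Wo * stride:stride]
    return cols.reshape(B * Ho * Wo, kh * kw * C), Ho, Wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, ws: str | None = None) -> Tensor:
    """2-D cross-correlation, NHWC layout, one GEMM per call.

    x: (B, H, W, C); w: (O, C, kh, kw); b: (O,).  Backward reuses the patch
    matrix for the weight gradient and folds the input gradient back with a
    kh*kw-term shifted accumulation (col2im).  `ws` names a workspace slot
    for buffer recycling; callers looping over identical shapes (training)
    should pass a distinct tag per call site.
    """
    B, H, W, C = x.shape
    O, Cw, kh, kw = w.shape
    if C != Cw:
        raise ValueError(f"input has {C} channels but kernel expects {Cw}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if padding:
        # interior write into a zero-initialized pooled pad buffer; the
        # border stays zero across reuses because only the interior changes
        xp = _scratch(ws and ws + ":pad",
                      (B, H + 2 * padding, W + 2 * padding, C), x.data.dtype,
                      zero=(ws is None))
        xp[:, padding:-padding, padding:-padding, :] = x.data
    else:
        xp = x.data
    cols, Ho, Wo = _im2col(xp, kh, kw, stride, ws and ws + ":cols")
    wmat = np.ascontiguousarray(
        w.data.transpose(2, 3, 1, 0).reshape(kh * kw * C, O))
    out = cols @ wmat  # (B*L, O)
    if b is not None:
        out += b.data
    out_data = out.reshape(B, Ho, Wo, O)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gm = np.ascontiguousarray(g.reshape(B * Ho * Wo, O))
        if b is not None and b.requires_grad:
            b._accum(gm.sum(axis=0))
        if w.requires_grad:
            dw = (cols.T @ gm).reshape(kh, kw, C, O)
            w._accum(dw.transpose(3, 2, 0, 1))
        if x.requires_grad:
            dcols_flat = _scratch(ws and ws + ":dcols",
                                  (B * Ho * Wo, kh * kw * C), gm.dtype)
            np.matmul(gm, wmat.T, out=dcols_flat)
            dcols = dcols_flat.reshape(B, Ho, Wo, kh, kw, C)
            dxp = _scratch(ws and ws + ":dxp", xp.shape, xp.dtype, zero=True)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i:i + Ho * stride:stride,
                        j:j + Wo * stride:stride] += dcols[:, :, :, i, j]
            if padding:
                dxp = dxp[:, padding:-padding, padding:-padding, :]
            x._accum(dxp)

    return Tensor(out_data, _parents=parents, _backward=bwd)


def avg_pool2x2(x: Tensor) -> Tensor:
    """2×2 average pooling with stride 2, NHWC (trailing odd row/col dropped)."""
    B, H, W, C = x.shape
    Ho, Wo = H // 2, W // 2
    v = x.data[:, :Ho * 2, :Wo * 2, :].reshape(B, Ho, 2, Wo, 2, C)
    out_data = v.mean(axis=(2, 4))

    def bwd(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            dx[:, :Ho * 2, :Wo * 2, :] = np.repeat(
                np.repeat(g, 2, axis=1), 2, axis=2) / 4.0
            x._accum(dx)

    return Tensor(out_data, _parents=(x,), _backward=bwd)
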