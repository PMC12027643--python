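"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a ``float32`` ndarray together with an optional
gradient and a backward closure.  The op set is exactly what the
segmentation network needs: broadcast arithmetic, matmul, 2-D cross
correlation (stride 1, zero "same" padding, optional channel groups),
2x2 max pooling, bilinear resizing, reductions, and the usual pointwise
nonlinearities.  ``backward()`` runs a topological sweep accumulating
into ``.grad``.
"""

from __future__ import annotations

import functools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "no_grad"]


class _NoGrad:
    """Context manager disabling graph construction (inference mode)."""

    _enabled = True  # True = gradients are being recorded

    def __enter__(self):
        self._prev = _NoGrad._enabled
        _NoGrad._enabled = False
        return self

    def __exit__(self, *exc):
        _NoGrad._enabled = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        if x.dtype == np.float64:  # keep double precision for numeric checks
            return x
        return x.astype(np.float32, copy=False)
    arr = np.asarray(x)
    if arr.dtype == np.float64:
        return arr
    return arr.astype(np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")
    __array_priority__ = 100.0

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _NoGrad._enabled
        self._backward = None
        self._prev: tuple = ()
        self.name = name

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing ------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        req = _NoGrad._enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): _as_array(grad)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and t._backward is None:
                t._accum(g)  # leaf
            if t._backward is not None:
                for parent, pg in zip(t._prev, t._backward(g)):
                    if pg is None or not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    elif parent._backward is None:
                        parent._accum(pg)
                    else:
                        grads[id(parent)] = pg

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bw(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data

        def bw(g):
            return (_unbroadcast(g * b, self.shape), _unbroadcast(g * a, other.shape))

        return self._make(a * b, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data

        def bw(g):
            return (
                _unbroadcast(g / b, self.shape),
                _unbroadcast(-g * a / (b * b), other.shape),
            )

        return self._make(a / b, (self, other), bw)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        a = self.data

        def bw(g):
            return (g * p * np.power(a, p - 1),)

        return self._make(np.power(a, p), (self,), bw)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self.data, other.data
        out = a @ b

        def bw(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(out, (self, other), bw)

    # -- pointwise -----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        a = self.data
        s = np.empty_like(a)
        pos = a >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
        ez = np.exp(a[~pos])
        s[~pos] = ez / (1.0 + ez)
        return self._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def exp(self):
        e = np.exp(self.data)
        return self._make(e, (self,), lambda g: (g * e,))

    def log(self):
        a = self.data
        return self._make(np.log(a), (self,), lambda g: (g / a,))

    def sqrt(self):
        r = np.sqrt(self.data)
        return self._make(r, (self,), lambda g: (g / (2.0 * r),))

    def clip(self, lo: float, hi: float):
        a = self.data
        mask = (a >= lo) & (a <= hi)
        return self._make(np.clip(a, lo, hi), (self,), lambda g: (g * mask,))

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return self._make(self.data.reshape(shape), (self,), lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return self._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(out_data, (self,), bw)

    @staticmethod
    def concat(tensors: list, axis: int = 0) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            return tuple(np.split(g, splits, axis=axis))

        return tensors[0]._make(data, tensors, bw)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, shape).astype(np.float32),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, shape).astype(np.float32),)

        return self._make(out, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max over one axis; ties share the gradient equally."""
        out = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out).astype(np.float32)
        mask /= mask.sum(axis=axis, keepdims=True)
        out_r = out if keepdims else np.squeeze(out, axis=axis)

        def bw(g):
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (g2 * mask,)

        return self._make(out_r, (self,), bw)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        return self._make(s, (self,), bw)

    # -- structured ops ------------------------------------------------
    def pad2d(self, ph: int, pw: int):
        if ph == 0 and pw == 0:
            return self
        data = np.pad(self.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        H, W = self.shape[2], self.shape[3]

        def bw(g):
            return (g[:, :, ph : ph + H, pw : pw + W],)

        return self._make(data, (self,), bw)

    def pad2d_asym(self, top: int, bottom: int, left: int, right: int):
        if not (top or bottom or left or right):
            return self
        data = np.pad(self.data, ((0, 0), (0, 0), (top, bottom), (left, right)))
        H, W = self.shape[2], self.shape[3]

        def bw(g):
            return (g[:, :, top : top + H, left : left + W],)

        return self._make(data, (self,), bw)

    def conv_transpose2x2(self, weight: "Tensor", bias: "Tensor" | None = None):
        """2x2 stride-2 transposed convolution (weight: Cin, Cout, 2, 2)."""
        w = weight.data
        B, cin, H, W = self.shape
        out = np.einsum("bcij,couv->boiujv", self.data, w, optimize=True)
        out = out.reshape(B, w.shape[1], 2 * H, 2 * W)
        if bias is not None:
            out = out + bias.data.reshape(1, -1, 1, 1)

        def bw(g):
            g6 = g.reshape(B, w.shape[1], H, 2, W, 2)
            gx = np.einsum("boiujv,couv->bcij", g6, w, optimize=True)
            gw = np.einsum("boiujv,bcij->couv", g6, self.data, optimize=True)
            gb = g.sum(axis=(0, 2, 3)) if bias is not None else None
            return (gx.astype(g.dtype), gw.astype(g.dtype), gb)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out, parents, bw)

    def conv2d(self, weight: "Tensor", bias: "Tensor" | None = None, groups: int = 1):
        """Stride-1 cross-correlation with zero 'same' padding.

        ``weight`` is (Cout, Cin/groups, kh, kw); spatial extents are
        preserved for odd kernels (strip kernels use kh=1 or kw=1).
        """
        w = weight.data
        cout, cin_g, kh, kw = w.shape
        B, cin, H, W = self.shape
        if cin != cin_g * groups:
            raise ValueError(
                f"conv2d channel mismatch: input has {cin} channels, "
                f"weight expects {cin_g * groups}"
            )
        ph, pw = (kh - 1) // 2, (kw - 1) // 2
        depthwise = groups == cin and cout == cin
        # cache im2col patches while recording gradients: the weight gradient
        # reuses them as a single matmul
        keep = _NoGrad._enabled and (self.requires_grad or weight.requires_grad)
        if depthwise:
            out, win = _dw_corr2d(self.data, w, ph, pw, return_win=keep)
        else:
            out, cols = _corr2d(self.data, w, ph, pw, groups, return_cols=keep)
        if bias is not None:
            out += bias.data.reshape(1, -1, 1, 1)

        def bw(g):
            # grad wrt input: full correlation with flipped, axis-swapped kernel
            wf = w[:, :, ::-1, ::-1]
            g = np.ascontiguousarray(g)
            if depthwise:
                gx, _ = _dw_corr2d(g, wf, kh - 1 - ph, kw - 1 - pw)
                gw = np.einsum("bcijuv,bcij->cuv", win, g, optimize=True)[:, None]
            else:
                wf = wf.reshape(groups, cout // groups, cin_g, kh, kw)
                wf = wf.transpose(0, 2, 1, 3, 4).reshape(cin, cout // groups, kh, kw)
                gx, _ = _corr2d(g, wf, kh - 1 - ph, kw - 1 - pw, groups)
                co_g = cout // groups
                gw = np.empty_like(w)
                for gi in range(groups):
                    gcols = (
                        g[:, gi * co_g : (gi + 1) * co_g]
                        .transpose(0, 2, 3, 1)
                        .reshape(-1, co_g)
                    )
                    gw[gi * co_g : (gi + 1) * co_g] = (
                        (cols[gi].T @ gcols).T.reshape(co_g, cin_g, kh, kw)
                    )
            gb = g.sum(axis=(0, 2, 3)) if bias is not None else None
            return (gx, gw, gb)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out, parents, bw)

    def maxpool2x2(self):
        B, C, H, W = self.shape
        if H % 2 or W % 2:
            raise ValueError(f"maxpool2x2 requires even spatial extents, got {H}x{W}")
        r = self.data.reshape(B, C, H // 2, 2, W // 2, 2)
        out = r.max(axis=(3, 5))
        mask = r == out[:, :, :, None, :, None]
        # resolve ties toward a single argmax so the gradient is a partition
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        mask = (
            (flat & first)
            .reshape(B, C, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
        )

        def bw(g):
            ge = g[:, :, :, None, :, None] * mask
            return (ge.reshape(B, C, H, W).astype(g.dtype),)

        return self._make(out, (self,), bw)

    def bilinear_resize(self, out_h: int, out_w: int):
        """Bilinear interpolation to (out_h, out_w), half-pixel centers."""
        B, C, H, W = self.shape
        if out_h == H and out_w == W:
            return self
        Rh = _interp_matrix(H, out_h)
        Rw = _interp_matrix(W, out_w)

        def apply(a, Mh, Mw):
            t = Mh @ a.reshape(-1, a.shape[2], a.shape[3])  # rows
            t = t @ Mw.T  # cols
            return t.reshape(a.shape[0], a.shape[1], Mh.shape[0], Mw.shape[0])

        out = apply(self.data, Rh, Rw)

        def bw(g):
            return (apply(g, Rh.T, Rw.T),)

        return self._make(out, (self,), bw)


def _corr2d(x: np.ndarray, w: np.ndarray, ph: int, pw: int, groups: int, return_cols: bool = False):
    """im2col + matmul cross-correlation, stride 1.

    Returns ``(out, cols)``; ``cols`` (per group, as (B*Ho*Wo, cin_g*kh*kw))
    is kept only when requested, for reuse by the weight gradient.
    """
    B, cin, H, W = x.shape
    cout, cin_g, kh, kw = w.shape
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Ho, Wo = H + 2 * ph - kh + 1, W + 2 * pw - kw + 1
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # B,cin,Ho,Wo,kh,kw
    out = np.empty((B, cout, Ho, Wo), dtype=x.dtype)
    co_g = cout // groups
    saved = [] if return_cols else None
    for g in range(groups):
        wg = win if groups == 1 else win[:, g * cin_g : (g + 1) * cin_g]
        cols = wg.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, cin_g * kh * kw)
        if return_cols:
            saved.append(cols)
        o = cols @ w[g * co_g : (g + 1) * co_g].reshape(co_g, -1).T
        out[:, g * co_g : (g + 1) * co_g] = o.reshape(B, Ho, Wo, co_g).transpose(
            0, 3, 1, 2
        )
    return out, saved


def _dw_corr2d(x: np.ndarray, w: np.ndarray, ph: int, pw: int, return_win: bool = False):
    """Depthwise cross-correlation (weight: C, 1, kh, kw), stride 1."""
    kh, kw = w.shape[2:]
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # B,C,Ho,Wo,kh,kw
    out = np.einsum("bcijuv,cuv->bcij", win, w[:, 0], optimize=True)
    return out.astype(x.dtype, copy=False), (win if return_win else None)


@functools.lru_cache(maxsize=256)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (half-pixel)."""
    R = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        R[:, 0] = 1.0
        return R
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(np.float32)
    R[np.arange(n_out), lo] += 1.0 - frac
    R[np.arange(n_out), hi] += frac
    return R
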