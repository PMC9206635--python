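"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sized for the fixed encoder/decoder architectures
in this package: dense and strided convolutions (2D and 3D), linear
upsampling, linear layers, elementwise math with broadcasting, reductions,
slicing, softmax, a box filter (for SSIM) and differentiable backward
warping (for the template-deformation decoders). Gradients are accumulated
by topological traversal of the recorded graph.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = ["Tensor", "conv", "upsample_linear", "box_filter", "warp_channels", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over broadcast axes back to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
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

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(out_data, (self,), backward)

    def abs(self):
        out_data = np.abs(self.data)
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def clamp(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(out_data, (self,), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.shape

        def backward(g):
            if self.requires_grad:
                full = np.zeros(shape)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(out_data, (self,), backward)

    # -- reductions & linear algebra -------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def matmul(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    def softmax(self, axis: int = 1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# structured primitives


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def conv(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """N-d convolution (cross-correlation) over channel-first batches.

    ``x``: (B, Cin, *S); ``w``: (Cout, Cin, *K); ``b``: (Cout,).
    Implemented as a sum over kernel offsets of strided slices, which keeps
    both directions of the backward pass simple strided accumulations.
    """
    B, cin = x.shape[:2]
    spatial = x.shape[2:]
    d = len(spatial)
    cout = w.shape[0]
    K = w.shape[2:]
    padw = [(0, 0), (0, 0)] + [(pad, pad)] * d
    xp = np.pad(x.data, padw)
    out_sp = tuple((s + 2 * pad - k) // stride + 1 for s, k in zip(spatial, K))
    # im2col view: (B, Cin, *So, *K), strided subsample for the stride
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=tuple(range(2, 2 + d)))
    sub = (slice(None), slice(None)) + (slice(None, None, stride),) * d
    win = win[sub]
    kernel_axes = tuple(range(2 + d, 2 + 2 * d))
    # y[b, o, s] = sum_{c, k} win[b, c, s, k] * w[o, c, k]
    y = np.tensordot(win, w.data, axes=((1,) + kernel_axes, (1,) + tuple(range(2, 2 + d))))
    y = np.moveaxis(y, -1, 1)
    y = np.ascontiguousarray(y)
    y += b.data.reshape((1, cout) + (1,) * d)

    def backward(g):
        if w.requires_grad:
            # dW[o, c, k] = sum_{b, s} g[b, o, s] * win[b, c, s, k]
            spatial_axes = tuple(range(2, 2 + d))
            dw = np.tensordot(g, win, axes=((0,) + spatial_axes, (0,) + spatial_axes))
            w._accum(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for kk in product(*[range(k) for k in K]):
                sl = tuple(
                    slice(kk[i], kk[i] + (out_sp[i] - 1) * stride + 1, stride)
                    for i in range(d)
                )
                wk = w.data[(slice(None), slice(None)) + kk]  # (Cout, Cin)
                contrib = np.tensordot(g, wk, axes=(1, 0))  # (B, *So, Cin)
                dxp[(slice(None), slice(None)) + sl] += np.moveaxis(contrib, -1, 1)
            core = tuple(
                [slice(None), slice(None)] + [slice(pad, pad + s) for s in spatial]
            )
            x._accum(dxp[core])
        if b.requires_grad:
            b._accum(g.sum(axis=(0,) + tuple(range(2, 2 + d))))

    return Tensor._make(y, (x, w, b), backward)


_UPSAMPLE_CACHE: dict[int, np.ndarray] = {}


def _upsample_matrix(n: int) -> np.ndarray:
    """(2n, n) linear-interpolation matrix, half-voxel aligned."""
    M = _UPSAMPLE_CACHE.get(n)
    if M is None:
        out = np.arange(2 * n, dtype=float)
        src = (out + 0.5) / 2.0 - 0.5
        src = np.clip(src, 0.0, n - 1.0)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n - 1)
        frac = src - lo
        M = np.zeros((2 * n, n))
        M[np.arange(2 * n), lo] += 1.0 - frac
        M[np.arange(2 * n), hi] += frac
        _UPSAMPLE_CACHE[n] = M
    return M


def upsample_linear(x: Tensor) -> Tensor:
    """Double every spatial axis of (B, C, *S) by linear interpolation."""
    d = x.ndim - 2
    data = x.data
    mats = []
    for ax in range(d):
        M = _upsample_matrix(data.shape[2 + ax])
        data = np.moveaxis(np.tensordot(M, data, axes=(1, 2 + ax)), 0, 2 + ax)
        mats.append(M)

    def backward(g):
        if not x.requires_grad:
            return
        for ax in reversed(range(d)):
            g = np.moveaxis(np.tensordot(mats[ax].T, g, axes=(1, 2 + ax)), 0, 2 + ax)
        x._accum(g)

    return Tensor._make(data, (x,), backward)


def box_filter(x: Tensor, size: int) -> Tensor:
    """Uniform (box) filter over the spatial axes of (B, C, *S).

    Zero padding, normalized by the full window size; the operator is
    symmetric, so its adjoint is itself.
    """
    from scipy.ndimage import uniform_filter

    d = x.ndim - 2
    sizes = [1, 1] + [size] * d

    def apply(a):
        return uniform_filter(a, size=sizes, mode="constant", cval=0.0)

    out = apply(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(apply(g))

    return Tensor._make(out, (x,), backward)


def _interp_gather(img: np.ndarray, idx_flat: np.ndarray) -> np.ndarray:
    """Gather (B, C, V) values from (B, C, *S) at flat spatial index (B, V)."""
    B, C = img.shape[:2]
    flat = img.reshape(B, C, -1)
    return np.take_along_axis(flat, idx_flat[:, None, :], axis=2)


def warp_channels(img: Tensor, phi: Tensor) -> Tensor:
    """Differentiable backward warp ``out(v) = img(v + phi(v))``.

    ``img``: (B, C, *S) (or (1, C, *S), broadcast over the batch);
    ``phi``: (B, d, *S) voxel-unit displacements. Linear interpolation with
    coordinate clamping at the grid edge. Differentiable in both arguments.
    """
    B = phi.shape[0]
    d = phi.shape[1]
    spatial = phi.shape[2:]
    C = img.shape[1]
    img_data = np.broadcast_to(img.data, (B, C) + spatial)

    base = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in spatial], indexing="ij")
    )
    coords = base[None] + phi.data  # (B, d, *S)
    upper = np.array(spatial, dtype=float) - 1.0
    clipped = np.clip(coords, 0.0, upper.reshape((1, d) + (1,) * d))
    in_range = (coords > 0.0) & (coords < upper.reshape((1, d) + (1,) * d))
    f = np.floor(clipped)
    frac = clipped - f
    f = f.astype(int)

    strides = np.ones(d, dtype=int)
    for i in range(d - 2, -1, -1):
        strides[i] = strides[i + 1] * spatial[i + 1]

    V = int(np.prod(spatial))
    out = np.zeros((B, C, V))
    corner_cache = []
    for offs in product((0, 1), repeat=d):
        idx = np.zeros((B, V), dtype=int)
        w = np.ones((B, V))
        wfac = []  # per-axis weight factors for the phi gradient
        for ax in range(d):
            o = offs[ax]
            pos = np.minimum(f[:, ax] + o, int(upper[ax])).reshape(B, V)
            idx += pos * strides[ax]
            fa = frac[:, ax].reshape(B, V)
            factor = fa if o == 1 else 1.0 - fa
            wfac.append((factor, 1.0 if o == 1 else -1.0))
            w *= factor
        vals = _interp_gather(img_data, idx)  # (B, C, V)
        out += vals * w[:, None, :]
        corner_cache.append((idx, w, wfac, vals))

    out = out.reshape((B, C) + spatial)

    def backward(g):
        gf = g.reshape(B, C, V)
        if img.requires_grad:
            dimg = np.zeros((B, C, V))
            for idx, w, _, _ in corner_cache:
                contrib = gf * w[:, None, :]
                np.add.at(
                    dimg,
                    (np.arange(B)[:, None, None], np.arange(C)[None, :, None], idx[:, None, :]),
                    contrib,
                )
            dimg = dimg.reshape((B, C) + spatial)
            img._accum(_unbroadcast(dimg, img.shape))
        if phi.requires_grad:
            dphi = np.zeros((B, d, V))
            for idx, w, wfac, vals in corner_cache:
                gv = (gf * vals).sum(axis=1)  # (B, V)
                for ax in range(d):
                    others = np.ones((B, V))
                    for ax2 in range(d):
                        if ax2 != ax:
                            others *= wfac[ax2][0]
                    dphi[:, ax] += gv * others * wfac[ax][1]
            mask = in_range.reshape(B, d, V)
            dphi *= mask
            phi._accum(dphi.reshape((B, d) + spatial))

    return Tensor._make(out, (img, phi), backward)
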