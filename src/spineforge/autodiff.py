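"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training core of this package is deliberately dependency-light: a small
tape-based engine with exactly the operations the registration network needs
(dense/convolutional layers, channel gating, nearest upsampling, and a
differentiable trilinear warp).  All arithmetic is float32; gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(DTYPE, copy=False)
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape entry that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._backward is not None for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bw(g):
            a._accumulate(_unbroadcast(g, a.data.shape))
            b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bw(g):
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, Tensor._lift(other)

        def bw(g):
            a._accumulate(g @ b.data.T)
            b._accumulate(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), bw)

    __matmul__ = matmul

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bw)

    def recip(self) -> "Tensor":
        a = self
        out_data = 1.0 / a.data

        def bw(g):
            a._accumulate(-g * out_data * out_data)

        return Tensor._make(out_data, (a,), bw)

    def sin(self) -> "Tensor":
        a = self

        def bw(g):
            a._accumulate(g * np.cos(a.data))

        return Tensor._make(np.sin(a.data), (a,), bw)

    def cos(self) -> "Tensor":
        a = self

        def bw(g):
            a._accumulate(-g * np.sin(a.data))

        return Tensor._make(np.cos(a.data), (a,), bw)

    def tanh(self) -> "Tensor":
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            a._accumulate(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (a,), bw)

    def sigmoid(self) -> "Tensor":
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bw)

    def leaky_relu(self, slope: float = 0.1) -> "Tensor":
        a = self
        mask = a.data > 0
        scale = np.where(mask, DTYPE(1.0), DTYPE(slope))

        def bw(g):
            a._accumulate(g * scale)

        return Tensor._make(a.data * scale, (a,), bw)

    def abs(self) -> "Tensor":
        a = self
        sign = np.sign(a.data)

        def bw(g):
            a._accumulate(g * sign)

        return Tensor._make(np.abs(a.data), (a,), bw)

    # -- reductions and reshaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def bw(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy()
                              if np.ndim(g) else np.full(a.data.shape, g, dtype=DTYPE))
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g2, a.data.shape).astype(DTYPE))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims, dtype=DTYPE), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            ax = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[i] for i in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bw(g):
            a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, axes) -> "Tensor":
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accumulate(np.ascontiguousarray(g.transpose(inv)))

        return Tensor._make(np.ascontiguousarray(a.data.transpose(axes)), (a,), bw)

    def __getitem__(self, idx) -> "Tensor":
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accumulate(full)

        return Tensor._make(a.data[idx].copy(), (a,), bw)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]

    def bw(g):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis).reshape(t.data.shape))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, bw)


# -- convolutions (channels-first, zero 'same'-style padding) ------------------

def _im2colT(x: np.ndarray, kshape: tuple, stride: int, pads: tuple):
    """Transposed column matrix of x (B, Cin, *S): (Cin*prod(K), B*prod(So)).

    Built from one contiguous crop per kernel offset — far cheaper than a
    windowed gather, since each copy moves long contiguous runs.
    """
    nd = x.ndim - 2
    nb, cin = x.shape[:2]
    xp = np.pad(x, [(0, 0), (0, 0)] + [(p, p) for p in pads])
    out_spatial = tuple(
        (x.shape[2 + d] + 2 * pads[d] - kshape[d]) // stride + 1 for d in range(nd))
    n_k = int(np.prod(kshape))
    n_o = int(np.prod(out_spatial))
    colt = np.empty((cin * n_k, nb * n_o), dtype=DTYPE)
    view = colt.reshape(cin, n_k, nb, n_o)
    perm = (1, 0) + tuple(range(2, 2 + nd))
    for j, off in enumerate(np.ndindex(*kshape)):
        sl = tuple(slice(o, o + out_spatial[d] * stride, stride)
                   for d, o in enumerate(off))
        crop = xp[(slice(None), slice(None)) + sl]
        view[:, j] = crop.transpose(perm).reshape(cin, nb, n_o)
    return colt, out_spatial


def _convnd(x: Tensor, w: Tensor, bias: Tensor | None, stride: int, pads: tuple) -> Tensor:
    """Batched N-d cross-correlation: x (B, Cin, *S), w (Cout, Cin, *K)."""
    nd = x.data.ndim - 2
    nb = x.data.shape[0]
    kshape = w.data.shape[2:]
    cout, cin = w.data.shape[:2]
    colt, out_spatial = _im2colT(x.data, kshape, stride, pads)
    wmat = w.data.reshape(cout, -1)
    out = (wmat @ colt).reshape(cout, nb, *out_spatial)
    out = np.ascontiguousarray(np.moveaxis(out, 0, 1))
    if bias is not None:
        out += bias.data.reshape((1, cout) + (1,) * nd)

    parents = [x, w] if bias is None else [x, w, bias]

    def bw(g):
        g2 = np.ascontiguousarray(np.moveaxis(g, 1, 0)).reshape(cout, -1)
        w._accumulate((g2 @ colt.T).reshape(w.data.shape))
        if bias is not None:
            bias._accumulate(g2.sum(axis=1))
        if not (x.requires_grad or x._backward is not None):
            return  # constant input: no input gradient needed
        if stride == 1:
            # dx = full correlation of g with spatially-flipped, axis-swapped w
            wflip = w.data[(slice(None), slice(None)) + (slice(None, None, -1),) * nd]
            w2 = np.ascontiguousarray(np.swapaxes(wflip, 0, 1)).reshape(cin, -1)
            back_pads = tuple(k - 1 - p for k, p in zip(kshape, pads))
            gcolt, _ = _im2colT(g, kshape, 1, back_pads)
            dx = (w2 @ gcolt).reshape(cin, nb, *x.data.shape[2:])
            x._accumulate(np.moveaxis(dx, 0, 1))
        else:
            dcol = (wmat.T @ g2).reshape(cin, *kshape, nb, *out_spatial)
            gxp = np.zeros([nb, cin]
                           + [s + 2 * p for s, p in zip(x.data.shape[2:], pads)],
                           dtype=DTYPE)
            for off in np.ndindex(*kshape):
                sl_x = tuple(slice(o, o + out_spatial[d] * stride, stride)
                             for d, o in enumerate(off))
                src = dcol[(slice(None),) + off]  # (Cin, B, *So)
                gxp[(slice(None), slice(None)) + sl_x] += np.swapaxes(src, 0, 1)
            core = (slice(None), slice(None)) + tuple(
                slice(p, p + s) for p, s in zip(pads, x.data.shape[2:]))
            x._accumulate(gxp[core])

    return Tensor._make(out.astype(DTYPE), parents, bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    """x: (B, Cin, H, W)."""
    return _convnd(x, w, b, stride, (pad, pad))


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    """x: (B, Cin, X, Y, Z)."""
    return _convnd(x, w, b, stride, (pad, pad, pad))


def conv3d_anisotropic(x: Tensor, w: Tensor, b: Tensor | None, pads: tuple) -> Tensor:
    """3-d conv with per-axis padding (for anisotropic kernels), stride 1."""
    return _convnd(x, w, b, 1, tuple(pads))


def upsample_nearest3d(x: Tensor, factor: int = 2) -> Tensor:
    """(B, C, X, Y, Z) -> (B, C, fX, fY, fZ) by voxel replication."""
    a = x
    nb, c, X, Y, Z = x.data.shape
    f = factor
    out = x.data.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)

    def bw(g):
        g8 = g.reshape(nb, c, X, f, Y, f, Z, f)
        a._accumulate(g8.sum(axis=(3, 5, 7)))

    return Tensor._make(out, (a,), bw)


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a soft dependency
    _njit = None


def _warp_kernel_py(tpl, field, out, grad):
    """Trilinear pull-back sample + analytic coordinate gradients.

    tpl is zero-padded by one voxel; out gets the sampled values and grad the
    partials of the sample w.r.t. each displacement component.
    """
    nx, ny, nz = out.shape
    mx = tpl.shape[0] - 1.000001
    my = tpl.shape[1] - 1.000001
    mz = tpl.shape[2] - 1.000001
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                cx = i + field[0, i, j, k] + 1.0
                cy = j + field[1, i, j, k] + 1.0
                cz = k + field[2, i, j, k] + 1.0
                if cx < 0.0 or cy < 0.0 or cz < 0.0 or \
                        cx > mx or cy > my or cz > mz:
                    out[i, j, k] = 0.0
                    grad[0, i, j, k] = 0.0
                    grad[1, i, j, k] = 0.0
                    grad[2, i, j, k] = 0.0
                    continue
                x0 = int(cx); y0 = int(cy); z0 = int(cz)
                fx = cx - x0; fy = cy - y0; fz = cz - z0
                c000 = tpl[x0, y0, z0]; c001 = tpl[x0, y0, z0 + 1]
                c010 = tpl[x0, y0 + 1, z0]; c011 = tpl[x0, y0 + 1, z0 + 1]
                c100 = tpl[x0 + 1, y0, z0]; c101 = tpl[x0 + 1, y0, z0 + 1]
                c110 = tpl[x0 + 1, y0 + 1, z0]; c111 = tpl[x0 + 1, y0 + 1, z0 + 1]
                c00 = c000 * (1 - fz) + c001 * fz
                c01 = c010 * (1 - fz) + c011 * fz
                c10 = c100 * (1 - fz) + c101 * fz
                c11 = c110 * (1 - fz) + c111 * fz
                c0 = c00 * (1 - fy) + c01 * fy
                c1 = c10 * (1 - fy) + c11 * fy
                out[i, j, k] = c0 * (1 - fx) + c1 * fx
                grad[0, i, j, k] = c1 - c0
                grad[1, i, j, k] = (c01 - c00) * (1 - fx) + (c11 - c10) * fx
                grad[2, i, j, k] = (
                    ((c001 - c000) * (1 - fy) + (c011 - c010) * fy) * (1 - fx)
                    + ((c101 - c100) * (1 - fy) + (c111 - c110) * fy) * fx)


_warp_kernel = _njit(cache=True)(_warp_kernel_py) if _njit else _warp_kernel_py
# keyed by id(); the original array is kept in the value so the id stays live
_pad_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _padded_template(template: np.ndarray) -> np.ndarray:
    key = id(template)
    hit = _pad_cache.get(key)
    if hit is not None and hit[0] is template:
        return hit[1]
    tpl = np.pad(np.asarray(template, dtype=DTYPE), 1)
    if len(_pad_cache) > 64:
        _pad_cache.clear()
    _pad_cache[key] = (template, tpl)
    return tpl


def warp3d(template: np.ndarray, field: Tensor) -> Tensor:
    """Differentiable pull-back warp: out(x) = template(x + u(x)).

    ``template`` is a constant (X, Y, Z) volume; ``field`` holds voxel-unit
    displacements with shape (3, X, Y, Z).  Trilinear sampling, zero outside.
    Gradients flow into the field only.
    """
    tpl = _padded_template(template)
    shape = field.data.shape[1:]
    out = np.empty(shape, dtype=DTYPE)
    grad = np.empty((3, *shape), dtype=DTYPE)
    _warp_kernel(tpl, field.data, out, grad)

    def bw(g):
        field._accumulate(grad * g)

    return Tensor._make(out, (field,), bw)
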