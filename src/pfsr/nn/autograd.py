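"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The reconstruction network needs exactly the operations defined here: 3D
convolution (stride 1 and 2, zero padding), leaky ReLU, sigmoid gates,
channel/spatial pooling, concatenation, 3D pixel shuffle, aligned trilinear
2x upsampling and an L1 loss.  Each op records a backward closure on a tape;
``Tensor.backward`` replays the tape in reverse topological order.

Tensors are unbatched and channel-first: feature maps have shape
``(C, D, H, W)``.  Convolutions are evaluated as im2col + GEMM, built from 27
strided slice copies so the hot loop stays inside BLAS; large volumes are
processed in slabs along the first spatial axis to bound the im2col buffer.

Gradients are exact (verified against central finite differences in the test
suite); no approximation is made anywhere in the backward pass.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_GRAD_ENABLED = True

# cap on the im2col buffer (number of float elements) per slab
_COL_BUDGET = 48_000_000


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def backward(self, seed: np.ndarray | None = None):
        """Accumulate gradients of this (scalar) tensor w.r.t. all tape leaves."""
        if seed is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar tensor")
            seed = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS (deep tapes overflow recursion limits)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(seed, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _track(out: Tensor, parents: Iterable[Tensor], backward) -> Tensor:
    """Attach tape metadata if gradients are enabled and any parent needs them."""
    parents = tuple(parents)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents or p._backward for p in parents):
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- elementwise ----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data)
    return _track(out, (a, b), lambda g: ((a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape))))


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data)

    def bwd(g):
        return ((a, _unbroadcast(g * b.data, a.shape)), (b, _unbroadcast(g * a.data, b.shape)))

    return _track(out, (a, b), bwd)


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    pos = x.data >= 0
    out = Tensor(np.where(pos, x.data, slope * x.data))

    def bwd(g):
        return ((x, np.where(pos, g, np.asarray(slope, dtype=g.dtype) * g)),)

    return _track(out, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(y.astype(x.dtype))
    return _track(out, (x,), lambda g: ((x, g * (y * (1.0 - y)).astype(g.dtype)),))


# -- pooling / reductions -------------------------------------------------

def spatial_mean(x: Tensor) -> Tensor:
    """Global average over the spatial axes; output shape (C, 1, 1, 1)."""
    out = Tensor(x.data.mean(axis=(1, 2, 3), keepdims=True))
    n = x.data[0].size

    def bwd(g):
        return ((x, np.broadcast_to(g / n, x.shape).astype(g.dtype)),)

    return _track(out, (x,), bwd)


def channel_mean(x: Tensor) -> Tensor:
    """Mean over the channel axis; output shape (1, D, H, W)."""
    c = x.shape[0]
    out = Tensor(x.data.mean(axis=0, keepdims=True))
    return _track(out, (x,), lambda g: ((x, np.broadcast_to(g / c, x.shape).astype(g.dtype)),))


def channel_max(x: Tensor) -> Tensor:
    """Max over the channel axis; gradient routes to the first arg-max channel."""
    idx = x.data.argmax(axis=0)
    out = Tensor(np.take_along_axis(x.data, idx[None], axis=0))

    def bwd(g):
        gx = np.zeros_like(x.data, dtype=g.dtype)
        np.put_along_axis(gx, idx[None], g, axis=0)
        return ((x, gx),)

    return _track(out, (x,), bwd)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=0))
    sizes = [t.shape[0] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        return tuple((t, g[offsets[i] : offsets[i + 1]]) for i, t in enumerate(tensors))

    return _track(out, tuple(tensors), bwd)


# -- shape ops ------------------------------------------------------------

def pixel_shuffle3d(x: Tensor, r: int) -> Tensor:
    """Rearrange channel groups of size r³ into r-times finer spatial blocks.

    Channel ``c*r³ + (a*r + b)*r + d`` of the input maps to output channel
    ``c`` at spatial offset ``(a, b, d)`` within each r³ block (offset index
    varies fastest along the last spatial axis).  The map is a bijection on
    elements, hence exactly invertible.
    """
    cin, d, h, w = x.shape
    if cin % r**3 != 0:
        raise ValueError(f"channel count {cin} is not divisible by r³ = {r**3}")
    c = cin // r**3
    y = x.data.reshape(c, r, r, r, d, h, w).transpose(0, 4, 1, 5, 2, 6, 3)
    out = Tensor(np.ascontiguousarray(y.reshape(c, d * r, h * r, w * r)))

    def bwd(g):
        gg = g.reshape(c, d, r, h, r, w, r).transpose(0, 2, 4, 6, 1, 3, 5)
        return ((x, np.ascontiguousarray(gg.reshape(cin, d, h, w))),)

    return _track(out, (x,), bwd)


def pixel_unshuffle3d(x: Tensor, r: int) -> Tensor:
    """Exact inverse of :func:`pixel_shuffle3d`."""
    c, dr, hr, wr = x.shape
    if dr % r or hr % r or wr % r:
        raise ValueError("spatial dims must be divisible by r")
    d, h, w = dr // r, hr // r, wr // r
    y = x.data.reshape(c, d, r, h, r, w, r).transpose(0, 2, 4, 6, 1, 3, 5)
    out = Tensor(np.ascontiguousarray(y.reshape(c * r**3, d, h, w)))

    def bwd(g):
        gg = g.reshape(c, r, r, r, d, h, w).transpose(0, 4, 1, 5, 2, 6, 3)
        return ((x, np.ascontiguousarray(gg.reshape(c, dr, hr, wr))),)

    return _track(out, (x,), bwd)


def _up2_axis(a: np.ndarray, axis: int) -> np.ndarray:
    """Aligned 2x linear upsampling along one axis: out[2i]=a[i], out[2i+1]=(a[i]+a[i+1])/2."""
    a = np.moveaxis(a, axis, -1)
    n = a.shape[-1]
    out = np.empty(a.shape[:-1] + (2 * n,), dtype=a.dtype)
    out[..., 0::2] = a
    out[..., 1:-1:2] = 0.5 * (a[..., :-1] + a[..., 1:])
    out[..., -1] = a[..., -1]  # clamped half-step extrapolation
    return np.moveaxis(out, -1, axis)


def _up2_axis_transpose(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, -1)
    geven = g[..., 0::2]
    godd = g[..., 1::2]
    out = geven + 0.5 * godd
    out[..., 1:] += 0.5 * godd[..., :-1]
    out[..., -1] += 0.5 * godd[..., -1]
    return np.moveaxis(out, -1, axis)


def upsample_trilinear2(x: Tensor) -> Tensor:
    """Aligned trilinear 2x upsampling of a (C, D, H, W) feature stack."""
    y = x.data
    for ax in (1, 2, 3):
        y = _up2_axis(y, ax)
    out = Tensor(y)

    def bwd(g):
        for ax in (3, 2, 1):
            g = _up2_axis_transpose(g, ax)
        return ((x, g),)

    return _track(out, (x,), bwd)


# -- convolution ----------------------------------------------------------

def _conv_out_len(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def _im2col_slab(xpad, k, stride, z0, z1, ho, wo):
    """im2col for output-z rows [z0, z1): returns (k³·C, nslab) matrix."""
    c = xpad.shape[0]
    nz = z1 - z0
    col = np.empty((k**3, c, nz, ho, wo), dtype=xpad.dtype)
    i = 0
    for dz in range(k):
        zs = slice(stride * z0 + dz, stride * z0 + dz + stride * (nz - 1) + 1, stride)
        for dy in range(k):
            ys = slice(dy, dy + stride * (ho - 1) + 1, stride)
            for dx in range(k):
                xs = slice(dx, dx + stride * (wo - 1) + 1, stride)
                col[i] = xpad[:, zs, ys, xs]
                i += 1
    return col.reshape(k**3 * c, nz * ho * wo)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int | None = None) -> Tensor:
    """3D cross-correlation with zero padding.

    ``x``: (Cin, D, H, W); ``w``: (Cout, Cin, k, k, k); ``b``: (Cout,) or None.
    Default padding is ``(k-1)//2`` so stride-1 convolutions preserve the
    spatial shape and stride-2 convolutions halve even shapes exactly.
    """
    cout, cin, k, _, _ = w.shape
    if x.shape[0] != cin:
        raise ValueError(f"input has {x.shape[0]} channels, weight expects {cin}")
    if pad is None:
        pad = (k - 1) // 2
    d, h, wd = x.shape[1:]
    do, ho, wo = (_conv_out_len(n, k, stride, pad) for n in (d, h, wd))

    if pad:
        xpad = np.pad(x.data, ((0, 0),) + ((pad, pad),) * 3)
    else:
        xpad = x.data
    wmat = np.ascontiguousarray(w.data.transpose(2, 3, 4, 1, 0).reshape(k**3 * cin, cout).T)

    slab = max(1, min(do, _COL_BUDGET // (k**3 * cin * ho * wo + 1)))
    # a single-slab conv under an active tape caches its im2col matrix for reuse
    cache_col = _GRAD_ENABLED and slab >= do
    col_cache: list[np.ndarray] = []
    y = np.empty((cout, do, ho, wo), dtype=x.dtype)
    for z0 in range(0, do, slab):
        z1 = min(z0 + slab, do)
        col = _im2col_slab(xpad, k, stride, z0, z1, ho, wo)
        if cache_col:
            col_cache.append(col)
        y[:, z0:z1] = (wmat @ col).reshape(cout, z1 - z0, ho, wo)
    if b is not None:
        y += b.data.reshape(-1, 1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gw_mat = np.zeros((cout, k**3 * cin), dtype=g.dtype)
        gxpad = np.zeros(xpad.shape, dtype=g.dtype)
        for z0 in range(0, do, slab):
            z1 = min(z0 + slab, do)
            nz = z1 - z0
            gslab = g[:, z0:z1].reshape(cout, -1)
            col = col_cache[0] if cache_col else _im2col_slab(xpad, k, stride, z0, z1, ho, wo)
            gw_mat += gslab @ col.T.astype(g.dtype, copy=False)
            gcol = (wmat.T.astype(g.dtype, copy=False) @ gslab).reshape(k**3, cin, nz, ho, wo)
            i = 0
            for dz in range(k):
                zs = slice(stride * z0 + dz, stride * z0 + dz + stride * (nz - 1) + 1, stride)
                for dy in range(k):
                    ys = slice(dy, dy + stride * (ho - 1) + 1, stride)
                    for dx in range(k):
                        xs = slice(dx, dx + stride * (wo - 1) + 1, stride)
                        gxpad[:, zs, ys, xs] += gcol[i]
                        i += 1
        gx = gxpad[:, pad : pad + d, pad : pad + h, pad : pad + wd] if pad else gxpad
        gw = gw_mat.T.reshape(k, k, k, cin, cout).transpose(4, 3, 0, 1, 2)
        grads = [(x, gx), (w, np.ascontiguousarray(gw))]
        if b is not None:
            grads.append((b, g.sum(axis=(1, 2, 3))))
        return tuple(grads)

    return _track(Tensor(y), parents, bwd)


# -- loss -----------------------------------------------------------------

def l1_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean absolute error against a constant target."""
    diff = pred.data - np.asarray(target, dtype=pred.dtype)
    out = Tensor(np.asarray(np.abs(diff).mean(), dtype=pred.dtype))

    def bwd(g):
        return ((pred, (g * np.sign(diff) / diff.size).astype(pred.dtype)),)

    return _track(out, (pred,), bwd)
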