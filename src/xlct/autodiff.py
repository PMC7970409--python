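"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a small convolutional residual network trained
with a windowed-SSIM + L1 composite loss: elementwise arithmetic, ReLU,
absolute value, reductions, and stride-1 2D cross-correlation ("conv") via
im2col. Written because no deep-learning framework is available in the
target environment; the API loosely mirrors the familiar tensor/backward
idiom.

All data is float32; gradients are accumulated in float32 as well.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "relu", "mean", "mean_abs"]


class Tensor:
    """Array node in the computation graph.

    ``backward()`` may only be called on a scalar-valued node; gradients are
    accumulated into ``.grad`` of every ancestor with ``requires_grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor) -> None:
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            order.append(node)

        visit(self)
        self.grad = np.array(1.0, dtype=np.float32)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic (same shape, or python/0-d scalar) --------

    def __add__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._bcast_accum(g)
            other._bcast_accum(g)
        return Tensor(self.data + other.data, parents=(self, other),
                      backward=bwd)

    __radd__ = __add__

    def __sub__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._bcast_accum(g)
            other._bcast_accum(-g)
        return Tensor(self.data - other.data, parents=(self, other),
                      backward=bwd)

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._bcast_accum(g * other.data)
            other._bcast_accum(g * self.data)
        return Tensor(self.data * other.data, parents=(self, other),
                      backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            self._bcast_accum(g / other.data)
            other._bcast_accum(-g * out_data / other.data)
        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __neg__(self):
        return self * (-1.0)

    def _bcast_accum(self, g: np.ndarray) -> None:
        """Accumulate, summing over broadcast dimensions."""
        if not self.requires_grad:
            return
        g = np.asarray(g)
        extra = g.ndim - self.data.ndim
        if extra > 0:
            g = g.sum(axis=tuple(range(extra)))
        axes = tuple(i for i, s in enumerate(self.data.shape)
                     if s == 1 and g.shape[i] != 1)
        if axes:
            g = g.sum(axis=axes, keepdims=True)
        self._accumulate(g)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        x._bcast_accum(g * mask)
    return Tensor(np.where(mask, x.data, 0.0), parents=(x,), backward=bwd)


def mean(x: Tensor) -> Tensor:
    n = x.data.size

    def bwd(g):
        x._bcast_accum(np.full(x.data.shape, g / n, dtype=np.float32))
    return Tensor(np.float32(x.data.mean()), parents=(x,), backward=bwd)


def mean_abs(x: Tensor) -> Tensor:
    """Mean absolute value with the 0-subgradient at the kink."""
    n = x.data.size
    s = np.sign(x.data)

    def bwd(g):
        x._bcast_accum(g * s / n)
    return Tensor(np.float32(np.abs(x.data).mean()), parents=(x,),
                  backward=bwd)


# ---------------------------------------------------------------------------
# 2D cross-correlation (the "convolution" of CNN practice), stride 1.
# Channels-last (B, H, W, C) layout throughout: the im2col patch copy and the
# GEMM output are then memory-local, which dominates runtime on small images.

def _im2col(x: np.ndarray, kh: int, kw: int, pad: int):
    """(B, H, W, C) -> ((B·Ho·Wo, kh·kw·C) patches, (B, Ho, Wo)).

    Built from kh·kw contiguous slice copies (fast memcpy path) rather than
    a strided gather; patch order is therefore (kh, kw, C)-major.
    """
    bsz, h, w_, c = x.shape
    if pad:
        xp = np.zeros((bsz, h + 2 * pad, w_ + 2 * pad, c), dtype=x.dtype)
        xp[:, pad:pad + h, pad:pad + w_, :] = x
    else:
        xp = x
    ho, wo = xp.shape[1] - kh + 1, xp.shape[2] - kw + 1
    cols = np.empty((bsz, ho, wo, kh * kw, c), dtype=x.dtype)
    for u in range(kh):
        for v in range(kw):
            cols[:, :, :, u * kw + v, :] = xp[:, u:u + ho, v:v + wo, :]
    return cols.reshape(bsz * ho * wo, kh * kw * c), (bsz, ho, wo)


def _wmat(w: np.ndarray) -> np.ndarray:
    """(Cout, Cin, kh, kw) -> (Cout, kh·kw·Cin), matching _im2col order."""
    return np.ascontiguousarray(w.transpose(0, 2, 3, 1)).reshape(w.shape[0], -1)


def _corr(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Raw correlation of (B,H,W,Cin) with (Cout,Cin,kh,kw) -> (B,Ho,Wo,Cout)."""
    cols, (b, ho, wo) = _im2col(x, w.shape[2], w.shape[3], pad)
    out = cols @ _wmat(w).T
    return out.reshape(b, ho, wo, w.shape[0])


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           pad: int = 1) -> Tensor:
    """Stride-1 2D correlation: x (B,H,W,Cin) with w (Cout,Cin,kh,kw).

    pad=1 with a 3×3 kernel keeps spatial shape ("same"); pad=0 is "valid".
    """
    kh, kw = w.data.shape[2], w.data.shape[3]
    cout, cin = w.data.shape[0], w.data.shape[1]
    cols, (bb, ho, wo) = _im2col(x.data, kh, kw, pad)
    out_data = cols @ _wmat(w.data).T
    if b is not None:
        out_data += b.data
    out_data = out_data.reshape(bb, ho, wo, -1)

    def bwd(g):
        gmat = g.reshape(-1, cout)
        if w.requires_grad:
            dw = (gmat.T @ cols).reshape(cout, kh, kw, cin)
            w._accumulate(dw.transpose(0, 3, 1, 2))
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            w_flip = np.ascontiguousarray(
                w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
            x._bcast_accum(_corr(g, w_flip, pad=kh - 1 - pad))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=bwd)
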