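"""Reverse-mode automatic differentiation on numpy arrays.

A compact tape-based engine providing exactly the operations the
attention-augmented residual network needs: dense/batched matrix products,
2-D convolution (via im2col), batch normalization, max pooling, bilinear
resampling, softmax and cross-entropy.  Tensors carry float32 data; every
op that participates in a graph stores a closure computing the gradients of
its parents.  Gradients of all structured ops are validated against central
finite differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "add",
    "mul",
    "matmul",
    "relu",
    "reshape",
    "transpose",
    "conv2d",
    "batchnorm2d",
    "maxpool2d",
    "global_avg_pool",
    "bilinear_resize",
    "bilinear_resize_array",
    "softmax_lastdim",
    "cross_entropy",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference paths)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """A float32 ndarray plus optional gradient tape metadata."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward_fn: Optional[Callable] = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        track = _grad_enabled and (
            requires_grad or any(p.requires_grad for p in parents)
        )
        self.requires_grad = track
        self._parents = tuple(parents) if track else ()
        self._backward_fn = backward_fn if track else None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None):
        """Backpropagate from this tensor.

        ``grad`` seeds the output gradient; defaults to all-ones (a scalar
        loss passes ``None``).
        """
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
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
        seed = np.ones_like(self.data) if grad is None else np.asarray(grad, np.float32)
        if seed.shape != self.data.shape:
            raise ValueError(f"seed gradient shape {seed.shape} != {self.data.shape}")
        self.grad = seed
        for node in reversed(topo):
            if node._backward_fn is None or node.grad is None:
                continue
            grads = node._backward_fn(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(np.float32, copy=False)
                else:
                    parent.grad = parent.grad + g

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bw(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return Tensor(out_data, parents=(a, b), backward_fn=bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def bw(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return Tensor(out_data, parents=(a, b), backward_fn=bw)


def matmul(a, b) -> Tensor:
    """Matrix product; supports batched operands per numpy semantics."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = np.matmul(a.data, b.data)

    def bw(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return Tensor(out_data, parents=(a, b), backward_fn=bw)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def bw(g):
        return (g * mask,)

    return Tensor(out_data, parents=(x,), backward_fn=bw)


def reshape(x: Tensor, shape) -> Tensor:
    x = _as_tensor(x)
    orig = x.data.shape

    def bw(g):
        return (g.reshape(orig),)

    return Tensor(x.data.reshape(shape), parents=(x,), backward_fn=bw)


def transpose(x: Tensor, axes) -> Tensor:
    x = _as_tensor(x)
    inv = np.argsort(axes)

    def bw(g):
        return (g.transpose(inv),)

    return Tensor(x.data.transpose(axes), parents=(x,), backward_fn=bw)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int):
    """Extract sliding windows: returns (cols, Ho, Wo) with cols of shape
    (B, C*kh*kw, Ho*Wo)."""
    B, C, H, W = x.shape
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(B, C, kh, kw, Ho, Wo),
        strides=(s[0], s[1], s[2], s[3], s[2] * sh, s[3] * sw),
        writeable=False,
    )
    cols = np.ascontiguousarray(windows).reshape(B, C * kh * kw, Ho * Wo)
    return cols, Ho, Wo


def _col2im(dcols: np.ndarray, x_shape, kh, kw, sh, sw, ph, pw, Ho, Wo):
    B, C, H, W = x_shape
    dxp = np.zeros((B, C, H + 2 * ph, W + 2 * pw), dtype=np.float32)
    d6 = dcols.reshape(B, C, kh, kw, Ho, Wo)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += d6[:, :, i, j]
    if ph or pw:
        return dxp[:, :, ph : ph + H, pw : pw + W]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor], stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation with weight (Cout, Cin, kh, kw) and optional bias."""
    x, w = _as_tensor(x), _as_tensor(w)
    Cout, Cin, kh, kw = w.data.shape
    if x.data.ndim != 4 or x.data.shape[1] != Cin:
        raise ValueError(
            f"conv2d input shape {x.data.shape} incompatible with weight {w.data.shape}"
        )
    cols, Ho, Wo = _im2col(x.data, kh, kw, stride, stride, padding, padding)
    wm = w.data.reshape(Cout, Cin * kh * kw)
    out = np.matmul(wm, cols)  # (B, Cout, Ho*Wo)
    if b is not None:
        out = out + b.data[None, :, None]
    B = x.data.shape[0]
    out_data = out.reshape(B, Cout, Ho, Wo)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gm = g.reshape(B, Cout, Ho * Wo)
        dw = np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0).reshape(w.data.shape)
        dcols = np.matmul(wm.T[None], gm)
        dx = _col2im(dcols, x.data.shape, kh, kw, stride, stride, padding, padding, Ho, Wo)
        if b is None:
            return dx, dw
        return dx, dw, gm.sum(axis=(0, 2))

    return Tensor(out_data, parents=parents, backward_fn=bw)


# ---------------------------------------------------------------------------
# normalization / pooling
# ---------------------------------------------------------------------------

def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (B, H, W).

    In training mode batch statistics are used and the running buffers are
    updated in place (exponential moving average, unbiased variance).
    """
    x = _as_tensor(x)
    xd = x.data
    if training:
        m = xd.mean(axis=(0, 2, 3))
        v = xd.var(axis=(0, 2, 3))
        n = xd.shape[0] * xd.shape[2] * xd.shape[3]
        running_mean *= 1 - momentum
        running_mean += momentum * m
        unbiased = v * (n / max(n - 1, 1))
        running_var *= 1 - momentum
        running_var += momentum * unbiased
    else:
        m, v = running_mean, running_var
    ivstd = 1.0 / np.sqrt(v + eps)
    xhat = (xd - m[None, :, None, None]) * ivstd[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bw(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        dxhat = g * gamma.data[None, :, None, None]
        if training:
            n = xd.shape[0] * xd.shape[2] * xd.shape[3]
            iv = ivstd[None, :, None, None]
            mean_dxhat = dxhat.mean(axis=(0, 2, 3))[None, :, None, None]
            mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
            dx = iv * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
        else:
            dx = dxhat * ivstd[None, :, None, None]
        return dx, dgamma, dbeta

    return Tensor(out_data, parents=(x, gamma, beta), backward_fn=bw)


def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    x = _as_tensor(x)
    B, C, H, W = x.data.shape
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2), constant_values=-np.inf)
    Ho = (H + 2 * padding - kernel) // stride + 1
    Wo = (W + 2 * padding - kernel) // stride + 1
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(B, C, kernel, kernel, Ho, Wo),
        strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
        writeable=False,
    )
    wcols = np.ascontiguousarray(windows).reshape(B, C, kernel * kernel, Ho * Wo)
    idx = wcols.argmax(axis=2)
    out_data = np.take_along_axis(wcols, idx[:, :, None, :], axis=2)[:, :, 0, :].reshape(
        B, C, Ho, Wo
    )

    def bw(g):
        dcols = np.zeros((B, C, kernel * kernel, Ho * Wo), dtype=np.float32)
        np.put_along_axis(dcols, idx[:, :, None, :], g.reshape(B, C, 1, Ho * Wo), axis=2)
        dx = _col2im(
            dcols.reshape(B, C * kernel * kernel, Ho * Wo),
            x.data.shape, kernel, kernel, stride, stride, padding, padding, Ho, Wo,
        )
        return (dx,)

    return Tensor(out_data, parents=(x,), backward_fn=bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """Adaptive average pooling to 1x1, flattened to (B, C)."""
    x = _as_tensor(x)
    B, C, H, W = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def bw(g):
        return (np.broadcast_to(g[:, :, None, None] / (H * W), x.data.shape).astype(np.float32),)

    return Tensor(out_data, parents=(x,), backward_fn=bw)


# ---------------------------------------------------------------------------
# bilinear resampling
# ---------------------------------------------------------------------------

def _bilinear_coeffs(n_in: int, n_out: int):
    """Half-pixel-center source coordinates (corner alignment off)."""
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(np.int64)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = (src - i0).astype(np.float32)
    w0 = 1.0 - w1
    return i0, i1, w0, w1


def bilinear_resize_array(x: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of the trailing two axes (pure numpy, no grad)."""
    Ho, Wo = out_hw
    H, W = x.shape[-2], x.shape[-1]
    if (H, W) == (Ho, Wo):
        return x.copy()
    r0, r1, wr0, wr1 = _bilinear_coeffs(H, Ho)
    c0, c1, wc0, wc1 = _bilinear_coeffs(W, Wo)
    top = x[..., r0, :] * wr0[:, None] + x[..., r1, :] * wr1[:, None]
    out = top[..., :, c0] * wc0 + top[..., :, c1] * wc1
    return out.astype(x.dtype, copy=False)


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Differentiable bilinear resize of a (B, C, H, W) tensor."""
    x = _as_tensor(x)
    B, C, H, W = x.data.shape
    Ho, Wo = out_hw
    if Ho <= 0 or Wo <= 0:
        raise ValueError(f"target size must be positive, got {out_hw}")
    if (H, W) == (Ho, Wo):
        def bw_id(g):
            return (g,)
        return Tensor(x.data, parents=(x,), backward_fn=bw_id)
    r0, r1, wr0, wr1 = _bilinear_coeffs(H, Ho)
    c0, c1, wc0, wc1 = _bilinear_coeffs(W, Wo)
    top = x.data[:, :, r0, :] * wr0[None, None, :, None] + x.data[:, :, r1, :] * wr1[None, None, :, None]
    out_data = top[:, :, :, c0] * wc0[None, None, None, :] + top[:, :, :, c1] * wc1[None, None, None, :]

    def bw(g):
        # scatter through columns then rows
        dtop = np.zeros((B, C, Ho, W), dtype=np.float32)
        np.add.at(dtop, (slice(None), slice(None), slice(None), c0), g * wc0[None, None, None, :])
        np.add.at(dtop, (slice(None), slice(None), slice(None), c1), g * wc1[None, None, None, :])
        dx = np.zeros((B, C, H, W), dtype=np.float32)
        np.add.at(dx, (slice(None), slice(None), r0, slice(None)), dtop * wr0[None, None, :, None])
        np.add.at(dx, (slice(None), slice(None), r1, slice(None)), dtop * wr1[None, None, :, None])
        return (dx,)

    return Tensor(out_data.astype(np.float32), parents=(x,), backward_fn=bw)


# ---------------------------------------------------------------------------
# softmax / loss
# ---------------------------------------------------------------------------

def softmax_lastdim(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    a = e / e.sum(axis=-1, keepdims=True)

    def bw(g):
        return (a * (g - (g * a).sum(axis=-1, keepdims=True)),)

    return Tensor(a, parents=(x,), backward_fn=bw)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy, L = -mean_i log softmax(z_i)[y_i]."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data
    B = z.shape[0]
    if labels.shape != (B,):
        raise ValueError(f"labels shape {labels.shape} != ({B},)")
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    nll = lse - z[np.arange(B), labels]
    out_data = np.float32(nll.mean())

    def bw(g):
        p = np.exp(z - zmax)
        p /= p.sum(axis=1, keepdims=True)
        p[np.arange(B), labels] -= 1.0
        return (g * p / B,)

    return Tensor(out_data, parents=(logits,), backward_fn=bw)
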