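"""Minimal reverse-mode automatic differentiation over float32 numpy arrays.

The engine is deliberately small: NCHW tensors, a define-by-run tape, and
exactly the operations a convolutional encoder--decoder needs (strided /
dilated / depthwise convolution, batch normalisation, bilinear resampling,
global pooling, fully connected layers, elementwise nonlinearities and a
softmax cross-entropy head). Everything runs on one CPU through BLAS matmuls.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "concat",
    "conv2d",
    "depthwise_conv2d",
    "global_avg_pool",
    "global_max_pool",
    "resize_bilinear",
    "pad2d",
    "softmax_cross_entropy",
    "softmax2d",
]

_GRAD_ENABLED = True


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


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-topological accumulation starting from this node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # Operator sugar used sparingly in model code.
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(go):
        if a.requires_grad:
            a._accumulate(_unbroadcast(go, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(go, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(go):
        if a.requires_grad:
            a._accumulate(_unbroadcast(go * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(go * a.data, b.data.shape))

    return _node(out_data, (a, b), backward)


def matmul(x: Tensor, w: Tensor) -> Tensor:
    """(N, C) @ (C, O) for fully connected layers."""
    x, w = _as_tensor(x), _as_tensor(w)
    out_data = x.data @ w.data

    def backward(go):
        if x.requires_grad:
            x._accumulate(go @ w.data.T)
        if w.requires_grad:
            w._accumulate(x.data.T @ go)

    return _node(out_data, (x, w), backward)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0).astype(np.float32)

    def backward(go):
        x._accumulate(go * mask)

    return _node(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))

    def backward(go):
        x._accumulate(go * out_data * (1.0 - out_data))

    return _node(out_data, (x,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(go):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * go.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(go[tuple(idx)])

    return _node(out_data, tuple(ts), backward)


def pad2d(x: Tensor, pad: tuple[int, int, int, int]) -> Tensor:
    """Zero-pad an NCHW tensor; pad = (top, bottom, left, right)."""
    x = _as_tensor(x)
    t, b, l, r = pad
    out_data = np.pad(x.data, ((0, 0), (0, 0), (t, b), (l, r)))

    def backward(go):
        h, w = x.data.shape[2:]
        x._accumulate(go[:, :, t : t + h, l : l + w])

    return _node(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# Convolution via sliding windows + BLAS


def _windows(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int) -> np.ndarray:
    """View of padded input with shape (N, C, OH, OW, KH, KW)."""
    eh = (kh - 1) * dilation + 1
    ew = (kw - 1) * dilation + 1
    v = np.lib.stride_tricks.sliding_window_view(xp, (eh, ew), axis=(2, 3))
    return v[:, :, ::stride, ::stride, ::dilation, ::dilation]


def _conv_raw(xp: np.ndarray, w: np.ndarray, stride: int, dilation: int) -> np.ndarray:
    """Cross-correlate padded NCHW input with (O, C, KH, KW) kernel."""
    n, c, _, _ = xp.shape
    o, _, kh, kw = w.shape
    v = _windows(xp, kh, kw, stride, dilation)
    oh, ow = v.shape[2], v.shape[3]
    cols = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * oh * ow, c * kh * kw
    )
    y = cols @ w.reshape(o, c * kh * kw).T
    return y.reshape(n, oh, ow, o).transpose(0, 3, 1, 2)


def _conv_input_grad(
    go: np.ndarray,
    w: np.ndarray,
    x_shape: tuple[int, ...],
    stride: int,
    padding: int,
    dilation: int,
) -> np.ndarray:
    """Gradient of conv2d w.r.t. its input (transposed convolution)."""
    n, c, h, wdt = x_shape
    o, _, kh, kw = w.shape
    oh, ow = go.shape[2], go.shape[3]
    # Zero-stuff the output gradient back onto the stride-1 grid.
    gs = np.zeros((n, o, (oh - 1) * stride + 1, (ow - 1) * stride + 1), dtype=go.dtype)
    gs[:, :, ::stride, ::stride] = go
    ph = dilation * (kh - 1)
    pw = dilation * (kw - 1)
    gsp = np.pad(gs, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    w_t = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    full = _conv_raw(gsp, w_t, stride=1, dilation=dilation)  # (N, C, *, *)
    # Embed into the padded-input frame, then strip the padding.
    dxp = np.zeros((n, c, h + 2 * padding, wdt + 2 * padding), dtype=go.dtype)
    fh = min(full.shape[2], dxp.shape[2])
    fw = min(full.shape[3], dxp.shape[3])
    dxp[:, :, :fh, :fw] = full[:, :, :fh, :fw]
    if padding:
        return dxp[:, :, padding : padding + h, padding : padding + wdt]
    return dxp


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """2-D cross-correlation, NCHW input, (O, C, KH, KW) kernel."""
    x, w = _as_tensor(x), _as_tensor(w)
    if x.data.shape[1] != w.data.shape[1]:
        raise ValueError(
            f"conv2d channel mismatch: input has {x.data.shape[1]}, "
            f"kernel expects {w.data.shape[1]}"
        )
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    out_data = _conv_raw(xp, w.data, stride, dilation)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    kh, kw = w.data.shape[2:]

    def backward(go):
        if b is not None and b.requires_grad:
            b._accumulate(go.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            v = _windows(xp, kh, kw, stride, dilation)
            dw = np.einsum("noij,ncijkl->ockl", go, v, optimize=True)
            w._accumulate(dw.astype(np.float32))
        if x.requires_grad:
            x._accumulate(
                _conv_input_grad(go, w.data, x.data.shape, stride, padding, dilation)
            )

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


def depthwise_conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """Per-channel convolution; kernel shape (C, KH, KW)."""
    x, w = _as_tensor(x), _as_tensor(w)
    c = x.data.shape[1]
    if w.data.shape[0] != c:
        raise ValueError(
            f"depthwise kernel has {w.data.shape[0]} channels, input has {c}"
        )
    kh, kw = w.data.shape[1:]
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    v = _windows(xp, kh, kw, stride, dilation)
    out_data = np.einsum("ncijkl,ckl->ncij", v, w.data, optimize=True).astype(np.float32)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(go):
        if b is not None and b.requires_grad:
            b._accumulate(go.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.einsum("ncij,ncijkl->ckl", go, v, optimize=True)
            w._accumulate(dw.astype(np.float32))
        if x.requires_grad:
            # Reuse the grouped=1 machinery channel-by-channel via a block kernel.
            wg = np.zeros((c, c, kh, kw), dtype=np.float32)
            wg[np.arange(c), np.arange(c)] = w.data
            x._accumulate(
                _conv_input_grad(go, wg, x.data.shape, stride, padding, dilation)
            )

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


# ---------------------------------------------------------------------------
# Pooling and resampling


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C)."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(go):
        x._accumulate(
            np.broadcast_to(go[:, :, None, None] / (h * w), x.data.shape).astype(
                np.float32
            )
        )

    return _node(out_data, (x,), backward)


def global_max_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C); gradient routed to the (first) argmax."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=2)
    out_data = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]

    def backward(go):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[:, :, None], go[:, :, None], axis=2)
        x._accumulate(dflat.reshape(x.data.shape))

    return _node(out_data, (x,), backward)


def _interp_matrix(out_size: int, in_size: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix, half-pixel-centre convention."""
    a = np.zeros((out_size, in_size), dtype=np.float32)
    if in_size == 1:
        a[:, 0] = 1.0
        return a
    scale = in_size / out_size
    src = (np.arange(out_size, dtype=np.float64) + 0.5) * scale - 0.5
    src = np.clip(src, 0.0, in_size - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, in_size - 1)
    frac = (src - i0).astype(np.float32)
    a[np.arange(out_size), i0] += 1.0 - frac
    a[np.arange(out_size), i1] += frac
    return a


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resampling of an NCHW tensor (separable, exact adjoint)."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    ah = _interp_matrix(out_h, h)
    aw = _interp_matrix(out_w, w)
    flat = x.data.reshape(n * c, h, w)
    out_data = (ah @ flat @ aw.T).reshape(n, c, out_h, out_w)

    def backward(go):
        g = go.reshape(n * c, out_h, out_w)
        dx = (ah.T @ g @ aw).reshape(n, c, h, w)
        x._accumulate(dx.astype(np.float32))

    return _node(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# Classification head


def softmax2d(logits: np.ndarray) -> np.ndarray:
    """Plain (non-tape) softmax over the channel axis of an NCHW array."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy; logits (N, K, H, W), integer target (N, H, W)."""
    logits = _as_tensor(logits)
    n, k, h, w = logits.data.shape
    if target.shape != (n, h, w):
        raise ValueError(f"target shape {target.shape} != {(n, h, w)}")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    t = target.astype(np.int64)
    picked = np.take_along_axis(logp, t[:, None, :, :], axis=1)[:, 0]
    out_data = np.array(-picked.mean(), dtype=np.float32)

    def backward(go):
        p = np.exp(logp)
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, t[:, None, :, :], 1.0, axis=1)
        logits._accumulate((p - onehot) * (go / (n * h * w)))

    return _node(out_data, (logits,), backward)
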