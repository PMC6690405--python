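"""Minimal reverse-mode autodiff on NumPy arrays.

Just enough machinery to train the dual-decoder Dense-U-Net on a CPU:
float32 tensors, a dynamic tape, and the handful of ops the architecture
needs (2-D convolution, batch norm, ReLU, average/max pooling, bilinear
resize, channel concatenation, sigmoid, binary cross-entropy with logits).

Convolutions are evaluated as a sum over kernel offsets of strided-slice ×
weight-matrix products (BLAS ``tensordot``), which avoids materialising
im2col buffers and keeps both directions of the pass memory-light.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Tensor:
    """A node on the tape: value, gradient slot, and a local backward rule."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=F32)
        self.grad: np.ndarray | None = None
        self.parents: tuple[Tensor, ...] = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(F32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-propagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node.parents:  # free non-leaf grads early
                node.grad = None


class Parameter(Tensor):
    """A trainable leaf tensor.  ``decay=True`` marks it for L2 weight decay."""

    __slots__ = ("decay",)

    def __init__(self, data, decay=False):
        super().__init__(data, requires_grad=True)
        self.decay = decay


# ---------------------------------------------------------------------------
# ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)
    return Tensor(a.data + b.data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(g * F32(s))
    return Tensor(a.data * F32(s), (a,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)
    return Tensor(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data.astype(np.float64)))
    y = y.astype(F32)
    def backward(g):
        if x.requires_grad:
            x._accumulate(g * y * (1.0 - y))
    return Tensor(y, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])
    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  tuple(tensors), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution, NCHW layout, kernel (Co, Ci, Kh, Kw)."""
    B, Ci, H, W = x.data.shape
    Co, Ci2, Kh, Kw = w.data.shape
    assert Ci == Ci2, (Ci, Ci2)
    s, p = stride, padding
    Ho = (H + 2 * p - Kh) // s + 1
    Wo = (W + 2 * p - Kw) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    out = np.zeros((B, Ho, Wo, Co), dtype=F32)
    for kh in range(Kh):
        for kw in range(Kw):
            xs = xp[:, :, kh:kh + s * Ho:s, kw:kw + s * Wo:s]
            # (B,Ci,Ho,Wo) x (Co,Ci) -> (B,Ho,Wo,Co)
            out += np.tensordot(xs, w.data[:, :, kh, kw], axes=([1], [1]))
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        gl = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # (B,Ho,Wo,Co)
        if b is not None and b.requires_grad:
            b._accumulate(gl.sum(axis=(0, 1, 2)))
        need_x = x.requires_grad
        gx = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(w.data) if w.requires_grad else None
        for kh in range(Kh):
            for kw in range(Kw):
                xs = xp[:, :, kh:kh + s * Ho:s, kw:kw + s * Wo:s]
                if gw is not None:
                    # (B,Ho,Wo,Co)^T . (B,Ci,Ho,Wo) over B,Ho,Wo -> (Co,Ci)
                    gw[:, :, kh, kw] = np.tensordot(
                        gl, xs, axes=([0, 1, 2], [0, 2, 3]))
                if need_x:
                    # (B,Ho,Wo,Co) x (Co,Ci) -> (B,Ho,Wo,Ci)
                    t = np.tensordot(gl, w.data[:, :, kh, kw], axes=([3], [0]))
                    gx[:, :, kh:kh + s * Ho:s, kw:kw + s * Wo:s] += \
                        t.transpose(0, 3, 1, 2)
        if gw is not None:
            w._accumulate(gw)
        if need_x:
            x._accumulate(gx[:, :, p:p + H, p:p + W] if p else gx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out, parents, backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Channel-wise batch normalization (NCHW).  Updates running stats in place."""
    xd = x.data
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = (1.0 / np.sqrt(var + eps)).astype(F32)
    xhat = (xd - mean[None, :, None, None].astype(F32)) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
            if training:
                m = xd.shape[0] * xd.shape[2] * xd.shape[3]
                gmean = g.mean(axis=(0, 2, 3))[None, :, None, None]
                gxhat_mean = (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
                x._accumulate(gs * (g - gmean - xhat * gxhat_mean))
                del m
            else:
                x._accumulate(gs * g)

    return Tensor(out, (x, gamma, beta), backward)


def avg_pool2(x: Tensor) -> Tensor:
    """2×2 average pooling with stride 2 (even spatial dims required)."""
    B, C, H, W = x.data.shape
    assert H % 2 == 0 and W % 2 == 0, (H, W)
    out = x.data.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
    def backward(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * F32(0.25)
            x._accumulate(gx)
    return Tensor(out, (x,), backward)


def max_pool(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    """Max pooling via per-offset running max; the winning offset is cached."""
    B, C, H, W = x.data.shape
    k, s, p = kernel, stride, padding
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                constant_values=-np.inf) if p else x.data
    out = np.full((B, C, Ho, Wo), -np.inf, dtype=F32)
    winner = np.zeros((B, C, Ho, Wo), dtype=np.uint8)
    for i, (kh, kw) in enumerate((a, b) for a in range(k) for b in range(k)):
        xs = xp[:, :, kh:kh + s * Ho:s, kw:kw + s * Wo:s]
        better = xs > out
        out = np.where(better, xs, out)
        winner[better] = i
    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(xp)
        for i, (kh, kw) in enumerate((a, b) for a in range(k) for b in range(k)):
            sel = winner == i
            gx[:, :, kh:kh + s * Ho:s, kw:kw + s * Wo:s] += g * sel
        x._accumulate(gx[:, :, p:p + H, p:p + W] if p else gx)
    return Tensor(out, (x,), backward)


_resize_ops: dict[tuple[int, int], np.ndarray] = {}


def _resize_operator(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation operator (n_out × n_in)."""
    key = (n_in, n_out)
    if key not in _resize_ops:
        op = np.zeros((n_out, n_in), dtype=F32)
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0, n_in - 1)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        t = (src - lo).astype(F32)
        op[np.arange(n_out), lo] += 1 - t
        op[np.arange(n_out), hi] += t
        _resize_ops[key] = op
    return _resize_ops[key]


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize to (out_h, out_w), separable row/column operators."""
    B, C, H, W = x.data.shape
    R = _resize_operator(H, out_h)
    Cop = _resize_operator(W, out_w)
    tmp = np.tensordot(x.data, Cop, axes=([3], [1]))       # (B,C,H,Wo)
    out = np.tensordot(tmp, R, axes=([2], [1]))            # (B,C,Wo,Ho)
    out = np.ascontiguousarray(out.transpose(0, 1, 3, 2))
    def backward(g):
        if x.requires_grad:
            t = np.tensordot(g, R, axes=([2], [0]))        # (B,C,Wo,H)
            gx = np.tensordot(t.transpose(0, 1, 3, 2), Cop, axes=([3], [0]))
            x._accumulate(gx)
    return Tensor(out, (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from pre-sigmoid logits."""
    z = logits.data.astype(np.float64)
    t = np.asarray(targets, dtype=np.float64)
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    n = z.size
    def backward(g):
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-z))
            logits._accumulate((g * (sig - t) / n).astype(F32))
    return Tensor(np.float32(loss), (logits,), backward)
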