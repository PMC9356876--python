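"""A compact reverse-mode autodiff engine on numpy arrays.

Just enough machinery for the two convolutional networks in this package:
tensors carry float32 data and an optional gradient; operations build a
graph of backward closures that :meth:`Tensor.backward` replays in reverse
topological order. Convolutions use im2col/col2im so the heavy lifting is
a single matrix multiply per layer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "relu",
    "add",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "batch_norm2d",
    "softmax_cross_entropy2d",
    "sigmoid_focal_loss",
    "smooth_l1_loss",
]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this (typically scalar) tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def item(self) -> float:
        return float(self.data)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accumulate(g * mask)

    return _node(x.data * mask, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        a._accumulate(g)
        b._accumulate(g)

    return _node(a.data + b.data, (a, b), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _node(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


# --------------------------------------------------------------- im2col core


def _conv_out_size(h, w, kh, kw, stride, pad):
    return (h + 2 * pad - kh) // stride + 1, (w + 2 * pad - kw) // stride + 1


def _im2col(x, kh, kw, stride, pad):
    n, c, h, w = x.shape
    ho, wo = _conv_out_size(h, w, kh, kw, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
    )
    return np.ascontiguousarray(cols).reshape(n, c * kh * kw, ho * wo), (ho, wo)


def _col2im(cols, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    ho, wo = _conv_out_size(h, w, kh, kw, stride, pad)
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                cols[:, :, i, j]
            )
    if pad == 0:
        return xp
    return xp[:, :, pad : pad + h, pad : pad + w]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution; x (N,C,H,W), w (K,C,kh,kw), b (K,)."""
    k, c, kh, kw = w.data.shape
    cols, (ho, wo) = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(k, c * kh * kw)
    out = np.einsum("kp,npq->nkq", wmat, cols).reshape(-1, k, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, k, 1, 1)

    def backward(g):
        gmat = g.reshape(g.shape[0], k, ho * wo)
        w._accumulate(
            np.einsum("nkq,npq->kp", gmat, cols).reshape(w.data.shape)
        )
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        dcols = np.einsum("kp,nkq->npq", wmat, gmat)
        x._accumulate(_col2im(dcols, x.data.shape, kh, kw, stride, pad))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def conv_transpose2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None,
    stride: int = 2,
    pad: int = 1,
    output_padding: int = 1,
) -> Tensor:
    """Transposed convolution; x (N,C,H,W), w (C,K,kh,kw).

    With kernel 3, stride 2, pad 1, output_padding 1 the spatial size
    exactly doubles.
    """
    n, c, h, wdt = x.shape
    _, k, kh, kw = w.data.shape
    ho = (h - 1) * stride - 2 * pad + kh + output_padding
    wo = (wdt - 1) * stride - 2 * pad + kw + output_padding
    wmat = w.data.reshape(c, k * kh * kw)
    xmat = x.data.reshape(n, c, h * wdt)
    cols = np.einsum("cp,ncq->npq", wmat, xmat)
    # scatter columns into the (padded) output grid
    out = _col2im(
        cols,
        (n, k, ho, wo),
        kh,
        kw,
        stride,
        pad,
    )
    if b is not None:
        out = out + b.data.reshape(1, k, 1, 1)

    def backward(g):
        gcols, _ = _im2col(g, kh, kw, stride, pad)
        # im2col of the gradient only covers the first (h, w) grid cells
        gcols = gcols[:, :, : h * wdt]
        w._accumulate(
            np.einsum("ncq,npq->cp", xmat, gcols).reshape(w.data.shape)
        )
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        dx = np.einsum("cp,npq->ncq", wmat, gcols).reshape(x.data.shape)
        x._accumulate(dx)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Channel-wise batch normalization; running stats updated in place."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    std = np.sqrt(var + eps).astype(np.float32)
    xhat = (x.data - mean.reshape(1, -1, 1, 1)) / std.reshape(1, -1, 1, 1)
    out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        gxhat = g * gamma.data.reshape(1, -1, 1, 1)
        if training:
            dx = (
                gxhat
                - gxhat.mean(axis=(0, 2, 3), keepdims=True)
                - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
            ) / std.reshape(1, -1, 1, 1)
        else:
            dx = gxhat / std.reshape(1, -1, 1, 1)
        x._accumulate(dx)

    _ = m
    return _node(out, (x, gamma, beta), backward)


# -------------------------------------------------------------------- losses


def softmax_cross_entropy2d(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy; logits (N,K,H,W), target (N,H,W) int."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n, k, h, w = p.shape
    idx = (
        np.arange(n)[:, None, None],
        target,
        np.arange(h)[None, :, None],
        np.arange(w)[None, None, :],
    )
    loss = -np.log(np.maximum(p[idx], 1e-12)).mean()

    def backward(g):
        onehot = np.zeros_like(p)
        onehot[idx] = 1.0
        logits._accumulate(g * (p - onehot) / (n * h * w))

    return _node(np.float32(loss), (logits,), backward)


def sigmoid_focal_loss(
    logits: Tensor,
    targets: np.ndarray,
    gamma: float = 2.0,
    alpha: float = 0.25,
    weights: np.ndarray | None = None,
    normalizer: float = 1.0,
) -> Tensor:
    """Focal loss on sigmoid logits: -alpha_t (1-p_t)^gamma log p_t.

    ``weights`` masks out ignored anchors; the sum is divided by
    ``normalizer`` (conventionally the positive-anchor count).
    """
    x = logits.data
    t = targets
    p = 1.0 / (1.0 + np.exp(-x))
    pt = np.where(t == 1, p, 1 - p)
    at = np.where(t == 1, alpha, 1 - alpha)
    logpt = np.where(
        t == 1,
        -np.logaddexp(0, -x),  # log sigmoid(x), stable
        -np.logaddexp(0, x),
    )
    w = np.ones_like(p) if weights is None else weights
    loss = -(at * (1 - pt) ** gamma * logpt * w).sum() / normalizer

    def backward(g):
        # d/dx [-(1-pt)^g log pt] with pt = sigmoid(±x)
        sgn = np.where(t == 1, 1.0, -1.0)
        dpt_dx = sgn * p * (1 - p)
        dl_dpt = at * (
            gamma * (1 - pt) ** (gamma - 1) * logpt
            - (1 - pt) ** gamma / np.maximum(pt, 1e-12)
        )
        logits._accumulate(g * (dl_dpt * dpt_dx * w) / normalizer)

    return _node(np.float32(loss), (logits,), backward)


def smooth_l1_loss(
    pred: Tensor,
    target: np.ndarray,
    weights: np.ndarray | None = None,
    normalizer: float = 1.0,
) -> Tensor:
    """Huber-type loss: 0.5 d^2 for |d| < 1, |d| - 0.5 otherwise."""
    d = pred.data - target
    w = np.ones_like(d) if weights is None else weights
    per = np.where(np.abs(d) < 1, 0.5 * d * d, np.abs(d) - 0.5)
    loss = (per * w).sum() / normalizer

    def backward(g):
        grad = np.clip(d, -1, 1) * w / normalizer
        pred._accumulate(g * grad)

    return _node(np.float32(loss), (pred,), backward)
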