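"""Minimal reverse-mode autodiff and 2D CNN layers on numpy.

The segmentation networks in this package are small (tens of thousands of
parameters) and trained on CPU, so the backend is a compact tape-based
autograd engine: each op builds a :class:`Tensor` node holding its forward
value and a closure that maps the output gradient to parent gradients.
Convolutions use the im2col/matmul formulation; the gradient with respect
to the input is itself a convolution with the spatially flipped, channel-
transposed kernel, so one raw convolution routine serves both directions.

Array layout is ``(N, C, H, W)`` throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """A node in the autodiff graph: value, gradient, and backward closure."""

    __slots__ = ("data", "grad", "_parents", "_bw", "name")

    def __init__(self, data, parents=(), bw=None, name=""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._bw = bw
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad: np.ndarray) -> None:
        """Backpropagate ``grad`` (dL/dself) through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs here can be ~100 nodes deep
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
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._bw is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._bw(node.grad)):
                if g is None:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    __slots__ = ("weight_decay",)

    def __init__(self, data, name="", weight_decay=False):
        super().__init__(data, name=name)
        self.weight_decay = weight_decay


# ---------------------------------------------------------------- raw conv


def _conv2d_raw(x: np.ndarray, wmat: np.ndarray, k: int, pad: int) -> np.ndarray:
    """Correlate ``x`` (N,C,H,W) with ``wmat`` (F, C*k*k); stride 1."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,Ho,Wo,k,k)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    out = cols @ wmat.T
    return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2), cols


def conv2d(x: Tensor, w: Parameter, b: Parameter, pad: int) -> Tensor:
    """Same-size 2D convolution (stride 1); ``pad = (k-1)//2`` for 'same'."""
    f, c, k, _ = w.data.shape
    wmat = w.data.reshape(f, -1)
    out, cols = _conv2d_raw(x.data, wmat, k, pad)
    out += b.data.reshape(1, -1, 1, 1)

    def bw(dout):
        n, _, ho, wo = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, f)
        dw = (dflat.T @ cols).reshape(w.data.shape)
        db = dflat.sum(axis=0)
        # dL/dx = full correlation of dout with flipped, transposed kernel
        wrot = np.flip(w.data, axis=(2, 3)).transpose(1, 0, 2, 3).reshape(c, -1)
        dx, _ = _conv2d_raw(dout, wrot, k, k - 1 - pad)
        return dx, dw, db

    return Tensor(out, (x, w, b), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, (x,), lambda d: (d * mask,))


def batchnorm2d(
    x: Tensor,
    gamma: Parameter,
    beta: Parameter,
    running: dict,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W)."""
    g = gamma.data.reshape(1, -1, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
        var = x.data.var(axis=(0, 2, 3), keepdims=True)
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu.ravel()
        running["var"] = (1 - momentum) * running["var"] + momentum * var.ravel()
    else:
        mu = running["mean"].reshape(1, -1, 1, 1)
        var = running["var"].reshape(1, -1, 1, 1)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = g * xhat + beta.data.reshape(1, -1, 1, 1)

    def bw(dout):
        dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        dbeta = dout.sum(axis=(0, 2, 3))
        if training:
            m = dout.shape[0] * dout.shape[2] * dout.shape[3]
            dxhat = dout * g
            dx = (
                inv
                / m
                * (
                    m * dxhat
                    - dxhat.sum(axis=(0, 2, 3), keepdims=True)
                    - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                )
            )
        else:
            dx = dout * g * inv
        return dx, dgamma, dbeta

    return Tensor(out, (x, gamma, beta), bw)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)  # first max wins: deterministic tie-break
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bw(dout):
        dxr = np.zeros_like(xr)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        dx = (
            dxr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        return (dx,)

    return Tensor(out, (x,), bw)


def _interp_coeffs(n_out: int, n_in: int):
    """Bilinear ×2 sampling coordinates (align_corners=False, edge clamp)."""
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    i0f = np.floor(src)
    w1 = src - i0f
    i0 = np.clip(i0f.astype(int), 0, n_in - 1)
    i1 = np.clip(i0f.astype(int) + 1, 0, n_in - 1)
    return i0, i1, w1


def upsample_bilinear2x(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    hi0, hi1, hw1 = _interp_coeffs(2 * h, h)
    wi0, wi1, ww1 = _interp_coeffs(2 * w, w)

    def interp(a):
        a = a[:, :, hi0, :] * (1 - hw1)[None, None, :, None] + a[:, :, hi1, :] * hw1[
            None, None, :, None
        ]
        a = a[:, :, :, wi0] * (1 - ww1)[None, None, None, :] + a[:, :, :, wi1] * ww1[
            None, None, None, :
        ]
        return a

    out = interp(x.data)

    def bw(dout):
        # transpose of the two gathers: scatter along W then H
        dh = np.zeros((n, c, 2 * h, w))
        np.add.at(
            dh.transpose(3, 0, 1, 2), wi0, (dout * (1 - ww1)).transpose(3, 0, 1, 2)
        )
        np.add.at(dh.transpose(3, 0, 1, 2), wi1, (dout * ww1).transpose(3, 0, 1, 2))
        dx = np.zeros((n, c, h, w))
        np.add.at(
            dx.transpose(2, 0, 1, 3),
            hi0,
            (dh * (1 - hw1)[None, None, :, None]).transpose(2, 0, 1, 3),
        )
        np.add.at(
            dx.transpose(2, 0, 1, 3),
            hi1,
            (dh * hw1[None, None, :, None]).transpose(2, 0, 1, 3),
        )
        return (dx,)

    return Tensor(out, (x,), bw)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    sizes = [t.data.shape[1] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=1)
    bounds = np.cumsum([0] + sizes)

    def bw(dout):
        return tuple(dout[:, bounds[i] : bounds[i + 1]] for i in range(len(sizes)))

    return Tensor(out, tuple(tensors), bw)


# ---------------------------------------------------------------- optimizer


class Adam:
    """Adam with decoupled weight decay on flagged parameters only."""

    def __init__(self, params, lr=1e-3, weight_decay=0.0, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and getattr(p, "weight_decay", False):
                p.data -= self.lr * self.weight_decay * p.data

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
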