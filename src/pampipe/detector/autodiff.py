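"""Minimal reverse-mode autodiff on numpy arrays.

Just enough machinery for a small convolutional classifier: broadcasting
elementwise ops, matmul, 2-D convolution via im2col, max-pooling, softmax and
a fused binary-cross-entropy-with-logits loss. Define-by-run: each forward
pass builds a fresh tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "maxpool2d", "softmax", "concat", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ---- graph traversal -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and not t._parents:  # leaf
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # ---- elementwise -----------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        o = self._coerce(other)
        return Tensor(
            self.data + o.data,
            parents=(self, o),
            backward=lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, o.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)
        return Tensor(
            self.data * o.data,
            parents=(self, o),
            backward=lambda g: (
                _unbroadcast(g * o.data, self.shape),
                _unbroadcast(g * self.data, o.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        return Tensor(
            self.data / o.data,
            parents=(self, o),
            backward=lambda g: (
                _unbroadcast(g / o.data, self.shape),
                _unbroadcast(-g * self.data / o.data**2, o.shape),
            ),
        )

    def __matmul__(self, other):
        o = self._coerce(other)

        def back(g):
            ga = g @ np.swapaxes(o.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, o.shape)

        return Tensor(self.data @ o.data, parents=(self, o), backward=back)

    # ---- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=(self,), backward=lambda g: (g * mask,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor(s, parents=(self,), backward=lambda g: (g * s * (1 - s),))

    def tanh(self):
        t = np.tanh(self.data)
        return Tensor(t, parents=(self,), backward=lambda g: (g * (1 - t**2),))

    def exp(self):
        e = np.exp(np.clip(self.data, -700, 700))
        return Tensor(e, parents=(self,), backward=lambda g: (g * e,))

    # ---- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=back)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor(
            self.data.reshape(shape), parents=(self,), backward=lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes), parents=(self,), backward=lambda g: (g.transpose(inv),)
        )


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(np.max(x.data, axis=axis, keepdims=True))  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors), backward=back)


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int):
    """(B,C,H,W) -> columns (B, H', W', C*kh*kw) with stride 1."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # view: (B, C, H', W', kh, kw) -> (B, H', W', C, kh, kw)
    cols = view.transpose(0, 2, 3, 1, 4, 5)
    b, ho, wo = cols.shape[:3]
    return np.ascontiguousarray(cols).reshape(b, ho, wo, -1), x.shape


def _col2im(gcols: np.ndarray, padded_shape, kh: int, kw: int, pad: int):
    b, c, hp, wp = padded_shape
    ho, wo = gcols.shape[1], gcols.shape[2]
    g = gcols.reshape(b, ho, wo, c, kh, kw)
    dx = np.zeros(padded_shape)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + ho, j : j + wo] += g[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, pad: int = 1) -> Tensor:
    """Stride-1 2-D convolution. weight: (out_c, in_c, kh, kw); bias: (out_c,)."""
    oc, ic, kh, kw = weight.shape
    cols, padded_shape = _im2col(x.data, kh, kw, pad)  # (B,H',W',ic*kh*kw)
    wmat = weight.data.reshape(oc, -1)  # (oc, ic*kh*kw)
    out = cols @ wmat.T + bias.data  # (B,H',W',oc)
    out = out.transpose(0, 3, 1, 2)

    def back(g):
        gout = g.transpose(0, 2, 3, 1)  # (B,H',W',oc)
        gcols = gout @ wmat  # (B,H',W',ic*kh*kw)
        dx = _col2im(gcols, padded_shape, kh, kw, pad)
        gw = np.tensordot(gout, cols, axes=([0, 1, 2], [0, 1, 2])).reshape(weight.shape)
        gb = gout.sum(axis=(0, 1, 2))
        return dx, gw, gb

    return Tensor(out, parents=(x, weight, bias), backward=back)


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """k×k max pooling; trailing rows/cols that don't fill a cell are dropped."""
    b, c, h, w = x.shape
    ho, wo = h // k, w // k
    xt = x.data[:, :, : ho * k, : wo * k].reshape(b, c, ho, k, wo, k)
    out = xt.max(axis=(3, 5))
    # mask of the (first) argmax in each cell
    expanded = out[:, :, :, None, :, None]
    mask = (xt == expanded).astype(np.float64)
    mask /= mask.sum(axis=(3, 5), keepdims=True)  # split ties evenly

    def back(g):
        gexp = g.reshape(b, c, ho, 1, wo, 1) * mask
        dx = np.zeros_like(x.data)
        dx[:, :, : ho * k, : wo * k] = gexp.reshape(b, c, ho * k, wo * k)
        return (dx,)

    return Tensor(out, parents=(x,), backward=back)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits (numerically stable, fused grad)."""
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def back(g):
        return (g * (p - y) / y.size,)

    return Tensor(loss, parents=(logits,), backward=back)


class Adam:
    """Adam optimizer over a list of leaf Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
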