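"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the dual-branch model needs: dense
linear algebra, elementwise nonlinearities, 3x3 "same" convolution,
2x2 max pooling, batched outer products, concatenation, reductions and
a fused softmax cross-entropy.  Gradients are validated against finite
differences in the test suite.

All tensors are float64; the models here are small enough that the
extra precision is cheaper than chasing float32 tolerance issues.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "add",
    "matmul",
    "mul",
    "scale",
    "relu",
    "sigmoid",
    "tanh",
    "reshape",
    "concat",
    "mean",
    "tsum",
    "tmax",
    "linear",
    "outer_rows",
    "conv2d",
    "maxpool2d",
    "softmax_cross_entropy",
    "softmax",
    "glorot_uniform",
    "Adam",
]


class Tensor:
    """A NumPy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from a scalar tensor through the recorded graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not (parent.requires_grad or parent._parents):
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else constant(x)


def _track(data, parents, backward) -> Tensor:
    """Create a result node; drop the tape if no parent needs gradients."""
    if any(p.requires_grad or p._parents for p in parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data

    def backward(g):
        return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape)))

    return _track(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data

    def backward(g):
        return (
            (a, _unbroadcast(g * b.data, a.data.shape)),
            (b, _unbroadcast(g * a.data, b.data.shape)),
        )

    return _track(out, (a, b), backward)


def scale(a, s: float) -> Tensor:
    a = _as_tensor(a)
    s = float(s)

    def backward(g):
        return ((a, g * s),)

    return _track(a.data * s, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data @ b.data

    def backward(g):
        return ((a, g @ b.data.T), (b, a.data.T @ g))

    return _track(out, (a, b), backward)


def linear(x, w, b=None) -> Tensor:
    out = matmul(x, w)
    return out if b is None else add(out, b)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def backward(g):
        return ((a, g * mask),)

    return _track(a.data * mask, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    # numerically stable logistic
    out = np.empty_like(a.data)
    pos = a.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    e = np.exp(a.data[~pos])
    out[~pos] = e / (1.0 + e)

    def backward(g):
        return ((a, g * out * (1.0 - out)),)

    return _track(out, (a,), backward)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    out = np.tanh(a.data)

    def backward(g):
        return ((a, g * (1.0 - out * out)),)

    return _track(out, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    orig = a.data.shape

    def backward(g):
        return ((a, g.reshape(orig)),)

    return _track(a.data.reshape(shape), (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return _track(out, tuple(tensors), backward)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return ((a, np.broadcast_to(g, a.data.shape) / n),)

    return _track(out, (a,), backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return ((a, np.broadcast_to(g, a.data.shape).copy()),)

    return _track(out, (a,), backward)


def tmax(a, axis: int, keepdims: bool = False) -> Tensor:
    """Max reduction along one axis; gradient flows to the first argmax."""
    a = _as_tensor(a)
    idx = np.argmax(a.data, axis=axis)
    out = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)
    res = out if keepdims else np.squeeze(out, axis=axis)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, np.expand_dims(idx, axis), g, axis=axis)
        return ((a, ga),)

    return _track(res, (a,), backward)


def outer_rows(a, b) -> Tensor:
    """Row-wise outer product: (B, p) x (B, q) -> (B, p*q), row-major flat."""
    a, b = _as_tensor(a), _as_tensor(b)
    B, p = a.data.shape
    _, q = b.data.shape
    out = (a.data[:, :, None] * b.data[:, None, :]).reshape(B, p * q)

    def backward(g):
        G = g.reshape(B, p, q)
        ga = (G * b.data[:, None, :]).sum(axis=2)
        gb = (G * a.data[:, :, None]).sum(axis=1)
        return ((a, ga), (b, gb))

    return _track(out, (a, b), backward)


# ---------------------------------------------------------------------------
# convolution / pooling (stride 1, "same" padding, odd kernels)
# ---------------------------------------------------------------------------


def _im2col(xp: np.ndarray, k: int, H: int, W: int) -> np.ndarray:
    B, C = xp.shape[:2]
    cols = np.empty((B, C, k, k, H * W), dtype=xp.dtype)
    for di in range(k):
        for dj in range(k):
            cols[:, :, di, dj, :] = xp[:, :, di : di + H, dj : dj + W].reshape(B, C, H * W)
    return cols.reshape(B, C * k * k, H * W)


def _col2im(cols: np.ndarray, B: int, C: int, k: int, H: int, W: int, pad: int) -> np.ndarray:
    cols = cols.reshape(B, C, k, k, H * W)
    xp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    for di in range(k):
        for dj in range(k):
            xp[:, :, di : di + H, dj : dj + W] += cols[:, :, di, dj, :].reshape(B, C, H, W)
    if pad == 0:
        return xp
    return xp[:, :, pad : pad + H, pad : pad + W]


def conv2d(x, w, b=None) -> Tensor:
    """Stride-1 same-padded 2-D convolution, NCHW layout, odd square kernel."""
    x, w = _as_tensor(x), _as_tensor(w)
    B, C, H, W = x.data.shape
    O, C2, k, k2 = w.data.shape
    if C != C2 or k != k2 or k % 2 == 0:
        raise ValueError("conv2d expects (O, C, k, k) weights with odd k matching input channels")
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = _im2col(xp, k, H, W)  # (B, C*k*k, H*W)
    wm = w.data.reshape(O, C * k * k)
    out = np.einsum("ok,bkn->bon", wm, cols, optimize=True).reshape(B, O, H, W)

    def backward(g):
        gm = g.reshape(B, O, H * W)
        gw = np.einsum("bon,bkn->ok", gm, cols, optimize=True).reshape(w.data.shape)
        gcols = np.einsum("ok,bon->bkn", wm, gm, optimize=True)
        gx = _col2im(gcols, B, C, k, H, W, pad)
        return ((x, gx), (w, gw))

    res = _track(out, (x, w), backward)
    if b is not None:
        res = add(res, reshape(_as_tensor(b), (1, O, 1, 1)))
    return res


def maxpool2d(x) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    x = _as_tensor(x)
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2d requires even spatial dimensions")
    Ho, Wo = H // 2, W // 2
    xr = x.data.reshape(B, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, 4)
    idx = np.argmax(xr, axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros((B, C, Ho, Wo, 4), dtype=g.dtype)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(B, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W)
        return ((x, gx),)

    return _track(out, (x,), backward)


# ---------------------------------------------------------------------------
# losses / misc
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, labels) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    B = logits.data.shape[0]
    probs = softmax(logits.data)
    p_true = np.clip(probs[np.arange(B), labels], 1e-12, None)
    loss = -np.log(p_true).mean()

    def backward(g):
        gl = probs.copy()
        gl[np.arange(B), labels] -= 1.0
        return ((logits, g * gl / B),)

    return _track(np.float64(loss), (logits,), backward)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Glorot/Xavier uniform init; conv fans follow the (O, C, k, k) layout."""
    if len(shape) == 2:
        fan_in, fan_out = shape
    elif len(shape) == 4:
        rcpt = shape[2] * shape[3]
        fan_in, fan_out = shape[1] * rcpt, shape[0] * rcpt
    else:
        raise ValueError(f"unsupported weight shape {shape}")
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam with parameter groups (each group may use its own learning rate)."""

    def __init__(self, params_or_groups, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        if params_or_groups and isinstance(params_or_groups[0], dict):
            groups = params_or_groups
        else:
            groups = [{"params": list(params_or_groups), "lr": lr}]
        self.groups = [
            {"params": list(g["params"]), "lr": float(g.get("lr", lr))} for g in groups
        ]
        self.betas = betas
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}
        for g in self.groups:
            for p in g["params"]:
                self._m[id(p)] = np.zeros_like(p.data)
                self._v[id(p)] = np.zeros_like(p.data)

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for g in self.groups:
            lr = g["lr"]
            for p in g["params"]:
                if p.grad is None:
                    continue
                m = self._m[id(p)]
                v = self._v[id(p)]
                m *= b1
                m += (1 - b1) * p.grad
                v *= b2
                v += (1 - b2) * p.grad * p.grad
                p.data -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
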