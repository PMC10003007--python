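"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package trains its sequence model with plain NumPy, so this module
provides the small set of differentiable primitives the encoder needs:
broadcast-aware arithmetic, (batched) matmul, 1-D convolution and max
pooling over the token axis, ELU/sigmoid/softmax, reductions, and the
token gather/scatter used by sparse attention.  Every primitive stores a
closure that maps the output gradient to parent-gradient contributions;
``Tensor.backward`` runs a topological sweep over the tape.

Gradient correctness is established by central-difference checks in the
test suite rather than by construction, so keep primitives simple.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "parameter",
    "matmul",
    "conv1d",
    "maxpool1d",
    "elu",
    "sigmoid",
    "softmax",
    "log",
    "exp",
    "clip",
    "gather_tokens",
    "scatter_tokens",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        # parents: sequence of (Tensor, fn) with fn(output_grad) -> parent grad
        self._parents = tuple(parents)

    # ---- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- autograd core -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, fn in node._parents:
                if not parent.requires_grad:
                    continue
                contrib = fn(g)
                if parent.grad is None:
                    parent.grad = contrib.copy()
                else:
                    parent.grad += contrib

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ----------------------------------------------------------
    def _binary(self, other, fwd, bwd_self, bwd_other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = fwd(self.data, other.data)
        req = self.requires_grad or other.requires_grad
        parents = []
        if self.requires_grad:
            parents.append((self, lambda g: _unbroadcast(bwd_self(g), self.data.shape)))
        if other.requires_grad:
            parents.append((other, lambda g: _unbroadcast(bwd_other(g), other.data.shape)))
        return Tensor(out_data, req, parents)

    def __add__(self, other):
        return self._binary(other, np.add, lambda g: g, lambda g: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, np.subtract, lambda g: g, lambda g: -g)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        return self._binary(o, np.multiply, lambda g: g * o.data, lambda g: g * self.data)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division only supported by constants")
        return self * (1.0 / other)

    # ---- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        src = self.data.shape
        out = Tensor(self.data.reshape(*shape), self.requires_grad,
                     [(self, lambda g: g.reshape(src))])
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(axes), self.requires_grad,
                      [(self, lambda g: g.transpose(inv))])

    # ---- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            g2 = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(g2, self.data.shape).copy()

        return Tensor(out_data, self.requires_grad, [(self, bwd)])

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def tensor(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


# ---- elementwise nonlinearities ---------------------------------------------

def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.data > 0
    out_data = np.where(pos, x.data, alpha * np.expm1(x.data))

    def bwd(g):
        return g * np.where(pos, 1.0, out_data + alpha)

    return Tensor(out_data, x.requires_grad, [(x, bwd)])


def sigmoid(x: Tensor) -> Tensor:
    out_data = 0.5 * (np.tanh(0.5 * x.data) + 1.0)  # numerically stable
    return Tensor(out_data, x.requires_grad,
                  [(x, lambda g: g * out_data * (1.0 - out_data))])


def log(x: Tensor) -> Tensor:
    return Tensor(np.log(x.data), x.requires_grad, [(x, lambda g: g / x.data)])


def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)
    return Tensor(out_data, x.requires_grad, [(x, lambda g: g * out_data)])


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    out_data = np.clip(x.data, lo, hi)
    inside = (x.data > lo) & (x.data < hi)
    return Tensor(out_data, x.requires_grad, [(x, lambda g: g * inside)])


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return s * (g - dot)

    return Tensor(s, x.requires_grad, [(x, bwd)])


# ---- linear algebra ----------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = np.matmul(a.data, b.data)
    parents = []
    if a.requires_grad:
        def bwd_a(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            return _unbroadcast(ga, a.data.shape)
        parents.append((a, bwd_a))
    if b.requires_grad:
        def bwd_b(g):
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            return _unbroadcast(gb, b.data.shape)
        parents.append((b, bwd_b))
    return Tensor(out_data, a.requires_grad or b.requires_grad, parents)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded 1-D convolution over the token axis.

    x: (batch, L, C_in), w: (K, C_in, C_out), b: (C_out,).
    """
    B, L, Cin = x.data.shape
    K, _, Cout = w.data.shape
    pl = (K - 1) // 2
    pr = K - 1 - pl
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)  # (B, L, Cin, K)
    out_data = np.einsum("blck,kco->blo", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data
    parents = []
    if x.requires_grad:
        def bwd_x(g):
            dxp = np.zeros_like(xp)
            for k in range(K):
                dxp[:, k:k + L, :] += np.matmul(g, w.data[k].T)
            return dxp[:, pl:pl + L, :]
        parents.append((x, bwd_x))
    if w.requires_grad:
        parents.append((w, lambda g: np.einsum("blck,blo->kco", win, g, optimize=True)))
    if b is not None and b.requires_grad:
        parents.append((b, lambda g: g.sum(axis=(0, 1))))
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    return Tensor(out_data, req, parents)


def maxpool1d(x: Tensor, width: int = 2) -> Tensor:
    """Non-overlapping max pool over the token axis; a ragged tail is dropped."""
    B, L, C = x.data.shape
    if L < width:
        raise ValueError(f"token count {L} smaller than pool width {width}")
    Lp = L // width
    x2 = x.data[:, :Lp * width, :].reshape(B, Lp, width, C)
    out_data = x2.max(axis=2)
    idx = x2.argmax(axis=2)

    def bwd(g):
        dx2 = np.zeros((B, Lp, width, C))
        np.put_along_axis(dx2, idx[:, :, None, :], g[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C))
        dx[:, :Lp * width, :] = dx2.reshape(B, Lp * width, C)
        return dx

    return Tensor(out_data, x.requires_grad, [(x, bwd)])


# ---- token gather / scatter (sparse attention) --------------------------------

def gather_tokens(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select token rows: x (..., L, D), idx (..., u) -> (..., u, D)."""
    idx = np.asarray(idx)
    out_data = np.take_along_axis(x.data, idx[..., None], axis=-2)

    def bwd(g):
        L, D = x.data.shape[-2:]
        lead = int(np.prod(x.data.shape[:-2], dtype=int))
        # C-ordered scratch buffer: x.data itself may be non-contiguous
        flat_dx = np.zeros((lead, L, D))
        flat_idx = idx.reshape(lead, -1)
        flat_g = np.ascontiguousarray(g).reshape(lead, -1, D)
        rows = np.repeat(np.arange(lead), flat_idx.shape[1])
        np.add.at(flat_dx, (rows, flat_idx.ravel()), flat_g.reshape(-1, D))
        return flat_dx.reshape(x.data.shape)

    return Tensor(out_data, x.requires_grad, [(x, bwd)])


def scatter_tokens(base: Tensor, idx: np.ndarray, rows: Tensor) -> Tensor:
    """Overwrite token rows of ``base`` at ``idx`` with ``rows`` (unique indices)."""
    idx = np.asarray(idx)
    out_data = base.data.copy()
    np.put_along_axis(out_data, idx[..., None], rows.data, axis=-2)
    parents = []
    if base.requires_grad:
        def bwd_base(g):
            gb = g.copy()
            np.put_along_axis(gb, idx[..., None], 0.0, axis=-2)
            return gb
        parents.append((base, bwd_base))
    if rows.requires_grad:
        parents.append((rows, lambda g: np.take_along_axis(g, idx[..., None], axis=-2)))
    return Tensor(out_data, base.requires_grad or rows.requires_grad, parents)


# ---- optimizer ----------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
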