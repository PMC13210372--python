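"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package's trainable components (temporal-conv encoders, the adjacency
MLP, GraphSAGE layers, the evidential head and every training loss) are
small dense networks; this module provides the tape-based `Tensor` they are
built from, plus `Linear` layers and SGD/Adam optimizers.

Gradients follow numpy broadcasting semantics: a gradient flowing into a
broadcast operand is summed over the broadcast axes.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Linear", "SGD", "Adam", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    """A node on the autodiff tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: Sequence["Tensor"] = (),
                 _backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order of the tape
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents
                         if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = _as_tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return Tensor(self.data / other.data, _parents=(self, other), _backward=bwd)

    def __rtruediv__(self, other) -> "Tensor":
        return _as_tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        return Tensor(self.data ** p, _parents=(self,), _backward=bwd)

    def __matmul__(self, other) -> "Tensor":
        """Matrix product. Supports (...,m,k) @ (...,k,n), 1-D @ 2-D and 2-D @ 1-D."""
        other = _as_tensor(other)
        a_vec = self.ndim == 1
        b_vec = other.ndim == 1

        def bwd(g):
            a, b = self.data, other.data
            a2 = a[None, :] if a_vec else a
            b2 = b[:, None] if b_vec else b
            g2 = g
            if a_vec:
                g2 = np.expand_dims(g2, -2)
            if b_vec:
                g2 = np.expand_dims(g2, -1)
            if self.requires_grad:
                ga = g2 @ np.swapaxes(b2, -1, -2)
                if a_vec:
                    ga = ga.reshape(-1, a.shape[0]).sum(axis=0)
                self._accumulate(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                gb = np.swapaxes(a2, -1, -2) @ g2
                if b_vec:
                    gb = gb.reshape(-1, b.shape[0], 1)[..., 0].sum(axis=0) \
                        if gb.ndim > 2 else gb.reshape(b.shape)
                other._accumulate(_unbroadcast(gb, b.shape))

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=bwd)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bwd)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bwd)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        return Tensor(s, _parents=(self,), _backward=bwd)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - t ** 2))

        return Tensor(t, _parents=(self,), _backward=bwd)

    def lgamma(self) -> "Tensor":
        from scipy.special import digamma as _dg
        from scipy.special import gammaln as _gl

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * _dg(self.data))

        return Tensor(_gl(self.data), _parents=(self,), _backward=bwd)

    def digamma(self) -> "Tensor":
        from scipy.special import digamma as _dg
        from scipy.special import polygamma as _pg

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * _pg(1, self.data))

        return Tensor(_dg(self.data), _parents=(self,), _backward=bwd)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * sign)

        return Tensor(np.abs(self.data), _parents=(self,), _backward=bwd)

    # -- reductions and reshaping -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bwd)

    def transpose(self, *axes) -> "Tensor":
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=bwd)

    def __getitem__(self, idx) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accumulate(acc)

        return Tensor(self.data[idx], _parents=(self,), _backward=bwd)

    # -- composite helpers -------------------------------------------------
    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  _parents=tuple(tensors), _backward=bwd)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor(np.stack([t.data for t in tensors], axis=axis),
                  _parents=tuple(tensors), _backward=bwd)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Linear:
    """Dense layer y = x W^T + b with Glorot-uniform init."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        limit = np.sqrt(6.0 / (in_dim + out_dim))
        self.W = Parameter(rng.uniform(-limit, limit, size=(out_dim, in_dim)))
        self.b = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W.transpose()
        return y if self.b is None else y + self.b

    def parameters(self) -> list[Parameter]:
        return [self.W] + ([self.b] if self.b is not None else [])


def zero_grads(params: Iterable[Tensor]) -> None:
    for p in params:
        p.grad = None


class SGD:
    def __init__(self, params: Sequence[Tensor], lr: float = 1e-2):
        self.params = list(params)
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self) -> None:
        zero_grads(self.params)


class Adam:
    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                # decoupled decay (AdamW-style)
                p.data -= self.lr * self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        zero_grads(self.params)
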