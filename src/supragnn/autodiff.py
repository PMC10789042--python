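"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The model in this package is small (tens of thousands of parameters, graphs
with at most a few hundred nodes), so a compact tape-based engine over dense
``float64`` arrays is sufficient and keeps the whole stack dependency-light.
Gradients are exact (validated against central differences in the test
suite); broadcasting follows NumPy semantics, with gradients summed back to
the parent shape.

Only the operations the model needs are implemented: arithmetic, matmul,
reductions, reshapes, element-wise nonlinearities, concatenation, windowed
max-pooling and basic slicing.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "Adam"]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient tape.

    Parameters with ``requires_grad=True`` accumulate ``.grad`` when
    :meth:`backward` is called on a downstream scalar.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward_fn = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward_fn):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward_fn = backward_fn
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        """Accumulate a gradient; ``own=True`` promises ``grad`` is freshly
        allocated for this parent and may be stored without copying."""
        g = _sum_to_shape(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g if (own and g is grad) else g.copy()
        else:
            self.grad += g

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g)
            if b.requires_grad:
                b._accum(g)

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(-g, own=True)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g * b.data, own=True)
            if b.requires_grad:
                b._accum(g * a.data, own=True)

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g / b.data, own=True)
            if b.requires_grad:
                b._accum(-g * a.data / (b.data**2), own=True)

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def bwd(g, a=self, e=exponent):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1), own=True)

        return Tensor._make(self.data**exponent, (self,), bwd)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ np.swapaxes(b.data, -1, -2), own=True)
            if b.requires_grad:
                b._accum(np.swapaxes(a.data, -1, -2) @ g, own=True)

        return Tensor._make(self.data @ other.data, (self, other), bwd)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            g = np.asarray(g)
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Maximum along ``axis``; gradient is split evenly among ties."""
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)

        def bwd(g, a=self, ax=axis, kd=keepdims, m=mask):
            if not a.requires_grad:
                return
            g = np.asarray(g)
            if not kd:
                g = np.expand_dims(g, ax)
            a._accum(g * m)

        data = out_data if keepdims else out_data.squeeze(axis=axis)
        return Tensor._make(data, (self,), bwd)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def bwd(g, a=self, s=orig):
            if a.requires_grad:
                a._accum(np.asarray(g).reshape(s))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def swapaxes(self, ax1: int, ax2: int):
        def bwd(g, a=self, i=ax1, j=ax2):
            if a.requires_grad:
                a._accum(np.swapaxes(np.asarray(g), i, j))

        return Tensor._make(np.swapaxes(self.data, ax1, ax2), (self,), bwd)

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        def bwd(g, a=self, i=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[i] = g
                a._accum(full)

        return Tensor._make(self.data[idx], (self,), bwd)

    # -- element-wise nonlinearities ------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o, own=True)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data, own=True)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m, own=True)

        return Tensor._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)

        def bwd(g, a=self, f=factor):
            if a.requires_grad:
                a._accum(g * f, own=True)

        return Tensor._make(self.data * factor, (self,), bwd)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * np.expm1(self.data))

        def bwd(g, a=self, p=pos, o=out_data, al=alpha):
            if a.requires_grad:
                a._accum(g * np.where(p, 1.0, o + al), own=True)

        return Tensor._make(out_data, (self,), bwd)

    def clamp_min(self, lo: float):
        """max(x, lo) with pass-through gradient where x > lo."""
        mask = self.data > lo

        def bwd(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return Tensor._make(np.maximum(self.data, lo), (self,), bwd)

    # -- autodiff driver ------------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from this tensor (gradient seeded with ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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

        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward_fn is not None:
                node._backward_fn(node.grad)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g, ts=tensors, off=offsets, ax=axis):
        g = np.asarray(g)
        for t, lo, hi in zip(ts, off[:-1], off[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[ax] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd
    )


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
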