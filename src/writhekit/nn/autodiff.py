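"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based engine providing exactly the operations the equivariant score
network needs: broadcasting arithmetic, matrix products, channel-mixing
linear maps on vector features, gather/scatter for graph message passing,
and a few pointwise nonlinearities.  Gradients flow only with respect to
parameters (coordinate-derived edge features enter as constants), so the
op set stays small.
"""

from __future__ import annotations

import numpy as np

#: dtype of every tape array; the generative stack runs in single precision
#: (equivariance tolerances are set accordingly), the writhe core in double.
DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph mechanics ----------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, grad: np.ndarray, fresh: bool = True) -> None:
        """Add ``grad`` to the stored gradient.

        ``fresh=True`` promises the caller created ``grad`` for this call
        (no aliasing), letting us adopt the array without a copy.
        """
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad if fresh else grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            # unbroadcast may return g itself: not fresh unless it reduced
            gs = _unbroadcast(g, self.shape)
            self._accum(gs, fresh=gs is not g)
            go = _unbroadcast(g, other.shape)
            other._accum(go, fresh=go is not g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bwd
        return out

    # -- reductions / shaping ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def expand_dims(self, axis: int):
        out = Tensor(np.expand_dims(self.data, axis), _parents=(self,))
        out._backward = lambda g: self._accum(np.squeeze(g, axis=axis))
        return out

    # -- pointwise nonlinearities --------------------------------------------

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * sig, _parents=(self,))
        out._backward = lambda g: self._accum(g * sig * (1.0 + self.data * (1.0 - sig)))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, _parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - t**2))
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor(r, _parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / r)
        return out


# -- free functions ---------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bwd
    return out


def gather(t: Tensor, index: np.ndarray) -> Tensor:
    """Row gather: out[k] = t[index[k]] (first axis)."""
    out = Tensor(t.data[index], _parents=(t,))

    def bwd(g):
        if t.requires_grad:
            acc = np.zeros_like(t.data)
            np.add.at(acc, index, g)
            t._accum(acc)

    out._backward = bwd
    return out


def scatter_sum(t: Tensor, index: np.ndarray, n_out: int) -> Tensor:
    """Segment sum over the first axis: out[i] = sum_{k: index[k]=i} t[k]."""
    data = np.zeros((n_out,) + t.data.shape[1:])
    np.add.at(data, index, t.data)
    out = Tensor(data, _parents=(t,))
    out._backward = lambda g: t._accum(g[index])
    return out


def segment_sum_contiguous(t: Tensor, group_size: int) -> Tensor:
    """Sum equal contiguous groups along the first axis.

    ``out[i] = sum(t[i*g : (i+1)*g])`` — a fast special case of
    :func:`scatter_sum` for edge lists ordered by source node.
    """
    g = group_size
    n = t.data.shape[0] // g
    out = Tensor(t.data.reshape(n, g, *t.data.shape[1:]).sum(axis=1), _parents=(t,))
    out._backward = lambda grad: t._accum(np.repeat(grad, g, axis=0))
    return out


def channel_linear(v: Tensor, w: Tensor) -> Tensor:
    """Mix vector-feature channels: (N, C, 3) x (C, D) -> (N, D, 3).

    Acts only on the channel axis, so the map commutes with rotations of
    the trailing 3-vector axis (equivariance-preserving).
    """
    # BLAS path: (N, C, 3) -> (N, 3, C) @ (C, D) -> (N, 3, D) -> (N, D, 3)
    vt = np.ascontiguousarray(v.data.swapaxes(1, 2))
    out = Tensor(np.matmul(vt, w.data).swapaxes(1, 2), _parents=(v, w))

    def bwd(g):
        gt = np.ascontiguousarray(g.swapaxes(1, 2))  # (N, 3, D)
        v._accum(np.matmul(gt, w.data.T).swapaxes(1, 2))
        if w.requires_grad:
            n, three, c = vt.shape
            w._accum(vt.reshape(-1, c).T @ gt.reshape(-1, gt.shape[2]))

    out._backward = bwd
    return out


def vector_norm(v: Tensor, eps: float = 1e-8) -> Tensor:
    """Invariant norm over the trailing 3-vector axis: (N, C, 3) -> (N, C)."""
    sq = (v * v).sum(axis=-1)
    return (sq + eps).sqrt()


def dot3(a: Tensor, b: Tensor) -> Tensor:
    """Invariant dot product over the trailing axis."""
    return (a * b).sum(axis=-1)


# -- parameters and optimization --------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> Parameter:
    scale = np.sqrt(2.0 / (n_in + n_out))
    return Parameter(rng.normal(scale=scale, size=(n_in, n_out)))


class Linear:
    """Dense layer y = x @ W + b."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = glorot(rng, n_in, n_out)
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class MLP:
    """Two-layer perceptron with SiLU activation."""

    def __init__(self, rng, n_in: int, n_hidden: int, n_out: int):
        self.l1 = Linear(rng, n_in, n_hidden)
        self.l2 = Linear(rng, n_hidden, n_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.l2(self.l1(x).silu())

    def parameters(self):
        return self.l1.parameters() + self.l2.parameters()


class Adam:
    """Adam optimizer with the standard bias correction."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
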