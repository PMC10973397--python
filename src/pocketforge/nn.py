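"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the micrograd style, vectorized over
float64 numpy arrays, with exactly the operations the generative core
needs: arithmetic with broadcasting, matmul, exp/log/tanh/relu,
reductions, concatenation, row gather and scatter-add (for message
passing), and a numerically stable log-softmax.  Gradient correctness
is property-tested against central finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "scatter_add", "Linear", "MLP", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")
    __array_priority__ = 100  # keep numpy from hijacking reflected ops

    def __init__(self, data, parents=(), backward=None, requires_grad=True):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad

    # -- bookkeeping -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor) -> None:
            stack = [(node, False)]
            while stack:
                cur, processed = stack.pop()
                if processed:
                    topo.append(cur)
                    continue
                if id(cur) in seen:
                    continue
                seen.add(id(cur))
                stack.append((cur, True))
                for parent in cur._parents:
                    stack.append((parent, False))

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(
            other, requires_grad=False)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(
                -g * self.data / (other.data ** 2), other.data.shape))

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = backward
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, (self,))

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- elementwise functions --------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), (self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), (self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data ** 2))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * sig, (self,))
        out._backward = lambda g: self._accum(
            g * (sig * (1.0 + self.data * (1.0 - sig))))
        return out

    # -- reductions / shaping ---------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        count = (self.data.size if axis is None
                 else self.data.shape[axis])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)

        out._backward = backward
        return out

    # -- softmax -----------------------------------------------------------

    def log_softmax(self, axis: int = -1):
        shift = self.data.max(axis=axis, keepdims=True)  # constant shift
        shifted = self - Tensor(shift, requires_grad=False)
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = backward
    return out


def scatter_add(src: Tensor, index: np.ndarray, num_rows: int) -> Tensor:
    """Row-wise segment sum: ``out[i] = sum(src[e] for e with index[e]==i)``."""
    index = np.asarray(index, dtype=int)
    data = np.zeros((num_rows,) + src.data.shape[1:], dtype=np.float64)
    np.add.at(data, index, src.data)
    out = Tensor(data, (src,))
    out._backward = lambda g: src._accum(g[index])
    return out


# ---------------------------------------------------------------------------
# Layers and optimizer
# ---------------------------------------------------------------------------

class Linear:
    """Affine layer with Kaiming-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = float(np.sqrt(6.0 / n_in))
        self.weight = Tensor(rng.uniform(-bound, bound, (n_in, n_out)))
        self.bias = Tensor(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class MLP:
    """Stack of Linear layers with SiLU activations between them.

    ``zero_last`` zero-initializes the final layer (useful for residual
    updates, which then start as the identity).
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 zero_last: bool = False):
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes, sizes[1:])]
        if zero_last:
            self.layers[-1].weight.data[:] = 0.0

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.silu()
        return x

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1 ** self.t)
            v_hat = self.v[k] / (1 - self.beta2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
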