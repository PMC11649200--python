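"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the tensor operations the VQA model needs:
broadcasting arithmetic, (batched) matrix products, reductions, the usual
pointwise nonlinearities, reshaping, and a numerically stable masked softmax.
Everything runs in float64 on a single thread, so a forward pass is
bit-reproducible given fixed parameters and inputs.

Design notes
------------
* ``Tensor`` wraps an ``ndarray`` and records a closure that accumulates
  gradients into its parents; ``backward`` walks the graph in reverse
  topological order.
* Broadcasting is handled by summing gradients over broadcast axes
  (:func:`_unbroadcast`), mirroring numpy semantics.
* ``detach`` cuts the graph — it is the gradient barrier the bias-balancing
  branch relies on, so "exactly zero gradient" means the parameter's ``grad``
  is never touched at all.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "Adam",
    "AdamW",
    "concat",
    "stack",
    "masked_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)  # copy: g may be a view
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs can be deep: LSTM over time)
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        while visiting:
            node, processed = visiting.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visiting.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    visiting.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        """Return a view of the data cut off from the graph (gradient barrier)."""
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accum(-g)

        return self._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return self._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def bw(g):
            if a.requires_grad:
                a._accum(g * e * np.power(a.data, e - 1.0))

        return self._make(np.power(a.data, e), (a,), bw)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.shape))

        return self._make(np.matmul(a.data, b.data), (a, b), bw)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise nonlinearities -----------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return self._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return self._make(np.log(a.data), (a,), bw)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            if a.requires_grad:
                a._accum(g * (1.0 - out_data * out_data))

        return self._make(out_data, (a,), bw)

    def sigmoid(self):
        a = self
        # stable logistic via tanh identity
        out_data = 0.5 * (np.tanh(0.5 * a.data) + 1.0)

        def bw(g):
            if a.requires_grad:
                a._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (a,), bw)

    def relu(self):
        a = self
        pos = a.data > 0

        def bw(g):
            if a.requires_grad:
                a._accum(g * pos)

        return self._make(a.data * pos, (a,), bw)

    def softplus(self):
        """log(1 + exp(x)), overflow-safe; derivative is the logistic."""
        a = self
        out_data = np.logaddexp(0.0, a.data)

        def bw(g):
            if a.requires_grad:
                a._accum(g * (0.5 * (np.tanh(0.5 * a.data) + 1.0)))

        return self._make(out_data, (a,), bw)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def bw(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return self._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bw(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return self._make(a.data.transpose(axes), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return self._make(a.data[idx], (a,), bw)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bw
    return out


def masked_softmax(scores: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax along `axis` with masked positions receiving *exactly* zero.

    Implemented as a single fused graph node: the forward pass subtracts
    the row max of the valid entries, exponentiates, zeroes masked
    positions and normalizes; the backward pass uses the closed form
    ds_i = p_i (g_i - sum_j g_j p_j), which is already zero at masked
    positions.  Requires at least one unmasked entry along `axis`.
    """
    scores = Tensor._lift(scores)
    mask = np.asarray(mask, dtype=bool)
    mask_b = np.broadcast_to(mask, scores.shape)
    if not mask_b.any(axis=axis).all():
        raise ValueError("masked_softmax: at least one position per row must be valid")
    shifted = np.where(mask_b, scores.data, -np.inf)
    shifted = shifted - shifted.max(axis=axis, keepdims=True)
    e = np.exp(shifted, where=mask_b, out=np.zeros_like(scores.data))
    p = e / e.sum(axis=axis, keepdims=True)

    a = scores

    def bw(g):
        if a.requires_grad:
            inner = (g * p).sum(axis=axis, keepdims=True)
            a._accum(p * (g - inner))

    return a._make(p, (a,), bw)


class Module:
    """Barebones parameter container with recursive discovery."""

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out[f"{key}.{i}"] = item
        return out

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)[:5]}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    """Affine map y = x W + b with Glorot-uniform init."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.weight = Parameter(rng.uniform(-limit, limit, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Layer normalization over the trailing feature axis."""

    def __init__(self, d: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        # fused primitive: normalization and its closed-form gradient in
        # one graph node each for x, gamma, beta
        x = Tensor._lift(x)
        gamma, beta = self.gamma, self.beta
        mu = x.data.mean(axis=-1, keepdims=True)
        centred = x.data - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = centred * inv
        out_data = xhat * gamma.data + beta.data

        def bw(g):
            if beta.requires_grad:
                beta._accum(_unbroadcast(g, beta.data.shape))
            if gamma.requires_grad:
                gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
            if x.requires_grad:
                gy = g * gamma.data
                m1 = gy.mean(axis=-1, keepdims=True)
                m2 = (gy * xhat).mean(axis=-1, keepdims=True)
                x._accum(inv * (gy - m1 - xhat * m2))

        return x._make(out_data, (x, gamma, beta), bw)


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class AdamW(Adam):
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        super().__init__(params, lr=lr, betas=betas, eps=eps)
        self.weight_decay = weight_decay

    def step(self) -> None:
        if self.weight_decay:
            for p in self.params:
                if p.grad is not None:
                    p.data = p.data * (1.0 - self.lr * self.weight_decay)
        super().step()
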