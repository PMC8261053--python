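"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module is the numerical core used by the convolutional encoder, the
transformer contextualizer and the training loops.  It provides a small
tape-based :class:`Tensor`, the handful of differentiable primitives the
architecture needs (broadcast arithmetic, batched matmul, indexing/gather,
reductions, GELU, softmax/log-sum-exp), layer building blocks free of any
internal normalization except GroupNorm (the transformer runs without
normalization layers), and an Adam optimizer with decoupled weight decay.

All gradients are validated against central finite differences in the test
suite; the engine is deliberately eager and simple rather than fast, sized
for desk-scale models.
"""

from __future__ import annotations

import json
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Dropout",
    "GroupNorm",
    "Adam",
    "concatenate",
    "gelu_array",
    "save_arrays",
    "load_arrays",
]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # store without copying; the second contribution allocates a new
            # array instead of mutating (incoming buffers may be shared views)
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node through the tape."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads to keep memory flat
                if node._parents:
                    node.grad = None

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2,
                                          other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            self._accum(g * p * self.data**(p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        in_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(in_shape))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        in_shape = self.data.shape
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (slice, int)) for p in parts)

        def backward(g):
            gx = np.zeros(in_shape, dtype=np.float64)
            if basic:
                gx[idx] = g  # slices/ints cannot alias: direct scatter
            else:
                np.add.at(gx, idx, g)
            self._accum(gx)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        in_shape = self.data.shape

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, in_shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, in_shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        """Exact Gaussian-error-linear unit, x·Φ(x)."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x / _SQRT2))
        out_data = x * phi

        def backward(g):
            pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
            self._accum(g * (phi + x * pdf))

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), backward)

    def logsumexp(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        s = e.sum(axis=axis, keepdims=True)
        out_data = np.squeeze(m + np.log(s), axis=axis)

        def backward(g):
            soft = e / s
            self._accum(np.expand_dims(g, axis) * soft)

        return Tensor._make(out_data, (self,), backward)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def gelu_array(x: np.ndarray) -> np.ndarray:
    """Plain-array exact GELU (for code paths outside the tape)."""
    return x * 0.5 * (1.0 + erf(x / _SQRT2))


# =============================================================================
# Modules
# =============================================================================


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive named-parameter traversal."""

    def parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        self._collect("", out)
        return out

    def _collect(self, prefix: str, out: dict[str, Parameter]) -> None:
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out[key] = val
            elif isinstance(val, Module):
                val._collect(key + ".", out)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        item._collect(f"{key}.{i}.", out)
                    elif isinstance(item, Parameter):
                        out[f"{key}.{i}"] = item

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: checkpoint {arr.shape} vs model {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, init: str = "xavier"):
        if init == "xavier":
            bound = np.sqrt(6.0 / (d_in + d_out))
            w = rng.uniform(-bound, bound, size=(d_in, d_out))
        elif init == "kaiming":
            w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class GroupNorm(Module):
    """Group normalization over (channels-in-group, length) per sample.

    Expects input of shape (batch, channels, length).
    """

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        if num_channels % num_groups:
            raise ValueError("channels must divide evenly into groups")
        self.num_groups = num_groups
        self.num_channels = num_channels
        self.eps = eps
        self.weight = Parameter(np.ones(num_channels))
        self.bias = Parameter(np.zeros(num_channels))

    def __call__(self, x: Tensor) -> Tensor:
        b, c, length = x.shape
        g = self.num_groups
        xg = x.reshape(b, g, (c // g) * length)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=2, keepdims=True)
        y = (xg - mu) / (var + self.eps).sqrt()
        y = y.reshape(b, c, length)
        w = self.weight.reshape(1, c, 1)
        bb = self.bias.reshape(1, c, 1)
        return y * w + bb


class Dropout(Module):
    """Inverted dropout; active only when a generator is supplied."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        if rng is None or self.p == 0.0:
            return x
        keep = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class Adam(Module):
    """Adam with decoupled (AdamW-style) weight decay."""

    def __init__(self, params: dict[str, Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = dict(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps)
                            + self.weight_decay * p.data)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {"__t__": np.asarray(self.t)}
        for k in self.params:
            out[f"m/{k}"] = self.m[k].copy()
            out[f"v/{k}"] = self.v[k].copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.t = int(state["__t__"])
        for k in self.params:
            self.m[k] = np.asarray(state[f"m/{k}"], dtype=np.float64).copy()
            self.v[k] = np.asarray(state[f"v/{k}"], dtype=np.float64).copy()


# =============================================================================
# Flat array serialization (checkpoint backing store)
# =============================================================================


def save_arrays(path, arrays: dict[str, np.ndarray], meta: dict | None = None) -> None:
    """Write a flat name→array mapping (plus a JSON metadata entry) to .npz."""
    payload = {k.replace("/", "\x1f"): v for k, v in arrays.items()}
    payload["__meta__"] = np.frombuffer(
        json.dumps(meta or {}).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_arrays(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        arrays = {k.replace("\x1f", "/"): f[k] for k in f.files if k != "__meta__"}
    return arrays, meta
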