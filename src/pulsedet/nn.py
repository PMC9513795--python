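"""Minimal reverse-mode automatic differentiation and neural-network layers.

The detection network is small enough that a compact tape-based tensor
engine on top of numpy covers everything it needs: broadcasting
arithmetic, batched matmul, 1D convolution / max-pooling, group and layer
normalisation, softmax attention, and an Adam optimiser.  Gradients of
every primitive are exercised by finite-difference checks in the test
suite.

Only the features the package uses are implemented; this is not a
general-purpose framework.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

DEFAULT_DTYPE = np.float32

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / cost-matrix evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DEFAULT_DTYPE if np.asarray(data).dtype.kind == "f" else None)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd core -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def build(t: Tensor) -> None:
            stack = [t]
            while stack:
                node = stack[-1]
                if id(node) in seen:
                    stack.pop()
                    continue
                unvisited = [p for p in node._parents if id(p) not in seen]
                if unvisited:
                    stack.extend(unvisited)
                else:
                    seen.add(id(node))
                    topo.append(node)
                    stack.pop()

        build(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    pid = id(parent)
                    if pid in grads:
                        grads[pid] = grads[pid] + pg
                    else:
                        grads[pid] = pg


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DEFAULT_DTYPE))


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], list] | None) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def bw(g):
        return [(a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape))]

    return _make(data, (a, b), bw)


def sub(a, b):
    return add(a, mul(b, -1.0))


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def bw(g):
        return [(a, _unbroadcast(g * b.data, a.shape)),
                (b, _unbroadcast(g * a.data, b.shape))]

    return _make(data, (a, b), bw)


def div(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data / b.data

    def bw(g):
        return [(a, _unbroadcast(g / b.data, a.shape)),
                (b, _unbroadcast(-g * a.data / (b.data ** 2), b.shape))]

    return _make(data, (a, b), bw)


def pow_(a, exponent: float):
    a = _as_tensor(a)
    data = a.data ** exponent

    def bw(g):
        return [(a, g * exponent * a.data ** (exponent - 1))]

    return _make(data, (a,), bw)


def exp(a):
    a = _as_tensor(a)
    data = np.exp(a.data)

    def bw(g):
        return [(a, g * data)]

    return _make(data, (a,), bw)


def log(a):
    a = _as_tensor(a)
    data = np.log(a.data)

    def bw(g):
        return [(a, g / a.data)]

    return _make(data, (a,), bw)


def tanh(a):
    a = _as_tensor(a)
    data = np.tanh(a.data)

    def bw(g):
        return [(a, g * (1.0 - data ** 2))]

    return _make(data, (a,), bw)


def sigmoid(a):
    a = _as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        return [(a, g * data * (1.0 - data))]

    return _make(data, (a,), bw)


def relu(a):
    a = _as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def bw(g):
        return [(a, g * mask)]

    return _make(data, (a,), bw)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def bw(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return [(a, _unbroadcast(ga, a.shape)), (b, _unbroadcast(gb, b.shape))]

    return _make(data, (a, b), bw)


def sum_(a, axis=None, keepdims: bool = False):
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        g_arr = np.asarray(g)
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(i % a.ndim for i in ax)
            shape = [1 if i in ax else s for i, s in enumerate(a.shape)]
            g_arr = g_arr.reshape(shape)
        return [(a, np.broadcast_to(g_arr, a.shape).copy())]

    return _make(data, (a,), bw)


def mean(a, axis=None, keepdims: bool = False):
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[i % a.ndim] for i in ax]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape):
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def bw(g):
        return [(a, g.reshape(a.shape))]

    return _make(data, (a,), bw)


def transpose(a, axes):
    a = _as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def bw(g):
        return [(a, g.transpose(inv))]

    return _make(data, (a,), bw)


def getitem(a, idx):
    a = _as_tensor(a)
    data = a.data[idx]

    def bw(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return [(a, ga)]

    return _make(data, (a,), bw)


def concatenate(tensors: Sequence[Tensor], axis: int = 0):
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        out = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            out.append((t, g[tuple(sl)]))
        return out

    return _make(data, tensors, bw)


def conv1d(x, w, b=None, stride: int = 1, padding: int = 0):
    """Cross-correlation of (B, Cin, L) with (Cout, Cin, K) filters."""
    x, w = _as_tensor(x), _as_tensor(w)
    parents = [x, w]
    B, Cin, L = x.shape
    Cout, _, K = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    Lp = xp.shape[-1]
    Lout = (Lp - K) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)[:, :, ::stride]
    # (B, Cin, Lout, K) x (Cout, Cin, K) -> (B, Lout, Cout)
    data = np.tensordot(win, w.data, axes=[(1, 3), (1, 2)]).transpose(0, 2, 1)
    if b is not None:
        b = _as_tensor(b)
        parents.append(b)
        data = data + b.data[:, None]

    def bw(g):
        gw = np.tensordot(g, win, axes=[(0, 2), (0, 2)])
        contrib = np.tensordot(g, w.data, axes=[(1,), (0,)]).transpose(0, 2, 1, 3)
        gxp = np.zeros_like(xp)
        for k in range(K):
            gxp[:, :, k:k + (Lout - 1) * stride + 1:stride] += contrib[:, :, :, k]
        gx = gxp[:, :, padding:Lp - padding] if padding else gxp
        grads = [(x, gx), (w, gw)]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2))))
        return grads

    return _make(data, parents, bw)


def maxpool1d(x, kernel: int, stride: int):
    x = _as_tensor(x)
    B, C, L = x.shape
    Lout = (L - kernel) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x.data, kernel, axis=2)[:, :, ::stride]
    arg = win.argmax(axis=-1)
    data = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        gx = np.zeros_like(x.data)
        for k in range(kernel):
            m = arg == k
            sel = np.zeros_like(g)
            sel[m] = g[m]
            gx[:, :, k:k + (Lout - 1) * stride + 1:stride] += sel
        return [(x, gx)]

    return _make(data, (x,), bw)


def group_norm(x, weight, bias, num_groups: int, eps: float = 1e-5):
    """Fused per-sample group normalisation over (B, C, L) with channel affine."""
    x, weight, bias = _as_tensor(x), _as_tensor(weight), _as_tensor(bias)
    B, C, L = x.shape
    g = num_groups
    xg = x.data.reshape(B, g, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(B, C, L)
    data = xhat * weight.data[:, None] + bias.data[:, None]

    def bw(grad):
        gweight = (grad * xhat).sum(axis=(0, 2))
        gbias = grad.sum(axis=(0, 2))
        dxhat = (grad * weight.data[:, None]).reshape(B, g, -1)
        xh = xhat.reshape(B, g, -1)
        m1 = dxhat.mean(axis=2, keepdims=True)
        m2 = (dxhat * xh).mean(axis=2, keepdims=True)
        gx = (inv * (dxhat - m1 - xh * m2)).reshape(B, C, L)
        return [(x, gx), (weight, gweight), (bias, gbias)]

    return _make(data, (x, weight, bias), bw)


def layer_norm(x, weight, bias, eps: float = 1e-5):
    """Fused normalisation over the last axis with elementwise affine."""
    x, weight, bias = _as_tensor(x), _as_tensor(weight), _as_tensor(bias)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    data = xhat * weight.data + bias.data

    def bw(grad):
        axes = tuple(range(grad.ndim - 1))
        gweight = (grad * xhat).sum(axis=axes)
        gbias = grad.sum(axis=axes)
        dxhat = grad * weight.data
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        gx = inv * (dxhat - m1 - xhat * m2)
        return [(x, gx), (weight, gweight), (bias, gbias)]

    return _make(data, (x, weight, bias), bw)


def softmax(x, axis: int = -1):
    x = _as_tensor(x)
    shifted = sub(x, Tensor(x.data.max(axis=axis, keepdims=True)))
    e = exp(shifted)
    return div(e, sum_(e, axis=axis, keepdims=True))


def log_softmax(x, axis: int = -1):
    x = _as_tensor(x)
    shifted = sub(x, Tensor(x.data.max(axis=axis, keepdims=True)))
    return sub(shifted, log(sum_(exp(shifted), axis=axis, keepdims=True)))


def minimum(a, b):
    """Elementwise min, differentiable a.e.: min(a, b) = a - relu(a - b)."""
    return sub(a, relu(sub(a, b)))


def maximum(a, b):
    return add(a, relu(sub(b, a)))


def abs_(a):
    a = _as_tensor(a)
    sign = np.sign(a.data)
    data = np.abs(a.data)

    def bw(g):
        return [(a, g * sign)]

    return _make(data, (a,), bw)


# Bind operators for convenience.
Tensor.__add__ = lambda self, o: add(self, o)
Tensor.__radd__ = lambda self, o: add(o, self)
Tensor.__sub__ = lambda self, o: sub(self, o)
Tensor.__rsub__ = lambda self, o: sub(o, self)
Tensor.__mul__ = lambda self, o: mul(self, o)
Tensor.__rmul__ = lambda self, o: mul(o, self)
Tensor.__truediv__ = lambda self, o: div(self, o)
Tensor.__neg__ = lambda self: mul(self, -1.0)
Tensor.__matmul__ = lambda self, o: matmul(self, o)
Tensor.__pow__ = lambda self, e: pow_(self, e)
Tensor.__getitem__ = getitem
Tensor.reshape = reshape
Tensor.transpose = transpose
Tensor.sum = sum_
Tensor.mean = mean


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class; collects Parameters from attributes, lists and submodules."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []

        def walk(obj, key: str) -> None:
            if isinstance(obj, Parameter):
                out.append((key, obj))
            elif isinstance(obj, Module):
                for name, v in vars(obj).items():
                    walk(v, f"{key}.{name}" if key else name)
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    walk(item, f"{key}.{i}")

        walk(self, prefix.rstrip("."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        bound = np.sqrt(1.0 / in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        if self.bias is not None:
            y = add(y, self.bias)
        return y


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        std = np.sqrt(2.0 / fan_in)  # Kaiming, ReLU networks
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class GroupNorm(Module):
    """Batch-independent channel-group normalisation over (B, C, L)."""

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        if num_channels % num_groups:
            raise ValueError("channels must divide evenly into groups")
        self.num_groups = num_groups
        self.num_channels = num_channels
        self.eps = eps
        self.weight = Parameter(np.ones(num_channels))
        self.bias = Parameter(np.zeros(num_channels))

    def forward(self, x: Tensor) -> Tensor:
        return group_norm(x, self.weight, self.bias, self.num_groups, self.eps)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.dim = dim
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.weight, self.bias, self.eps)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class MultiheadAttention(Module):
    """Standard scaled dot-product attention with shared projections."""

    def __init__(self, dim: int, num_heads: int, rng: np.random.Generator | None = None):
        if dim % num_heads:
            raise ValueError("dim must be divisible by num_heads")
        rng = rng or np.random.default_rng()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.q_proj = Linear(dim, dim, rng=rng)
        self.k_proj = Linear(dim, dim, rng=rng)
        self.v_proj = Linear(dim, dim, rng=rng)
        self.out_proj = Linear(dim, dim, rng=rng)

    def _split(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        return transpose(reshape(x, (B, L, self.num_heads, self.head_dim)), (0, 2, 1, 3))

    def forward(self, query: Tensor, key: Tensor, value: Tensor) -> Tensor:
        _, Lq, D = query.shape
        q = self._split(self.q_proj(query))
        k = self._split(self.k_proj(key))
        v = self._split(self.v_proj(value))
        scores = mul(matmul(q, transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(self.head_dim))
        attn = softmax(scores, axis=-1)
        ctx = matmul(attn, v)  # cross-attention may broadcast the batch axis
        B_out = ctx.shape[0]
        ctx = reshape(transpose(ctx, (0, 2, 1, 3)), (B_out, Lq, D))
        return self.out_proj(ctx)


class Adam:
    """Adam with decoupled weight decay and optional per-group learning-rate scale."""

    def __init__(self, param_groups: Iterable[dict], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.groups = []
        for group in param_groups:
            if isinstance(group, Parameter):
                group = {"params": [group]}
            g = {"params": list(group["params"]),
                 "lr_scale": float(group.get("lr_scale", 1.0))}
            self.groups.append(g)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._t = 0

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        for g in self.groups:
            lr = self.lr * g["lr_scale"]
            for p in g["params"]:
                if p.grad is None:
                    continue
                m, v = self._state.get(id(p), (np.zeros_like(p.data), np.zeros_like(p.data)))
                grad = p.grad.astype(p.data.dtype)
                m = b1 * m + (1 - b1) * grad
                v = b2 * v + (1 - b2) * grad ** 2
                self._state[id(p)] = (m, v)
                mhat = m / (1 - b1 ** self._t)
                vhat = v / (1 - b2 ** self._t)
                if self.weight_decay:
                    p.data = p.data - lr * self.weight_decay * p.data
                p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)


def numerical_gradient(fn: Callable[[], Tensor], param: Tensor, eps: float = 1e-4) -> np.ndarray:
    """Central finite-difference gradient of scalar `fn()` w.r.t. `param`."""
    grad = np.zeros_like(param.data, dtype=np.float64)
    flat = param.data.reshape(-1)
    gflat = grad.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = float(fn().data)
        flat[i] = orig - eps
        lo = float(fn().data)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return grad
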