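"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the package's compute engine: a :class:`Tensor` wrapping an
``ndarray`` with a recorded backward function, a handful of differentiable
operations (dense/batched matmul with broadcasting, elementwise
nonlinearities, reductions, gather/scatter along the node axis, a fused
LSTM, 1-D unfolding for convolutions, and a fused softmax cross-entropy),
and an Adam optimizer.  Every operation's gradient is validated against
central finite differences in the test suite.
"""

from __future__ import annotations

import weakref
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "glorot_uniform",
    "take_nodes",
    "segment_sum_nodes",
    "lstm",
    "unfold1d",
    "dropout",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "__weakref__")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype)
        self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep seeding d(self)/d(self) = 1 (self must be scalar)."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division by a Tensor is not supported")
        return self * (1.0 / other)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        a, b = self.data, other.data
        out = Tensor(a @ b, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

        out._backward = backward
        return out

    # ------------------------------------------------------------ elementwise
    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = _sigmoid(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data, dtype=g.dtype)
            np.add.at(full, key, g)
            self._accumulate(full)

        out._backward = backward
        return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def constant(data) -> Tensor:
    return Tensor(np.asarray(data))


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: Sequence[int] | None = None,
                   dtype=np.float32) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = (fan_in, fan_out) if shape is None else tuple(shape)
    return parameter(rng.uniform(-limit, limit, size=shape).astype(dtype))


# ------------------------------------------------------------------ gather/scatter
def take_nodes(t: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows along axis 1: (B, N, F)[:, idx] -> (B, E, F)."""
    out = Tensor(t.data[:, idx], parents=(t,))

    def backward(g):
        full = np.zeros_like(t.data, dtype=g.dtype)
        np.add.at(full, (slice(None), idx), g)
        t._accumulate(full)

    out._backward = backward
    return out


def segment_sum_nodes(t: Tensor, idx: np.ndarray, n: int) -> Tensor:
    """Scatter-add rows along axis 1: (B, E, F) summed into (B, n, F) at idx."""
    data = np.zeros((t.data.shape[0], n, t.data.shape[2]), dtype=t.data.dtype)
    np.add.at(data, (slice(None), idx), t.data)
    out = Tensor(data, parents=(t,))
    out._backward = lambda g: t._accumulate(g[:, idx])
    return out


# ------------------------------------------------------------------ fused LSTM
# Reusable per-shape work buffers: repeated training steps on same-shaped
# batches would otherwise pay the page-fault cost of ~100 MB of fresh
# allocations on every forward pass.  A workspace is checked out for the
# lifetime of the output tensor (whose backward closure reads the stored
# activations) and returned to the pool when that tensor is collected.
_LSTM_POOL: dict[tuple, list[dict[str, np.ndarray]]] = {}
_LSTM_POOL_LIMIT = 4


def _lstm_checkout(T: int, S: int, H: int, dtype):
    key = (T, S, H, np.dtype(dtype).str)
    pool = _LSTM_POOL.setdefault(key, [])
    if pool:
        return key, pool.pop()
    return key, {
        "gates": np.empty((T, S, 4 * H), dtype=dtype),
        "c": np.empty((T, S, H), dtype=dtype),
        "tc": np.empty((T, S, H), dtype=dtype),
        "h": np.empty((T, S, H), dtype=dtype),
        "hw": np.empty((S, 4 * H), dtype=dtype),
        "tmp": np.empty((S, H), dtype=dtype),
    }


def _lstm_checkin(key: tuple, ws: dict[str, np.ndarray]) -> None:
    if sum(len(v) for v in _LSTM_POOL.values()) < _LSTM_POOL_LIMIT:
        _LSTM_POOL.setdefault(key, []).append(ws)


def lstm(x: np.ndarray, wx: Tensor, wh: Tensor, b: Tensor,
         output: str = "last") -> Tensor:
    """Run a single-feature LSTM over (S, T) sequences with shared weights.

    ``wx`` is (1, 4H), ``wh`` is (H, 4H), ``b`` is (4H,); the gate layout is
    [input, forget, cell, output].  Returns the final hidden state (S, H)
    when ``output == "last"``, or the time-mean of hidden states for
    ``"mean"``.  Forward and backward passes are fused (single graph node)
    so long sequences do not inflate the autodiff graph.
    """
    if output not in ("last", "mean"):
        raise ValueError(f"unknown output mode {output!r}")
    S, T = x.shape
    H = wh.data.shape[0]
    dtype = wh.data.dtype
    xT = np.ascontiguousarray(np.asarray(x, dtype=dtype).T)  # (T, S)

    key, ws = _lstm_checkout(T, S, H, dtype)
    # activated gates per step, layout [i | f | o | g] along the last axis;
    # time-major storage keeps every per-step slice contiguous
    gates, c_s, tc_s, h_s = ws["gates"], ws["c"], ws["tc"], ws["h"]
    hw, tmp = ws["hw"], ws["tmp"]

    h = np.zeros((S, H), dtype=dtype)
    c = np.zeros((S, H), dtype=dtype)
    with np.errstate(over="ignore"):
        for t in range(T):
            z = gates[t]
            np.outer(xT[t], wx.data[0], out=z)
            np.matmul(h, wh.data, out=hw)
            z += hw
            z += b.data
            zs = z[:, :3 * H]  # sigmoid gates i, f, o
            np.negative(zs, out=zs)
            np.exp(zs, out=zs)
            zs += 1.0
            np.reciprocal(zs, out=zs)
            zg = z[:, 3 * H:]
            np.tanh(zg, out=zg)
            i = z[:, :H]
            f = z[:, H:2 * H]
            o = z[:, 2 * H:3 * H]
            g = z[:, 3 * H:]
            cn = c_s[t]
            np.multiply(f, c, out=cn)
            np.multiply(i, g, out=tmp)
            cn += tmp
            tc = np.tanh(cn, out=tc_s[t])
            hn = h_s[t]
            np.multiply(o, tc, out=hn)
            h, c = hn, cn

    out_data = h_s[-1].copy() if output == "last" else h_s.mean(axis=0)
    out = Tensor(out_data, parents=(wx, wh, b))
    weakref.finalize(out, _lstm_checkin, key, ws)

    def backward(grad):
        dtype_g = grad.dtype
        dwx = np.zeros_like(wx.data)
        dwh = np.zeros_like(wh.data)
        db = np.zeros_like(b.data)
        dh_next = np.zeros((S, H), dtype=dtype_g)
        dc = np.empty((S, H), dtype=dtype_g)
        dz = np.empty((S, 4 * H), dtype=dtype_g)
        dh = np.empty((S, H), dtype=dtype_g)
        tmp_b = np.empty((S, H), dtype=dtype_g)
        wh_t = np.ascontiguousarray(wh.data.T)
        g_scaled = None if output == "last" else grad / T
        dc[:] = 0.0
        for t in range(T - 1, -1, -1):
            if output == "last":
                if t == T - 1:
                    np.add(dh_next, grad, out=dh)
                else:
                    dh[:] = dh_next
            else:
                np.add(dh_next, g_scaled, out=dh)
            i = gates[t, :, :H]
            f = gates[t, :, H:2 * H]
            o = gates[t, :, 2 * H:3 * H]
            g = gates[t, :, 3 * H:]
            tc = tc_s[t]
            # dc += dh * o * (1 - tc^2); reuse tmp_b for intermediates
            np.multiply(tc, tc, out=tmp_b)
            np.subtract(1.0, tmp_b, out=tmp_b)
            tmp_b *= o
            tmp_b *= dh
            dc += tmp_b
            # gate-input gradients, layout [i | f | o | g]
            dzi = dz[:, :H]
            np.multiply(dc, g, out=dzi)        # di
            dzi *= i
            np.subtract(1.0, i, out=tmp_b)
            dzi *= tmp_b
            dzf = dz[:, H:2 * H]
            if t > 0:
                np.multiply(dc, c_s[t - 1], out=dzf)  # df
                dzf *= f
                np.subtract(1.0, f, out=tmp_b)
                dzf *= tmp_b
            else:
                dzf[:] = 0.0
            dzo = dz[:, 2 * H:3 * H]
            np.multiply(dh, tc, out=dzo)       # do
            dzo *= o
            np.subtract(1.0, o, out=tmp_b)
            dzo *= tmp_b
            dzg = dz[:, 3 * H:]
            np.multiply(dc, i, out=dzg)        # dg
            np.multiply(g, g, out=tmp_b)
            np.subtract(1.0, tmp_b, out=tmp_b)
            dzg *= tmp_b
            db += dz.sum(axis=0)
            dwx[0] += xT[t] @ dz
            if t > 0:
                dwh += h_s[t - 1].T @ dz
            np.matmul(dz, wh_t, out=dh_next)
            dc *= f                             # dc for step t-1
        if wx.requires_grad:
            wx._accumulate(dwx)
        if wh.requires_grad:
            wh._accumulate(dwh)
        if b.requires_grad:
            b._accumulate(db)

    out._backward = backward
    return out


# ------------------------------------------------------------------ convolution
# same checkout/checkin buffer reuse as the LSTM: unfolding reallocates a
# size-fold copy of the input every step otherwise
_UNFOLD_POOL: dict[tuple, list[np.ndarray]] = {}


def _unfold_checkout(shape, dtype):
    key = (shape, np.dtype(dtype).str)
    pool = _UNFOLD_POOL.setdefault(key, [])
    return key, (pool.pop() if pool else np.empty(shape, dtype=dtype))


def _unfold_checkin(key, buf):
    if sum(len(v) for v in _UNFOLD_POOL.values()) < 8:
        _UNFOLD_POOL.setdefault(key, []).append(buf)


def unfold1d(t: Tensor, size: int) -> Tensor:
    """Sliding windows along axis 1: (S, T, C) -> (S, T-size+1, size*C)."""
    S, T, C = t.data.shape
    L = T - size + 1
    win = np.lib.stride_tricks.sliding_window_view(t.data, size, axis=1)
    key, data = _unfold_checkout((S, L, size * C), t.data.dtype)
    np.copyto(data.reshape(S, L, size, C), win.transpose(0, 1, 3, 2))
    out = Tensor(data, parents=(t,))
    weakref.finalize(out, _unfold_checkin, key, data)

    def backward(g):
        g4 = g.reshape(S, L, size, C)
        full = np.zeros_like(t.data, dtype=g.dtype)
        for j in range(size):
            full[:, j:j + L] += g4[:, :, j]
        t._accumulate(full)

    out._backward = backward
    return out


def dropout(t: Tensor, p: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return t
    mask = (rng.random(t.data.shape) >= p).astype(t.data.dtype) / (1.0 - p)
    return t * constant(mask)


# ------------------------------------------------------------------ loss
def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy over a batch of integer labels."""
    probs = softmax(logits.data)
    n = logits.data.shape[0]
    nll = -np.log(np.maximum(probs[np.arange(n), labels], 1e-12))
    out = Tensor(np.asarray(nll.mean()), parents=(logits,))

    def backward(g):
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accumulate(g * grad / n)

    out._backward = backward
    return out


# ------------------------------------------------------------------ optimizer
class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[k]
            v = self._v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
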