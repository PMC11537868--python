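"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough primitives for a small transformer encoder and MLP heads:
broadcast arithmetic, batched matmul, softmax, layer norm, gathers for
embeddings and relative-position lookups, and a fused label-smoothed
cross-entropy.  Gradient correctness is checked against central finite
differences in the test suite.

All parameters and activations are float32; this engine is single-threaded
and deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "AdamW"]

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @classmethod
    def _op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=DTYPE)  # copy: grad may alias a child's grad
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        a, b = self, Tensor._wrap(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._op(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, Tensor._wrap(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._op(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __matmul__(self, other):
        a, b = self, Tensor._wrap(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

        return Tensor._op(a.data @ b.data, (a, b), backward)

    def power(self, p: float):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g * p * np.power(a.data, p - 1))

        return Tensor._op(np.power(a.data, p), (a,), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(g):
            a._accum(g.reshape(old))

        return Tensor._op(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(*inv))

        return Tensor._op(a.data.transpose(*axes), (a,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).astype(DTYPE))

        return Tensor._op(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        a = self
        mask = (a.data > 0).astype(DTYPE)

        def backward(g):
            a._accum(g * mask)

        return Tensor._op(a.data * mask, (a,), backward)

    def gelu(self):
        """tanh-approximation GELU (float32 throughout)."""
        a = self
        x = a.data
        c = DTYPE(np.sqrt(2.0 / np.pi))
        x2 = x * x
        t = np.tanh(c * (x + DTYPE(0.044715) * x2 * x))
        y = DTYPE(0.5) * x * (DTYPE(1.0) + t)
        dydx = DTYPE(0.5) * (DTYPE(1.0) + t) + DTYPE(0.5) * x * (DTYPE(1.0) - t * t) * c * (
            DTYPE(1.0) + DTYPE(3 * 0.044715) * x2
        )

        def backward(g):
            a._accum(g * dydx)

        return Tensor._op(y, (a,), backward)

    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accum(s * (g - dot))

        return Tensor._op(s, (a,), backward)

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-5):
        """Normalize over the last axis, then scale and shift."""
        a = self
        x = a.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out = xhat * gain.data + bias.data
        n = x.shape[-1]

        def backward(g):
            if gain.requires_grad:
                gain._accum(_unbroadcast(g * xhat, gain.data.shape))
            if bias.requires_grad:
                bias._accum(_unbroadcast(g, bias.data.shape))
            if a.requires_grad:
                gx = g * gain.data
                term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                a._accum(term * inv)

        return Tensor._op(out, (a, gain, bias), backward)

    # -- gathers -----------------------------------------------------------
    def embed(self, idx: np.ndarray):
        """Row lookup ``self[idx]`` along axis 0 (embedding table)."""
        a = self
        idx = np.asarray(idx)

        def backward(g):
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx.reshape(-1), g.reshape(-1, a.data.shape[-1]))
            a._accum(acc)

        return Tensor._op(a.data[idx], (a,), backward)

    def gather_last(self, idx: np.ndarray):
        """``out[..., i, j] = self[..., i, idx[i, j]]`` for a 2-D index map.

        Used to expand per-offset scores (..., N, M) into pairwise scores
        (..., N, N) through a relative-position index matrix.
        """
        a = self
        idx = np.asarray(idx)
        bshape = a.data.shape[:-2]
        full_idx = np.broadcast_to(idx, bshape + idx.shape)
        out = np.take_along_axis(a.data, full_idx, axis=-1)
        rows = np.broadcast_to(
            np.arange(idx.shape[0])[:, None], idx.shape
        )

        def backward(g):
            acc = np.zeros_like(a.data)
            flat_acc = acc.reshape(-1, *a.data.shape[-2:])
            flat_g = g.reshape(-1, *idx.shape)
            for b in range(flat_acc.shape[0]):
                np.add.at(flat_acc[b], (rows, idx), flat_g[b])
            a._accum(acc)

        return Tensor._op(out, (a,), backward)

    def take_rows(self, idx: np.ndarray):
        """Row selection for 2-D tensors (loss over selected positions)."""
        return self.embed(idx)

    # -- fused loss --------------------------------------------------------
    def cross_entropy_smoothed(self, labels: np.ndarray, eps: float = 0.0):
        """Mean label-smoothed cross-entropy over rows of an (n, V) logit matrix.

        Target distribution per row: (1-eps) one-hot + eps/V uniform.
        """
        a = self
        labels = np.asarray(labels)
        n, v = a.data.shape
        if n == 0:
            raise ValueError("cross entropy over zero rows")
        z = a.data - a.data.max(axis=-1, keepdims=True)
        logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
        logp = z - logsumexp
        q = np.full((n, v), eps / v, dtype=DTYPE)
        q[np.arange(n), labels] += 1.0 - eps
        loss = -(q * logp).sum() / n

        def backward(g):
            p = np.exp(logp)
            a._accum(g * (p - q) / n)

        return Tensor._op(np.asarray(loss, dtype=DTYPE), (a,), backward)


class AdamW:
    """Decoupled weight decay Adam over a dict of named parameters."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 3e-4,
        betas: tuple[float, float] = (0.9, 0.99),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
        no_decay: tuple[str, ...] = ("bias", "ln_", "_b"),
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.no_decay = no_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def _decays(self, name: str) -> bool:
        return not any(tag in name for tag in self.no_decay)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self, clip_norm: float | None = 1.0) -> float:
        """One update; returns the pre-clip global gradient norm."""
        grads = {
            k: (p.grad if p.grad is not None else np.zeros_like(p.data))
            for k, p in self.params.items()
        }
        gnorm = float(np.sqrt(sum(float((g**2).sum()) for g in grads.values())))
        scale = 1.0
        if clip_norm is not None and gnorm > clip_norm > 0:
            scale = clip_norm / (gnorm + 1e-12)
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            g = grads[k] * scale
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            if self.weight_decay and self._decays(k):
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return gnorm

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": {k: v.copy() for k, v in self.m.items()},
            "v": {k: v.copy() for k, v in self.v.items()},
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = state["t"]
        self.m = {k: np.array(v) for k, v in state["m"].items()}
        self.v = {k: np.array(v) for k, v in state["v"].items()}
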