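"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The fall-detection network is small (token widths of 9 or 81), so a compact
float64 tape is both fast enough on one CPU and bitwise deterministic, which
the reproducibility contract of the training pipeline relies on.

Only the operations the patch-transformer needs are implemented: broadcasted
arithmetic, batched matmul, reshapes, ReLU/GELU, row softmax, layer
normalisation, mean-pooling, padding and gather (for im2col convolution), and
a fused softmax cross-entropy.  Gradients accumulate into ``Tensor.grad``
after calling :meth:`Tensor.backward` on a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar) -> "Tensor":
        if isinstance(scalar, Tensor):
            raise TypeError("division is only supported by constants")
        return self * (1.0 / scalar)

    def __matmul__(self, other) -> "Tensor":
        other = self._coerce(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g, a=self, old=old):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def swapaxes(self, ax1: int, ax2: int) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(np.swapaxes(g, ax1, ax2))

        return Tensor._from_op(np.swapaxes(self.data, ax1, ax2), (self,), backward)

    def pad2d(self, pad: int) -> "Tensor":
        """Zero-pad the two spatial axes of a (B, H, W, C) tensor."""
        widths = ((0, 0), (pad, pad), (pad, pad), (0, 0))

        def backward(g, a=self, p=pad):
            if a.requires_grad:
                a._accumulate(g[:, p:-p or None, p:-p or None, :])

        return Tensor._from_op(np.pad(self.data, widths), (self,), backward)

    def gather_rows(self, index: np.ndarray) -> "Tensor":
        """Index axis 1 of a (B, M, C) tensor with an integer array.

        Output shape is (B, *index.shape, C); the backward pass scatter-adds,
        so repeated indices (overlapping conv patches) accumulate correctly.
        """
        out = self.data[:, index, :]

        def backward(g, a=self, idx=index):
            if a.requires_grad:
                ga = np.zeros_like(a.data)
                np.add.at(ga, (slice(None), idx), g)
                a._accumulate(ga)

        return Tensor._from_op(out, (self,), backward)

    # -- nonlinearities and reductions ----------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accumulate(g * m)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def gelu(self) -> "Tensor":
        # tanh approximation of GELU
        c = np.sqrt(2.0 / np.pi)
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out = 0.5 * x * (1.0 + t)

        def backward(g, a=self, t=t, x=x, c=c):
            sech2 = 1.0 - t**2
            local = 0.5 * (1.0 + t) + 0.5 * x * sech2 * c * (1.0 + 3 * 0.044715 * x**2)
            if a.requires_grad:
                a._accumulate(g * local)

        return Tensor._from_op(out, (self,), backward)

    def softmax(self) -> "Tensor":
        """Row-wise softmax over the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)

        def backward(g, a=self, s=s):
            if a.requires_grad:
                dot = (g * s).sum(axis=-1, keepdims=True)
                a._accumulate(s * (g - dot))

        return Tensor._from_op(s, (self,), backward)

    def layernorm(self, eps: float = 1e-5) -> "Tensor":
        """Normalise the last axis to zero mean and unit variance."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv

        def backward(g, a=self, y=y, inv=inv):
            n = y.shape[-1]
            if a.requires_grad:
                gm = g.mean(axis=-1, keepdims=True)
                gym = (g * y).mean(axis=-1, keepdims=True)
                a._accumulate(inv * (g - gm - y * gym))

        return Tensor._from_op(y, (self,), backward)

    def mean(self, axis: int) -> "Tensor":
        n = self.data.shape[axis]

        def backward(g, a=self, axis=axis, n=n):
            if a.requires_grad:
                a._accumulate(np.expand_dims(g, axis).repeat(n, axis) / n)

        return Tensor._from_op(self.data.mean(axis=axis), (self,), backward)

    # -- tape ------------------------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Differentiable concatenation."""
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, offs=offsets, axis=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._from_op(data, tuple(tensors), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between row logits and integer class labels."""
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    n = logits.data.shape[0]
    loss = -logp[np.arange(n), labels].mean()

    def backward(g, a=logits, labels=labels, logp=logp, n=n):
        if a.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            a._accumulate(g * p / n)

    return Tensor._from_op(loss, (logits,), backward)
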