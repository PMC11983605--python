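"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the hybrid tabular classifier: a ``Tensor``
wrapping an ndarray, a handful of differentiable primitives (matmul, conv via
im2col, element-wise nonlinearities, the feature-pair bilinear map used by the
topology stage) and a fused softmax cross-entropy head.  Gradients are
accumulated on a tape and released after ``backward``.

Every primitive's gradient is exercised against central finite differences in
the test suite; nothing here is architecture-specific.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor"]


class Tensor:
    """An ndarray plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, parents: Iterable["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        # collapse broadcast axes back onto the parameter's shape
        extra = grad.ndim - self.data.ndim
        if extra > 0:
            grad = grad.sum(axis=tuple(range(extra)))
        for ax, n in enumerate(self.data.shape):
            if n == 1 and grad.shape[ax] != 1:
                grad = grad.sum(axis=ax, keepdims=True)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        # free the graph
        for node in topo:
            node._backward = None
            node._parents = ()

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        def backward():
            self._accum(out.grad)
            other._accum(out.grad)

        out = self._make(self.data + other.data, (self, other), backward)
        return out

    def __mul__(self, other: "Tensor") -> "Tensor":
        def backward():
            self._accum(out.grad * other.data)
            other._accum(out.grad * self.data)

        out = self._make(self.data * other.data, (self, other), backward)
        return out

    def scale(self, c: float) -> "Tensor":
        def backward():
            self._accum(out.grad * c)

        out = self._make(self.data * c, (self,), backward)
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        def backward():
            self._accum(out.grad @ other.data.T)
            other._accum(self.data.T @ out.grad)

        out = self._make(self.data @ other.data, (self, other), backward)
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        def backward():
            self._accum(out.grad.reshape(self.data.shape))

        out = self._make(self.data.reshape(*shape), (self,), backward)
        return out

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward():
            for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
                t._accum(g)

        cat = np.concatenate([t.data for t in tensors], axis=axis)
        out = tensors[0]._make(cat, tensors, backward)
        return out

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        def backward():
            g = np.zeros_like(self.data)
            g[..., start:stop] = out.grad
            self._accum(g)

        out = self._make(self.data[..., start:stop], (self,), backward)
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward():
            self._accum(out.grad * mask)

        out = self._make(np.where(mask, self.data, 0.0), (self,), backward)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward():
            self._accum(out.grad * s * (1.0 - s))

        out = self._make(s, (self,), backward)
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def backward():
            self._accum(out.grad * (1.0 - t * t))

        out = self._make(t, (self,), backward)
        return out

    def dropout(self, p: float, rng: np.random.Generator | None) -> "Tensor":
        """Inverted dropout; identity when rng is None (inference) or p == 0."""
        if rng is None or p <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= p) / (1.0 - p)

        def backward():
            self._accum(out.grad * mask)

        out = self._make(self.data * mask, (self,), backward)
        return out

    # -- structured ops ----------------------------------------------------

    def conv1d_same(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """1-D cross-correlation, stride 1, 'same' zero padding.

        self: (B, C_in, F); weight: (C_out, C_in, k); bias: (C_out,).
        """
        B, C_in, F = self.data.shape
        C_out, _, k = weight.data.shape
        pad = (k - 1) // 2
        xp = np.pad(self.data, ((0, 0), (0, 0), (pad, k - 1 - pad)))
        # im2col: (B, F, C_in*k)
        cols = np.stack([xp[:, :, i : i + F] for i in range(k)], axis=-1)
        cols = cols.transpose(0, 2, 1, 3).reshape(B, F, C_in * k)
        Wm = weight.data.reshape(C_out, C_in * k)
        z = cols @ Wm.T + bias.data  # (B, F, C_out)

        def backward():
            g = out.grad.transpose(0, 2, 1)  # (B, F, C_out)
            bias._accum(g.sum(axis=(0, 1)))
            gw = g.reshape(B * F, C_out).T @ cols.reshape(B * F, C_in * k)
            weight._accum(gw.reshape(C_out, C_in, k))
            gcols = (g @ Wm).reshape(B, F, C_in, k).transpose(0, 2, 1, 3)
            gx = np.zeros_like(xp)
            for i in range(k):
                gx[:, :, i : i + F] += gcols[:, :, :, i]
            self._accum(gx[:, :, pad : pad + F])

        out = self._make(z.transpose(0, 2, 1), (self, weight, bias), backward)
        # note: z stored as (B, C_out, F)
        return out

    def pair_bilinear(self, weight: "Tensor") -> "Tensor":
        """Feature-pair map: out[b,i,j] = weight[i,j,:] . self[b,:].

        self: (B, D); weight: (D, D, D).  The ReLU of this is the learned
        adjacency matrix of the topology-refinement stage.
        """

        D = weight.data.shape[0]
        B = self.data.shape[0]
        Wm = weight.data.reshape(D * D, D)

        def backward():
            g = out.grad.reshape(B, D * D)  # (B, D*D)
            weight._accum((g.T @ self.data).reshape(D, D, D))
            self._accum(g @ Wm)

        z = (self.data @ Wm.T).reshape(B, D, D)
        out = self._make(z, (self, weight), backward)
        return out

    def bmm_vec(self, vec: "Tensor") -> "Tensor":
        """Batched matrix-vector product: (B, D, D) @ (B, D) -> (B, D)."""

        def backward():
            g = out.grad  # (B, D)
            self._accum(g[:, :, None] * vec.data[:, None, :])
            vec._accum(np.matmul(self.data.transpose(0, 2, 1), g[:, :, None])[..., 0])

        z = np.matmul(self.data, vec.data[:, :, None])[..., 0]
        out = self._make(z, (self, vec), backward)
        return out

    # -- losses ------------------------------------------------------------

    def softmax_cross_entropy(self, labels: np.ndarray) -> "Tensor":
        """Mean cross-entropy of softmax(self) against integer labels."""
        z = self.data - self.data.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        n = z.shape[0]
        loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-300))

        def backward():
            g = probs.copy()
            g[np.arange(n), labels] -= 1.0
            self._accum(out.grad * g / n)

        out = self._make(loss, (self,), backward)
        return out

    def sum_squares(self) -> "Tensor":
        def backward():
            self._accum(out.grad * 2.0 * self.data)

        out = self._make(np.sum(self.data * self.data), (self,), backward)
        return out
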