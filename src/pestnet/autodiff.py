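"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The cascade model needs gradients through convolutions, pooling, softmax
losses and — unusually — through the box parameters of a differentiable
crop-and-zoom.  This module provides a small tape-based engine with exactly
the operators the model uses.  Arrays are float32 throughout the network
path; the engine is deterministic (no threading, stable reduction order),
which the training reproducibility contract relies on.

Conventions: image tensors are NCHW; convolutions are 3x3, stride 1,
zero-padded ("same"); pooling is 2x2 max with stride 2.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad"]


class Tensor:
    """An array node on the autodiff tape.

    Supports the arithmetic the model needs (+, -, *, /, matmul) plus the
    neural-network operators defined as methods / module functions.  Call
    :meth:`backward` on a scalar result to populate ``.grad`` on every
    reachable tensor created with ``requires_grad=True``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32, copy=True)
        else:
            self.grad += g

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- backward pass -------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order by DFS
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------------

    @staticmethod
    def _unbroadcast(g, shape):
        """Sum gradient g down to `shape` (inverse of NumPy broadcasting)."""
        extra = g.ndim - len(shape)
        if extra > 0:
            g = g.sum(axis=tuple(range(extra)))
        axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
        if axes:
            g = g.sum(axis=axes, keepdims=True)
        return g

    def _coerce(self, other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def bwd(g):
            self._accum(Tensor._unbroadcast(g, self.data.shape))
            other._accum(Tensor._unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def bwd(g):
            self._accum(Tensor._unbroadcast(g * other.data, self.data.shape))
            other._accum(Tensor._unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def bwd(g):
            self._accum(Tensor._unbroadcast(g / other.data, self.data.shape))
            other._accum(
                Tensor._unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        return Tensor._make(out_data, (self, other), bwd)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), bwd)

    # -- reductions / reshapes -----------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        old = self.data.shape
        out_data = self.data.reshape(*shape)

        def bwd(g):
            self._accum(g.reshape(old))

        return Tensor._make(out_data, (self,), bwd)

    # -- nonlinearities -------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), bwd)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))

        def bwd(g):
            self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bwd)

    def log(self, floor: float = 0.0):
        """Natural log; values below `floor` are clamped (gradient passes
        only through unclamped entries)."""
        x = np.maximum(self.data, floor) if floor > 0 else self.data
        out_data = np.log(x)
        unclamped = self.data >= floor

        def bwd(g):
            self._accum(g * unclamped / np.maximum(self.data, floor))

        return Tensor._make(out_data, (self,), bwd)

    def clip(self, lo, hi):
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data >= lo) & (self.data <= hi)

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), bwd)

    def softmax(self):
        """Row-wise softmax over the last axis (numerically stable)."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)

        def bwd(g):
            dot = (g * p).sum(axis=-1, keepdims=True)
            self._accum(p * (g - dot))

        return Tensor._make(p, (self,), bwd)

    def take_rows(self, idx):
        """out[i] = self[i, idx[i]] — gather one entry per row."""
        idx = np.asarray(idx)
        rows = np.arange(self.data.shape[0])
        out_data = self.data[rows, idx]

        def bwd(g):
            gi = np.zeros_like(self.data)
            gi[rows, idx] = g
            self._accum(gi)

        return Tensor._make(out_data, (self,), bwd)

    # -- neural-network layers ------------------------------------------------

    def conv3x3(self, weight: "Tensor", bias: "Tensor"):
        """3x3 same-padding convolution, NCHW.

        weight: (Cout, Cin, 3, 3); bias: (Cout,).  Implemented as im2col +
        one GEMM so the heavy lifting stays in BLAS.
        """
        x = self.data
        n, c, h, w = x.shape
        cout = weight.data.shape[0]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        # columns in (C*9, N*H*W) orientation: each row is one (channel,
        # offset) plane, copied in long contiguous runs (cache friendly)
        cols = np.empty((c * 9, n * h * w), dtype=np.float32)
        for ci in range(c):
            for q in range(9):
                ky, kx = divmod(q, 3)
                cols[ci * 9 + q] = xp[:, ci, ky:ky + h, kx:kx + w].reshape(-1)
        wm = weight.data.reshape(cout, c * 9)
        out = wm @ cols  # (Cout, N*H*W)
        out_data = np.ascontiguousarray(
            out.reshape(cout, n, h, w).transpose(1, 0, 2, 3))
        out_data += bias.data[None, :, None, None]

        def bwd(g):
            gt = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(cout, -1)
            if weight.requires_grad:
                weight._accum((gt @ cols.T).reshape(weight.data.shape))
            if bias.requires_grad:
                bias._accum(gt.sum(axis=1))
            if self.requires_grad:
                dcols = wm.T @ gt  # (C*9, N*H*W)
                dxp = np.zeros_like(xp)
                for ci in range(c):
                    for q in range(9):
                        ky, kx = divmod(q, 3)
                        dxp[:, ci, ky:ky + h, kx:kx + w] += dcols[
                            ci * 9 + q].reshape(n, h, w)
                self._accum(dxp[:, :, 1:1 + h, 1:1 + w])

        return Tensor._make(out_data, (self, weight, bias), bwd)

    def maxpool2(self):
        """2x2 max pooling, stride 2; ties break to the first element."""
        n, c, h, w = self.data.shape
        h2, w2 = h // 2, w // 2
        r = self.data.reshape(n, c, h2, 2, w2, 2)
        out_data = r.max(axis=(3, 5))

        def bwd(g):
            # route gradient to the first-occurring maximum in each window
            rr = np.ascontiguousarray(r.transpose(0, 1, 2, 4, 3, 5)).reshape(
                n, c, h2, w2, 4)
            idx = rr.argmax(axis=-1)
            gr = np.zeros((n, c, h2, w2, 4), dtype=np.float32)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gx = gr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            self._accum(gx.reshape(n, c, h, w))

        return Tensor._make(out_data, (self,), bwd)

    def global_avg_pool(self):
        """(N, C, H, W) -> (N, C) spatial mean."""
        return self.mean(axis=(2, 3))

    def dropout(self, rate: float, rng: np.random.Generator):
        """Inverted dropout; call only in training mode."""
        if rate <= 0:
            return self
        keep = (rng.random(self.data.shape) >= rate).astype(np.float32)
        scale = 1.0 / (1.0 - rate)
        return self * Tensor(keep * scale)


class no_grad:
    """Context marker for evaluation-mode forward passes.

    The engine only records a tape for tensors with ``requires_grad=True``;
    evaluation passes wrap parameters via :func:`detach_params` instead, so
    this class exists for API clarity in user code.
    """

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False


def detach(t: Tensor) -> Tensor:
    """A grad-free view of a tensor's data."""
    return Tensor(t.data)
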