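"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operations the segmentation stack needs:
elementwise arithmetic with broadcasting, matrix multiplication, ReLU /
sigmoid, axis reductions (sum / mean / max), reshape, concatenation,
2-D convolution (strided, dilated, grouped), nearest-neighbour upsampling
and a fused softmax cross-entropy loss.  Gradients are accumulated by a
topological backward pass over the recorded graph.

All tensors wrap ``numpy.ndarray``; no dtype is forced, so float64 can be
used for finite-difference checks while models run in float32.
"""

from __future__ import annotations

import numpy as np

from . import conv as _conv

__all__ = ["Tensor", "concat", "conv2d", "upsample_nearest", "upsample_bilinear",
           "softmax_cross_entropy"]


def _as_array(x):
    if isinstance(x, np.ndarray):
        return x
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the adjoint of numpy broadcasting)."""
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
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.result_type(self.data, np.float32))
        self.grad = self.grad + g

    def backward(self, grad=None):
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    self._accumulate(np.outer(g, other.data) if self.data.ndim == 2
                                     else g * other.data)
                else:
                    self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                                  self.data.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    other._accumulate(np.outer(self.data, g) if other.data.ndim == 2
                                      else self.data * g)
                else:
                    other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                                   other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    # ------------------------------------------------------------ activations
    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor._from_op(out_data, (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            expanded = out_data if keepdims or axis is None else np.expand_dims(out_data, axis)
            mask = (self.data == expanded)
            counts = mask.sum(axis=axis, keepdims=True)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            # ties share the gradient equally, keeping the op finite-difference clean
            self._accumulate(mask * (g / counts))

        return Tensor._from_op(out_data, (self,), backward)


# ------------------------------------------------------------------ free ops
def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._from_op(out_data, tuple(tensors), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride: int = 1,
           padding: int = 0, dilation: int = 1, groups: int = 1) -> Tensor:
    """2-D convolution over NCHW input with OIHW weights (cross-correlation)."""
    x = Tensor._lift(x)
    w = Tensor._lift(w)
    out_data, cols = _conv.conv2d_forward(x.data, w.data, stride, padding, dilation, groups)
    if b is not None:
        b = Tensor._lift(b)
        out_data = out_data + b.data[None, :, None, None]
        parents = (x, w, b)
    else:
        parents = (x, w)

    def backward(g):
        dx, dw = _conv.conv2d_backward(
            g, x.data, w.data, cols, stride, padding, dilation, groups,
            need_dx=x.requires_grad, need_dw=w.requires_grad)
        if x.requires_grad:
            x._accumulate(dx)
        if w.requires_grad:
            w._accumulate(dw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._from_op(out_data, parents, backward)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour spatial upsampling by an integer factor (NCHW)."""
    x = Tensor._lift(x)
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h, w = x.data.shape
            x._accumulate(g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5)))

    return Tensor._from_op(out_data, (x,), backward)


def _interp_matrix(n_in: int, factor: int, dtype) -> np.ndarray:
    """1-D linear interpolation matrix for integer-factor upsampling.

    Uses the half-pixel-centre convention (align_corners=False), with
    edge clamping.
    """
    n_out = n_in * factor
    src = (np.arange(n_out) + 0.5) / factor - 0.5
    lo = np.floor(src).astype(int)
    w_hi = (src - lo).astype(dtype)
    lo_c = np.clip(lo, 0, n_in - 1)
    hi_c = np.clip(lo + 1, 0, n_in - 1)
    mat = np.zeros((n_out, n_in), dtype=dtype)
    np.add.at(mat, (np.arange(n_out), lo_c), 1.0 - w_hi)
    np.add.at(mat, (np.arange(n_out), hi_c), w_hi)
    return mat


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Bilinear spatial upsampling by an integer factor (NCHW)."""
    x = Tensor._lift(x)
    n, c, h, w = x.data.shape
    ah = _interp_matrix(h, factor, x.data.dtype)
    aw = _interp_matrix(w, factor, x.data.dtype)
    # (N,C,H,W) x (Hf,H) -> (N,C,W,Hf); then x (Wf,W) -> (N,C,Hf,Wf)
    out_data = np.tensordot(np.tensordot(x.data, ah, axes=([2], [1])),
                            aw, axes=([2], [1]))

    def backward(g):
        if x.requires_grad:
            # adjoint: (N,C,Hf,Wf) x (Hf,H) -> (N,C,Wf,H); then x (Wf,W) -> (N,C,H,W)
            gx = np.tensordot(np.tensordot(g, ah, axes=([2], [0])),
                              aw, axes=([2], [0]))
            x._accumulate(gx)

    return Tensor._from_op(out_data, (x,), backward)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray,
                          class_weights: np.ndarray | None = None) -> Tensor:
    """Mean softmax cross-entropy.

    ``logits``: (N, K, ...) scores with classes on axis 1;
    ``targets``: (N, ...) integer labels.  Optional per-class weights
    rescale each pixel's loss (mean is taken over the weighted sum).
    """
    logits = Tensor._lift(logits)
    z = logits.data
    targets = np.asarray(targets)
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    sez = ez.sum(axis=1, keepdims=True)
    softmax = ez / sez
    t_exp = np.expand_dims(targets, 1)
    logp_t = np.take_along_axis(z - zmax, t_exp, axis=1) - np.log(sez)
    if class_weights is None:
        denom = float(targets.size)
        loss = -logp_t.sum() / denom
        pix_w = None
    else:
        pix_w = np.asarray(class_weights, dtype=z.dtype)[targets]
        denom = float(pix_w.sum())
        loss = -(pix_w[:, None] * logp_t).sum() / denom

    def backward(g):
        if logits.requires_grad:
            grad = softmax.copy()
            np.put_along_axis(grad, t_exp,
                              np.take_along_axis(grad, t_exp, axis=1) - 1.0, axis=1)
            if pix_w is not None:
                grad *= pix_w[:, None]
            logits._accumulate(g * grad / denom)

    return Tensor._from_op(np.asarray(loss, dtype=z.dtype), (logits,), backward)
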