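"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` replays the tape in reverse topological
order and accumulates gradients.  Everything runs in float64 — the models in
this package are small enough that numerical robustness is worth more than
memory, and it lets gradient checks against central finite differences pass
at tight tolerances.

Only the operations the encoders and losses need are implemented:
broadcasting arithmetic, matmul (including batched), reductions, relu/exp/
log/sqrt, reshape/transpose/concatenate/slicing, and strided 2-D convolution
via a sliding-window view.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "concatenate", "conv2d", "norm_affine", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape recording (evaluation-mode forwards)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # Collapse leading extra axes.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: Iterable["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad and _grad_enabled
        self.grad: np.ndarray | None = None
        self._prev = tuple(_prev) if self.requires_grad else ()
        self._backward = _backward

    # -- bookkeeping ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data.item())

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        # Aliasing a child's grad array is safe: the reverse topological
        # order guarantees a child's backward has fully run before any
        # in-place accumulation on its parents happens.
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float64)
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
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
            for child in node._prev:
                stack.append((child, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- construction helpers --------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = _grad_enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req, _prev=[p for p in parents if p.requires_grad])
        if req:
            out._backward = backward(out)
        return out

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)

        def bw(out):
            def _b(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))
            return _b

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(out):
            def _b(g):
                self._accumulate(-g)
            return _b

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def bw(out):
            def _b(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            return _b

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def bw(out):
            def _b(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(
                        _unbroadcast(-g * self.data / other.data**2, other.shape)
                    )
            return _b

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def bw(out):
            def _b(g):
                self._accumulate(g * p * self.data ** (p - 1))
            return _b

        return Tensor._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = Tensor._lift(other)

        def bw(out):
            def _b(g):
                if self.requires_grad:
                    if other.data.ndim == 1:
                        ga = np.multiply.outer(g, other.data) if g.ndim else g * other.data
                    else:
                        ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accumulate(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    if self.data.ndim == 1:
                        gb = np.multiply.outer(self.data, g)
                    else:
                        gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accumulate(_unbroadcast(gb, other.shape))
            return _b

        return Tensor._make(self.data @ other.data, (self, other), bw)

    # -- elementwise ------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        # Capture the array, not the output tensor: a closure holding the
        # output would form a reference cycle (tensor -> closure -> tensor)
        # that keeps whole step graphs alive until a full gc pass.
        def bw(out):
            def _b(g):
                self._accumulate(g * out_data)
            return _b

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(out):
            def _b(g):
                self._accumulate(g / self.data)
            return _b

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(out):
            def _b(g):
                self._accumulate(g / (2.0 * out_data))
            return _b

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(out):
            def _b(g):
                self._accumulate(g * mask)
            return _b

        return Tensor._make(self.data * mask, (self,), bw)

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bw(out):
            def _b(g):
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.shape).copy())
                    return
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())
            return _b

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ----------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(out):
            def _b(g):
                self._accumulate(g.reshape(self.shape))
            return _b

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(out):
            def _b(g):
                self._accumulate(g.transpose(inv))
            return _b

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(out):
            def _b(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
            return _b

        return Tensor._make(self.data[idx], (self,), bw)


class Parameter(Tensor):
    """A trainable tensor (always requires gradients)."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(out):
        def _b(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accumulate(g[tuple(sl)])
        return _b

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._make(data, tensors, bw)


def norm_affine(
    x: Tensor,
    weight: Tensor,
    bias: Tensor,
    axes: tuple[int, ...],
    eps: float,
    running: tuple[np.ndarray, np.ndarray] | None = None,
) -> Tensor:
    """Fused normalise-and-affine: ``y = weight * (x - mean)/sqrt(var + eps)
    + bias`` with mean/var taken over ``axes`` (biased variance).

    ``weight``/``bias`` must already be shaped to broadcast against ``x``.
    With ``running=(mean, var)`` the supplied statistics are used instead of
    batch statistics and are treated as constants in the backward pass
    (evaluation-mode batch norm).  A single fused op keeps the tape short —
    the composed version dominated training time.
    """
    if running is None:
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
    else:
        mu, var = running
    sigma = np.sqrt(var + eps)
    xhat = (x.data - mu) / sigma
    out_data = weight.data * xhat + bias.data

    def bw(out):
        def _b(g):
            if weight.requires_grad:
                weight._accumulate(_unbroadcast(g * xhat, weight.shape))
            if bias.requires_grad:
                bias._accumulate(_unbroadcast(g, bias.shape))
            if x.requires_grad:
                dxhat = g * weight.data
                if running is not None:
                    x._accumulate(dxhat / sigma)
                else:
                    m1 = dxhat.mean(axis=axes, keepdims=True)
                    m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
                    x._accumulate((dxhat - m1 - xhat * m2) / sigma)
        return _b

    return Tensor._make(out_data, (x, weight, bias), bw)


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: tuple[int, int] = (1, 1),
    padding: tuple[int, int] = (0, 0),
) -> Tensor:
    """2-D cross-correlation: x (n, c_in, H, W) with w (c_out, c_in, kh, kw).

    Implemented with a sliding-window view plus einsum; the backward pass
    scatters through the same geometry with a small loop over kernel taps.
    """
    n, cin, H, W = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input has {cin}, weights expect {cin_w}")
    sh, sw = stride
    ph, pw = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Hp, Wp = xp.shape[2], xp.shape[3]
    oh = (Hp - kh) // sh + 1
    ow = (Wp - kw) // sw + 1
    if oh < 1 or ow < 1:
        raise ValueError("spatial size reduced below 1 by convolution")
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    view = view[:, :, ::sh, ::sw]  # (n, cin, oh, ow, kh, kw)
    # im2col + BLAS matmul: (n*oh*ow, cin*kh*kw) @ (cin*kh*kw, cout)
    col = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * oh * ow, cin * kh * kw
    )
    wmat = w.data.reshape(cout, cin * kh * kw)
    out_data = (col @ wmat.T).reshape(n, oh, ow, cout).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    out_data = np.ascontiguousarray(out_data)

    parents = [x, w] + ([b] if b is not None else [])

    def bw(out):
        def _b(g):
            gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(
                n * oh * ow, cout
            )
            if w.requires_grad:
                w._accumulate((gmat.T @ col).reshape(cout, cin, kh, kw))
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                if (sh, sw) == (1, 1):
                    # Transposed convolution as one matmul: correlate the
                    # padded output gradient with the flipped kernel.
                    gp = np.pad(
                        g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1))
                    )
                    gview = np.lib.stride_tricks.sliding_window_view(
                        gp, (kh, kw), axis=(2, 3)
                    )
                    gcol = np.ascontiguousarray(
                        gview.transpose(0, 2, 3, 1, 4, 5)
                    ).reshape(n * Hp * Wp, cout * kh * kw)
                    wf = w.data[:, :, ::-1, ::-1].transpose(0, 2, 3, 1).reshape(
                        cout * kh * kw, cin
                    )
                    gxp = (gcol @ wf).reshape(n, Hp, Wp, cin).transpose(0, 3, 1, 2)
                else:
                    gcol = (gmat @ wmat).reshape(n, oh, ow, cin, kh, kw)
                    gxp = np.zeros((n, cin, Hp, Wp))
                    for i in range(kh):
                        for j in range(kw):
                            gxp[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw] += (
                                gcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                            )
                x._accumulate(gxp[:, :, ph : ph + H, pw : pw + W])
        return _b

    return Tensor._make(out_data, parents, bw)
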