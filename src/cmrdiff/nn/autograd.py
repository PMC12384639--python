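"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based autograd engine: every operation returns a new
:class:`Tensor` holding the forward value and a closure that scatters the
upstream gradient into its parents. Only the operations the denoiser needs
are implemented (broadcast arithmetic, matmul, 2-D convolution via im2col,
group standardization, softmax, SiLU, reshaping, concatenation, nearest
upsampling, reductions). Gradients are validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype})"

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g):
        g = np.asarray(g, dtype=self.data.dtype)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None else g
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
                # free intermediate grads/graph references promptly
                if t is not self:
                    t._parents = ()
                    t._backward = None
                    t.grad = None

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _coerce(other, like):
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=like.data.dtype))

    def __add__(self, other):
        o = self._coerce(other, self)
        out_data = self.data + o.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g, o.data.shape))

        return Tensor._make(out_data, (self, o), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other, self))

    def __rsub__(self, other):
        return self._coerce(other, self) + (-self)

    def __mul__(self, other):
        o = self._coerce(other, self)
        out_data = self.data * o.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g * self.data, o.data.shape))

        return Tensor._make(out_data, (self, o), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("division only by constants")
        return self * (1.0 / float(other))

    def matmul(self, other: "Tensor") -> "Tensor":
        o = other
        out_data = self.data @ o.data

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(o.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if o.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                o._accumulate(_unbroadcast(gb, o.data.shape))

        return Tensor._make(out_data, (self, o), bw)

    __matmul__ = matmul

    # -- shaping --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(src))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice along one axis."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accumulate(full)

        return Tensor._make(self.data[idx], (self,), bw)

    # -- nonlinearities ---------------------------------------------------
    def silu(self):
        x = self.data
        sig = 1.0 / (1.0 + np.exp(-x))
        out_data = x * sig

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (sig * (1.0 + x * (1.0 - sig))))

        return Tensor._make(out_data, (self,), bw)

    def softmax(self, axis: int = -1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        e = np.exp(x - m)
        y = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accumulate(y * (g - dot))

        return Tensor._make(y, (self,), bw)

    # -- reductions -------------------------------------------------------
    def sum(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor._make(self.data.sum(), (self,), bw)

    def mean(self):
        n = self.data.size

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(g / n, self.data.shape))

        return Tensor._make(self.data.mean(), (self,), bw)

    # -- structured ops ---------------------------------------------------
    def group_standardize(self, groups: int, eps: float = 1e-5):
        """Per-sample, per-group standardization of an NCHW feature map.

        Returns (x - mean) / sqrt(var + eps) with statistics pooled over the
        channels of each group and all spatial positions. Affine scale/shift
        is applied by the caller (a parameter pair for plain group norm, a
        timestep-conditioned pair for adaptive group norm).
        """
        B, C, H, W = self.data.shape
        if C % groups:
            raise ValueError(f"channels {C} not divisible by groups {groups}")
        xg = self.data.reshape(B, groups, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (xg - mu) * inv
        out_data = xhat.reshape(B, C, H, W)
        n = xg.shape[2]

        def bw(g):
            if not self.requires_grad:
                return
            gg = g.reshape(B, groups, -1)
            s1 = gg.sum(axis=2, keepdims=True)
            s2 = (gg * xhat).sum(axis=2, keepdims=True)
            dx = inv / n * (n * gg - s1 - xhat * s2)
            self._accumulate(dx.reshape(B, C, H, W))

        return Tensor._make(out_data, (self,), bw)

    def conv2d(self, weight: "Tensor", bias: "Tensor" = None,
               stride: int = 1, padding: int = 0):
        """2-D convolution (cross-correlation), NCHW layout, via im2col."""
        x = self.data
        w = weight.data
        B, C, H, W = x.shape
        Cout, Cin, k, _ = w.shape
        if Cin != C:
            raise ValueError(f"input has {C} channels, weight expects {Cin}")
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
            if padding else x
        Hp, Wp = xp.shape[2], xp.shape[3]
        Ho = (Hp - k) // stride + 1
        Wo = (Wp - k) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]           # (B, C, Ho, Wo, k, k)
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * k * k)
        wmat = w.reshape(Cout, C * k * k).T
        out = col @ wmat                              # (B*Ho*Wo, Cout)
        if bias is not None:
            out = out + bias.data
        out_data = out.reshape(B, Ho, Wo, Cout).transpose(0, 3, 1, 2)
        out_data = np.ascontiguousarray(out_data)

        parents = (self, weight) + ((bias,) if bias is not None else ())

        def bw(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, Cout)
            if bias is not None and bias.requires_grad:
                bias._accumulate(gmat.sum(axis=0))
            if weight.requires_grad:
                gw = gmat.T @ col                     # (Cout, C*k*k)
                weight._accumulate(gw.reshape(Cout, C, k, k))
            if self.requires_grad:
                gcol = gmat @ wmat.T                  # (B*Ho*Wo, C*k*k)
                gcol = gcol.reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
                gxp = np.zeros((B, C, Hp, Wp), dtype=x.dtype)
                for i in range(k):
                    for j in range(k):
                        gxp[:, :, i:i + stride * Ho:stride,
                            j:j + stride * Wo:stride] += gcol[:, :, :, :, i, j]
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                self._accumulate(gxp)

        return Tensor._make(out_data, parents, bw)

    def upsample_nearest2x(self):
        x = self.data
        out_data = x.repeat(2, axis=2).repeat(2, axis=3)

        def bw(g):
            if self.requires_grad:
                B, C, H2, W2 = g.shape
                gr = g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
                self._accumulate(gr)

        return Tensor._make(out_data, (self,), bw)


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]

    def bw(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(start, start + s)
                t._accumulate(g[tuple(idx)])
            start += s

    return Tensor._make(out_data, tuple(tensors), bw)
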