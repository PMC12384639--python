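"""Neural-network building blocks on top of the numpy autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module", "Linear", "Conv2d", "GroupNorm", "AdaGroupNorm",
    "SelfAttention", "ResidualUnit", "Downsample", "Upsample", "TimeMLP",
]


class Module:
    """Parameter container with recursive traversal and state (de)serialization."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
                isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix=""):
        for n, p in self._params.items():
            yield (prefix + n, p)
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        return {n: p.data.copy() for n, p in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)[:5]}")
        for n, p in own.items():
            if p.data.shape != state[n].shape:
                raise ValueError(f"shape mismatch for {n}")
            p.data = state[n].astype(p.data.dtype).copy()


def _param(shape, rng: np.random.Generator, fan_in: int = None,
           dtype=np.float32, zero: bool = False) -> Tensor:
    if zero:
        data = np.zeros(shape, dtype=dtype)
    else:
        std = 1.0 / np.sqrt(fan_in) if fan_in else 0.02
        data = rng.normal(0.0, std, size=shape).astype(dtype)
    return Tensor(data, requires_grad=True)


class Linear(Module):
    def __init__(self, d_in, d_out, rng, dtype=np.float32, zero=False):
        super().__init__()
        self.weight = _param((d_in, d_out), rng, fan_in=d_in, dtype=dtype, zero=zero)
        self.bias = Tensor(np.zeros(d_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in, c_out, k, rng, stride=1, padding=None,
                 dtype=np.float32, zero=False):
        super().__init__()
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.weight = _param((c_out, c_in, k, k), rng, fan_in=c_in * k * k,
                             dtype=dtype, zero=zero)
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class GroupNorm(Module):
    """Group normalization with a learned per-channel affine."""

    def __init__(self, groups, channels, dtype=np.float32):
        super().__init__()
        if channels % groups:
            raise ValueError(f"{groups} groups do not divide {channels} channels")
        self.groups = groups
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=dtype),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=dtype),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.group_standardize(self.groups) * self.gamma + self.beta


class AdaGroupNorm(Module):
    """Adaptive group normalization: scale and shift come from the timestep
    embedding through a linear map, so normalization statistics stay fixed
    while the affine response tracks the noise level."""

    def __init__(self, groups, channels, temb_dim, rng, dtype=np.float32):
        super().__init__()
        if channels % groups:
            raise ValueError(f"{groups} groups do not divide {channels} channels")
        self.groups = groups
        self.channels = channels
        self.proj = Linear(temb_dim, 2 * channels, rng, dtype=dtype, zero=True)

    def __call__(self, x: Tensor, temb: Tensor) -> Tensor:
        B = x.shape[0]
        sb = self.proj(temb)                                  # (B, 2C)
        scale = sb.narrow(1, 0, self.channels).reshape(B, self.channels, 1, 1)
        shift = sb.narrow(1, self.channels, self.channels).reshape(
            B, self.channels, 1, 1)
        xhat = x.group_standardize(self.groups)
        return xhat * (scale + 1.0) + shift


class SelfAttention(Module):
    """Multi-head scaled dot-product self-attention over flattened spatial
    locations, with a final output projection. Pre-normalization and the
    residual connection are applied by the enclosing block."""

    def __init__(self, channels, heads, rng, dtype=np.float32):
        super().__init__()
        if channels % heads:
            raise ValueError(f"{heads} heads do not divide {channels} channels")
        self.heads = heads
        self.channels = channels
        self.wq = Linear(channels, channels, rng, dtype=dtype)
        self.wk = Linear(channels, channels, rng, dtype=dtype)
        self.wv = Linear(channels, channels, rng, dtype=dtype)
        self.wo = Linear(channels, channels, rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, N, C) -> (B, N, C)."""
        B, N, C = x.shape
        h, dk = self.heads, C // self.heads

        def split(t):
            return t.reshape(B, N, h, dk).transpose(0, 2, 1, 3)   # (B,h,N,dk)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
        attn = scores.softmax(axis=-1)
        out = attn @ v                                            # (B,h,N,dk)
        out = out.transpose(0, 2, 1, 3).reshape(B, N, C)
        return self.wo(out)


class AttentionBlock(Module):
    """Group-norm -> multi-head self-attention -> residual add, NCHW."""

    def __init__(self, channels, heads, groups, rng, dtype=np.float32):
        super().__init__()
        self.norm = GroupNorm(groups, channels, dtype=dtype)
        self.attn = SelfAttention(channels, heads, rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        hflat = self.norm(x).reshape(B, C, H * W).transpose(0, 2, 1)
        out = self.attn(hflat).transpose(0, 2, 1).reshape(B, C, H, W)
        return x + out


class ResidualUnit(Module):
    """Timestep-conditioned residual unit:

        h_out = h_in + W2 * SiLU(W1 * AdaGN(h_in, t))

    with W1, W2 3x3 convolutions and an identity final nonlinearity. A 1x1
    projection aligns the residual path when input and output widths differ.
    W2 is zero-initialized so every unit starts as the identity map.
    """

    def __init__(self, c_in, c_out, temb_dim, groups, rng, dtype=np.float32):
        super().__init__()
        self.adagn = AdaGroupNorm(groups, c_in, temb_dim, rng, dtype=dtype)
        self.conv1 = Conv2d(c_in, c_out, 3, rng, dtype=dtype)
        self.conv2 = Conv2d(c_out, c_out, 3, rng, dtype=dtype, zero=True)
        self.skip = None
        if c_in != c_out:
            self.skip = Conv2d(c_in, c_out, 1, rng, padding=0, dtype=dtype)

    def __call__(self, h: Tensor, temb: Tensor) -> Tensor:
        y = self.conv2(self.conv1(self.adagn(h, temb)).silu())
        base = self.skip(h) if self.skip is not None else h
        return base + y


class Downsample(Module):
    def __init__(self, channels, rng, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(channels, channels, 3, rng, stride=2, dtype=dtype)

    def __call__(self, x):
        return self.conv(x)


class Upsample(Module):
    def __init__(self, channels, rng, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(channels, channels, 3, rng, dtype=dtype)

    def __call__(self, x):
        return self.conv(x.upsample_nearest2x())


class TimeMLP(Module):
    """Two-layer SiLU MLP projecting the sinusoidal embedding to the
    conditioning vector consumed by every adaptive group norm."""

    def __init__(self, dim, rng, hidden=None, dtype=np.float32):
        super().__init__()
        hidden = hidden or dim
        self.fc1 = Linear(dim, hidden, rng, dtype=dtype)
        self.fc2 = Linear(hidden, dim, rng, dtype=dtype)

    def __call__(self, e: Tensor) -> Tensor:
        return self.fc2(self.fc1(e).silu())
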