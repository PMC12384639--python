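"""Asymmetric attention-enhanced UNet noise predictor.

The denoiser eps_theta(x_t, t) is a five-level UNet whose encoder applies
plain convolutional blocks at high resolution and attention-augmented blocks
at the two deepest levels; the decoder mirrors that placement immediately
after the bottleneck. The rationale: early blocks extract local tissue
texture cheaply, while self-attention at coarse resolutions (32x32 and
below) establishes global structural relationships between the cardiac
chambers that convolutions alone propagate too slowly.

Each block stacks two timestep-conditioned residual units; attention blocks
append a multi-head self-attention layer after every unit. Skip tensors are
recorded after the input convolution, every encoder residual unit and every
downsampling step, and are concatenated channel-wise into the decoder,
whose blocks therefore carry three residual units each.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .autograd import Tensor, concat, no_grad
from .layers import (Module, Conv2d, GroupNorm, AttentionBlock, ResidualUnit,
                     Downsample, Upsample, TimeMLP, SelfAttention)

__all__ = ["UNetSpec", "UNet", "build_unet", "sinusoidal_embedding",
           "self_attention", "residual_unit", "save_checkpoint",
           "load_checkpoint"]

_DEFAULT_CHANNELS = (64, 128, 256, 512, 1024)


@dataclass(frozen=True)
class UNetSpec:
    """Complete architectural description of the denoiser."""

    image_size: int = 128
    in_channels: int = 1
    out_channels: int = 1
    level_channels: tuple = _DEFAULT_CHANNELS
    down_kinds: tuple = ("plain", "plain", "plain", "attn", "attn")
    up_kinds: tuple = ("attn", "attn", "plain", "plain", "plain")
    heads: int = 8
    norm_groups: int = 16
    time_embed_dim: int = 256
    res_units_per_block: int = 2
    attn_max_resolution: int = 32

    def __post_init__(self):
        ch = tuple(self.level_channels)
        dk, uk = tuple(self.down_kinds), tuple(self.up_kinds)
        object.__setattr__(self, "level_channels", ch)
        object.__setattr__(self, "down_kinds", dk)
        object.__setattr__(self, "up_kinds", uk)
        L = len(ch)
        if not (len(dk) == len(uk) == L):
            raise ValueError("level_channels, down_kinds and up_kinds must "
                             "have equal length")
        if self.image_size % (1 << (L - 1)):
            raise ValueError(f"image_size {self.image_size} not divisible by "
                             f"2^{L - 1}")
        for k in dk + uk:
            if k not in ("plain", "attn"):
                raise ValueError(f"unknown block kind {k!r}")
        for lvl, c in enumerate(ch):
            if c % self.norm_groups:
                raise ValueError(f"norm_groups={self.norm_groups} does not "
                                 f"divide channel width {c} at level {lvl}")
        for lvl in range(L):
            side = self.image_size >> lvl
            if (dk[lvl] == "attn" or uk[L - 1 - lvl] == "attn"):
                if side > self.attn_max_resolution:
                    raise ValueError(
                        f"attention requested at level {lvl} "
                        f"(feature side {side} > {self.attn_max_resolution})")
                if ch[lvl] % self.heads:
                    raise ValueError(f"heads={self.heads} does not divide "
                                     f"channel width {ch[lvl]}")
        if self.time_embed_dim % 2:
            raise ValueError("time_embed_dim must be even")

    def level_side(self, level: int) -> int:
        return self.image_size >> level

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "UNetSpec":
        d = yaml.safe_load(text)
        for k in ("level_channels", "down_kinds", "up_kinds"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def sinusoidal_embedding(t, d: int) -> np.ndarray:
    """Sinusoidal positional embedding of a timestep (or batch of timesteps).

    Component i equals sin(t / 10000^(2i/d)) for even i and
    cos(t / 10000^(2i/d)) for odd i; all components lie in [-1, 1].
    """
    if d < 2 or d % 2:
        raise ValueError(f"embedding dimension must be even and >= 2, got {d}")
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("timesteps must be non-negative")
    i = np.arange(d, dtype=np.float64)
    angle = t[..., None] / np.power(10000.0, 2.0 * i / d)
    out = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return out


def self_attention(X: np.ndarray, heads: int, params: dict) -> np.ndarray:
    """Functional multi-head self-attention on a (N, C) or (B, N, C) array.

    ``params`` holds projection weights ``wq, wk, wv, wo`` of shape (C, C)
    and optional biases ``bq, bk, bv, bo``.
    """
    X = np.asarray(X)
    squeeze = X.ndim == 2
    if squeeze:
        X = X[None]
    B, N, C = X.shape
    if C % heads:
        raise ValueError(f"{heads} heads do not divide {C} channels")
    rng = np.random.default_rng(0)
    layer = SelfAttention(C, heads, rng, dtype=X.dtype)
    for nm, w in (("wq", "wq"), ("wk", "wk"), ("wv", "wv"), ("wo", "wo")):
        getattr(layer, nm).weight.data = np.asarray(params[w], dtype=X.dtype)
        bkey = "b" + w[1]
        if bkey in params:
            getattr(layer, nm).bias.data = np.asarray(params[bkey], dtype=X.dtype)
        else:
            getattr(layer, nm).bias.data = np.zeros(C, dtype=X.dtype)
    with no_grad():
        out = layer(Tensor(X)).data
    return out[0] if squeeze else out


def residual_unit(h: np.ndarray, t_emb: np.ndarray, unit: ResidualUnit) -> np.ndarray:
    """Apply a timestep-conditioned residual unit to a raw NCHW array."""
    with no_grad():
        return unit(Tensor(np.asarray(h)), Tensor(np.asarray(t_emb))).data


class UNet(Module):
    """Noise-prediction network built from a :class:`UNetSpec`."""

    def __init__(self, spec: UNetSpec, rng: np.random.Generator = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.spec = spec
        self.dtype = dtype
        ch = spec.level_channels
        L = len(ch)
        td, g, heads = spec.time_embed_dim, spec.norm_groups, spec.heads
        R = spec.res_units_per_block

        self.time_mlp = TimeMLP(td, rng, dtype=dtype)
        self.conv_in = Conv2d(spec.in_channels, ch[0], 3, rng, dtype=dtype)

        down, skip_ch = [], [ch[0]]
        c_prev = ch[0]
        for lvl in range(L):
            units, attns = [], []
            for _ in range(R):
                units.append(ResidualUnit(c_prev, ch[lvl], td, g, rng, dtype=dtype))
                attns.append(AttentionBlock(ch[lvl], heads, g, rng, dtype=dtype)
                             if spec.down_kinds[lvl] == "attn" else None)
                c_prev = ch[lvl]
                skip_ch.append(ch[lvl])
            ds = Downsample(ch[lvl], rng, dtype=dtype) if lvl < L - 1 else None
            if ds is not None:
                skip_ch.append(ch[lvl])
            down.append((units, attns, ds))
        self._register_blocks("down", down)
        self.down = down

        cmid = ch[-1]
        self.mid_res1 = ResidualUnit(cmid, cmid, td, g, rng, dtype=dtype)
        self.mid_attn = AttentionBlock(cmid, heads, g, rng, dtype=dtype)
        self.mid_res2 = ResidualUnit(cmid, cmid, td, g, rng, dtype=dtype)

        up = []
        c_prev = cmid
        rev = ch[::-1]
        for i in range(L):
            cout = rev[i]
            units, attns = [], []
            for _ in range(R + 1):
                cin = c_prev + skip_ch.pop()
                units.append(ResidualUnit(cin, cout, td, g, rng, dtype=dtype))
                attns.append(AttentionBlock(cout, heads, g, rng, dtype=dtype)
                             if spec.up_kinds[i] == "attn" else None)
                c_prev = cout
            us = Upsample(cout, rng, dtype=dtype) if i < L - 1 else None
            up.append((units, attns, us))
        assert not skip_ch
        self._register_blocks("up", up)
        self.up = up

        self.norm_out = GroupNorm(g, ch[0], dtype=dtype)
        self.conv_out = Conv2d(ch[0], spec.out_channels, 3, rng, dtype=dtype,
                               zero=True)

    def _register_blocks(self, name, blocks):
        mods = []
        for units, attns, resize in blocks:
            mods.extend(units)
            mods.extend(a for a in attns if a is not None)
            if resize is not None:
                mods.append(resize)
        setattr(self, f"_{name}_modules", mods)

    def __call__(self, x, t):
        """Predict the noise component of a batch.

        Parameters
        ----------
        x : array or Tensor, shape (B, C, H, W)
        t : int array, shape (B,) — 1-based timesteps.
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.dtype))
        t = np.atleast_1d(np.asarray(t))
        emb = sinusoidal_embedding(t, self.spec.time_embed_dim).astype(self.dtype)
        temb = self.time_mlp(Tensor(emb))

        h = self.conv_in(x)
        skips = [h]
        for units, attns, ds in self.down:
            for u, a in zip(units, attns):
                h = u(h, temb)
                if a is not None:
                    h = a(h)
                skips.append(h)
            if ds is not None:
                h = ds(h)
                skips.append(h)

        h = self.mid_res1(h, temb)
        h = self.mid_attn(h)
        h = self.mid_res2(h, temb)

        for units, attns, us in self.up:
            for u, a in zip(units, attns):
                h = u(concat([h, skips.pop()], axis=1), temb)
                if a is not None:
                    h = a(h)
            if us is not None:
                h = us(h)

        return self.conv_out(self.norm_out(h).silu())

    def predict(self, x, t) -> np.ndarray:
        """Inference-mode forward pass returning a plain array."""
        with no_grad():
            return self(x, t).data


def build_unet(spec: UNetSpec, rng: np.random.Generator = None,
               dtype=np.float32) -> UNet:
    """Instantiate the denoiser described by ``spec``."""
    return UNet(spec, rng=rng, dtype=dtype)


def save_checkpoint(path, model: UNet, extra: dict = None):
    """Write model weights plus embedded spec (and optional extra arrays)."""
    payload = {f"param::{n}": p.data for n, p in model.named_parameters()}
    payload["spec_yaml"] = np.frombuffer(
        model.spec.to_yaml().encode(), dtype=np.uint8)
    if extra:
        meta = {}
        for k, v in extra.items():
            if isinstance(v, np.ndarray):
                payload[f"extra::{k}"] = v
            else:
                meta[k] = v
        if meta:
            payload["extra_json"] = np.frombuffer(
                json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path, dtype=np.float32):
    """Rebuild a UNet from a checkpoint. Returns (model, extra_dict)."""
    with np.load(path) as z:
        spec = UNetSpec.from_yaml(bytes(z["spec_yaml"]).decode())
        model = UNet(spec, rng=np.random.default_rng(0), dtype=dtype)
        state = {k[len("param::"):]: z[k] for k in z.files
                 if k.startswith("param::")}
        model.load_state_dict(state)
        extra = {k[len("extra::"):]: z[k] for k in z.files
                 if k.startswith("extra::")}
        if "extra_json" in z.files:
            extra.update(json.loads(bytes(z["extra_json"]).decode()))
    return model, extra
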