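"""Denoiser architecture: embeddings, attention, residual units, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cmrdiff.nn import Tensor, no_grad
from cmrdiff.nn.layers import ResidualUnit, AttentionBlock
from cmrdiff.nn.unet import (UNetSpec, build_unet, sinusoidal_embedding,
                             self_attention, residual_unit, save_checkpoint,
                             load_checkpoint)


class TestSinusoidalEmbedding:
    def test_zero_timestep_parity_pattern(self):
        e = sinusoidal_embedding(0, 12)
        assert np.allclose(e[0::2], 0.0)   # sin(0)
        assert np.allclose(e[1::2], 1.0)   # cos(0)

    @settings(max_examples=50, derandomize=True)
    @given(t=st.integers(min_value=0, max_value=10_000),
           d=st.sampled_from([2, 8, 64, 256]))
    def test_components_bounded(self, t, d):
        e = sinusoidal_embedding(t, d)
        assert e.shape == (d,)
        assert np.all(np.abs(e) <= 1.0)

    def test_matches_literal_scalar_evaluation(self):
        t, d = 7, 8
        e = sinusoidal_embedding(t, d)
        for i in range(d):
            angle = t / 10000 ** (2 * i / d)
            want = np.sin(angle) if i % 2 == 0 else np.cos(angle)
            assert e[i] == pytest.approx(want, rel=1e-12)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            sinusoidal_embedding(3, 7)


def _attn_params(C, rng):
    p = {w: rng.normal(size=(C, C)) * 0.3 for w in ("wq", "wk", "wv", "wo")}
    p.update({b: rng.normal(size=C) * 0.1 for b in ("bq", "bk", "bv", "bo")})
    return p


def brute_force_attention(X, heads, p):
    """O(N^2) double loop over query/key pairs, one head at a time."""
    N, C = X.shape
    dk = C // heads
    q = X @ p["wq"] + p["bq"]
    k = X @ p["wk"] + p["bk"]
    v = X @ p["wv"] + p["bv"]
    out = np.zeros((N, C))
    for h in range(heads):
        sl = slice(h * dk, (h + 1) * dk)
        for i in range(N):
            logits = np.array([q[i, sl] @ k[j, sl] for j in range(N)]) / np.sqrt(dk)
            wts = np.exp(logits - logits.max())
            wts /= wts.sum()
            out[i, sl] = sum(wts[j] * v[j, sl] for j in range(N))
    return out @ p["wo"] + p["bo"]


class TestSelfAttention:
    def test_single_token_weight_is_one(self, rng):
        C = 8
        p = _attn_params(C, rng)
        X = rng.normal(size=(1, C))
        out = self_attention(X, 2, p)
        v = X @ p["wv"] + p["bv"]
        assert np.allclose(out, v @ p["wo"] + p["bo"], rtol=1e-6)

    def test_identical_tokens_give_uniform_attention(self, rng):
        C, N = 8, 6
        p = _attn_params(C, rng)
        X = np.tile(rng.normal(size=(1, C)), (N, 1))
        out = self_attention(X, 2, p)
        single = self_attention(X[:1], 2, p)
        # uniform weights over identical values == single-token output
        assert np.allclose(out, np.tile(single, (N, 1)), rtol=1e-6)

    def test_matches_brute_force_double_loop(self, rng):
        N, C, heads = 5, 16, 2
        p = _attn_params(C, rng)
        X = rng.normal(size=(N, C))
        assert np.allclose(self_attention(X, heads, p),
                           brute_force_attention(X, heads, p), rtol=1e-6)

    def test_spatial_permutation_equivariance(self, rng):
        N, C = 9, 8
        p = _attn_params(C, rng)
        X = rng.normal(size=(N, C))
        perm = rng.permutation(N)
        assert np.allclose(self_attention(X, 2, p)[perm],
                           self_attention(X[perm], 2, p), rtol=1e-6)

    def test_indivisible_heads_rejected(self, rng):
        p = _attn_params(9, rng)
        with pytest.raises(ValueError):
            self_attention(rng.normal(size=(4, 9)), 2, p)


class TestResidualUnit:
    def test_dead_second_conv_is_identity(self, rng):
        unit = ResidualUnit(4, 4, temb_dim=8, groups=2,
                            rng=np.random.default_rng(0), dtype=np.float64)
        # conv2 is zero-initialized by construction
        assert np.all(unit.conv2.weight.data == 0)
        h = rng.normal(size=(2, 4, 6, 6))
        temb = rng.normal(size=(2, 8))
        assert np.allclose(residual_unit(h, temb, unit), h)

    def test_standardization_invariant_to_input_rescale(self, rng):
        x = Tensor(np.abs(rng.normal(size=(2, 4, 5, 5))) + 0.5)
        a = x.group_standardize(2).data
        b = (x * 7.3).group_standardize(2).data
        assert np.allclose(a, b, atol=1e-5)

    def test_scalar_hand_composition(self):
        # 1x1 spatial input, 1 channel: the group standardization of a single
        # element is 0, so the unit reduces to arithmetic on the biases
        rng = np.random.default_rng(3)
        unit = ResidualUnit(1, 1, temb_dim=4, groups=1, rng=rng,
                            dtype=np.float64)
        # zero padding around the 1x1 input leaves only the kernel centers
        w1 = float(unit.conv1.weight.data[0, 0, 1, 1])
        unit.conv1.bias.data[:] = 0.3
        unit.conv2.weight.data[:] = 0.5
        unit.conv2.bias.data[:] = -0.1
        proj_w = unit.adagn.proj.weight.data
        proj_b = unit.adagn.proj.bias.data
        h = np.full((1, 1, 1, 1), 2.0)
        temb = np.full((1, 4), 0.25)
        sb = temb @ proj_w + proj_b
        scale, shift = sb[0, 0], sb[0, 1]
        xhat = 0.0                       # single-element standardization
        y = xhat * (1 + scale) + shift
        pre = w1 * y + 0.3
        silu = pre / (1 + np.exp(-pre))
        want = 2.0 + 0.5 * silu - 0.1
        got = residual_unit(h, temb, unit)
        assert got.squeeze() == pytest.approx(want, rel=1e-10)


class TestUNetSpec:
    def test_default_spec_attention_placement(self):
        spec = UNetSpec()
        assert spec.down_kinds.count("attn") == 2
        assert spec.up_kinds.count("attn") == 2
        for lvl, kind in enumerate(spec.down_kinds):
            if kind == "attn":
                assert spec.level_side(lvl) <= 32

    def test_attention_above_resolution_cap_rejected(self):
        with pytest.raises(ValueError):
            UNetSpec(down_kinds=("attn", "plain", "plain", "plain", "plain"),
                     up_kinds=("plain", "plain", "plain", "plain", "attn"))

    def test_group_mismatch_rejected(self):
        with pytest.raises(ValueError):
            UNetSpec(level_channels=(24, 48, 96, 192, 384), norm_groups=16)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            UNetSpec(level_channels=(64, 128), down_kinds=("plain",),
                     up_kinds=("plain",))

    def test_yaml_round_trip(self, tiny_spec):
        assert UNetSpec.from_yaml(tiny_spec.to_yaml()) == tiny_spec


def expected_tiny_param_count(spec):
    """Brute-force shape-product census of the tiny reference layout."""
    td = spec.time_embed_dim
    c0, c1 = spec.level_channels

    def conv(cin, cout, k=3):
        return cin * cout * k * k + cout

    def res(cin, cout):
        n = td * 2 * cin + 2 * cin            # AdaGN projection
        n += conv(cin, cout) + conv(cout, cout)
        if cin != cout:
            n += conv(cin, cout, k=1)
        return n

    def attn(c):
        return 2 * c + 4 * (c * c + c)        # norm affine + q,k,v,out

    n = 2 * (td * td + td)                    # time MLP
    n += conv(1, c0)                          # stem
    # encoder: level 0 plain (2 units + downsample), level 1 attn (2 units)
    n += res(c0, c0) + res(c0, c0) + conv(c0, c0)
    n += res(c0, c1) + attn(c1) + res(c1, c1) + attn(c1)
    # bottleneck
    n += res(c1, c1) + attn(c1) + res(c1, c1)
    # decoder: level 1 attn (3 units), upsample, level 0 plain (3 units)
    n += (res(c1 + c1, c1) + attn(c1) + res(c1 + c1, c1) + attn(c1)
          + res(c1 + c0, c1) + attn(c1))
    n += conv(c1, c1)
    n += res(c1 + c0, c0) + res(c0 + c0, c0) + res(c0 + c0, c0)
    # head
    n += 2 * c0 + conv(c0, 1)
    return n


class TestBuildUNet:
    def test_tiny_parameter_count_matches_shape_census(self, tiny_spec,
                                                       tiny_model):
        assert tiny_model.num_parameters() == expected_tiny_param_count(tiny_spec)

    def test_forward_shape_and_finiteness_reference_spec(self):
        model = build_unet(UNetSpec(), rng=np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(2, 1, 128, 128)) \
            .astype(np.float32)
        out = model.predict(x, np.array([1, 1000]))
        assert out.shape == (2, 1, 128, 128)
        assert np.all(np.isfinite(out))

    def test_gradient_reaches_every_parameter(self, tiny_model, rng):
        tiny_model.zero_grad()
        x = rng.normal(size=(2, 1, 16, 16)).astype(np.float32)
        out = tiny_model(x, np.array([3, 14]))
        (out * out).mean().backward()
        missing = [n for n, p in tiny_model.named_parameters()
                   if p.grad is None]
        assert missing == []

    def test_attention_blocks_only_at_deep_levels(self):
        model = build_unet(UNetSpec(image_size=64,
                                    level_channels=(8, 16, 32),
                                    down_kinds=("plain", "plain", "attn"),
                                    up_kinds=("attn", "plain", "plain"),
                                    heads=2, norm_groups=4),
                           rng=np.random.default_rng(0))
        down_attn = [any(a is not None for a in attns)
                     for _, attns, _ in model.down]
        up_attn = [any(a is not None for a in attns)
                   for _, attns, _ in model.up]
        assert down_attn == [False, False, True]
        assert up_attn == [True, False, False]

    def test_checkpoint_round_trip(self, tiny_model, tmp_path, rng):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, tiny_model, extra={"note": "hello",
                                                 "arr": np.arange(3)})
        again, extra = load_checkpoint(path)
        for (n1, p1), (n2, p2) in zip(tiny_model.named_parameters(),
                                      again.named_parameters()):
            assert n1 == n2
            assert np.array_equal(p1.data, p2.data)
        assert extra["note"] == "hello"
        assert np.array_equal(extra["arr"], np.arange(3))
        x = rng.normal(size=(1, 1, 16, 16)).astype(np.float32)
        assert np.array_equal(tiny_model.predict(x, [5]),
                              again.predict(x, [5]))
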