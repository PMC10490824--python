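"""Contracts of the network building blocks."""

import numpy as np
import pytest

from marrowdet import autograd as ag
from marrowdet.autograd import Tensor
from marrowdet.blocks import (
    CBS,
    ELAN,
    MP,
    CoTBlock,
    CoTConfig,
    CoTLAN,
    CoordAtt,
    CoordAttConfig,
    RepC,
    SPPCSP,
)
from marrowdet.nn import set_rng


@pytest.fixture(autouse=True)
def seeded_init():
    set_rng(np.random.default_rng(7))


def t(shape, rng, lo=-2.0, hi=2.0):
    return Tensor(rng.uniform(lo, hi, shape).astype(np.float32))


# ---------------------------------------------------------------------- CBS
def test_cbs_shape_contracts(rng):
    assert CBS(3, 32, 3, 1)(t((1, 3, 64, 64), rng)).shape == (1, 32, 64, 64)
    assert CBS(32, 64, 3, 2)(t((1, 32, 64, 64), rng)).shape == (1, 64, 32, 32)
    with pytest.raises(ValueError):
        CBS(3, 8, 4, 1)
    with pytest.raises(ValueError):
        CBS(3, 8, 3, 1)(t((1, 4, 8, 8), rng))


def test_cbs_inference_equals_naive_per_pixel_loop(rng):
    """Hand-set weights; compare to an explicit per-pixel convolution loop."""
    blk = CBS(2, 3, 3, 1).eval()
    w = rng.normal(0, 1, blk.conv.weight.shape).astype(np.float32)
    blk.conv.weight.data = w
    blk.bn.gamma.data = np.ones(3, np.float32)
    blk.bn.beta.data = np.zeros(3, np.float32)
    blk.bn.running_mean.data = np.zeros(3, np.float32)
    blk.bn.running_var.data = np.ones(3, np.float32) - blk.bn.eps
    x = t((1, 2, 5, 5), rng)
    out = blk(x).data
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    ref = np.zeros((1, 3, 5, 5), np.float32)
    for o in range(3):
        for y in range(5):
            for xx in range(5):
                acc = 0.0
                for c in range(2):
                    for i in range(3):
                        for j in range(3):
                            acc += w[o, c, i, j] * xp[0, c, y + i, xx + j]
                ref[0, o, y, xx] = acc / (1.0 + 1e-6) ** 0.5  # ~BN identity
    ref = ref / (1 + np.exp(-ref))  # SiLU
    assert np.allclose(out, ref, atol=1e-4)


# ----------------------------------------------------------------------- MP
def test_mp_halves_spatial_and_follows_channel_plan(rng):
    mp = MP(128, 256)
    assert mp(t((1, 128, 80, 80), rng)).shape == (1, 256, 40, 40)
    mp_same = MP(256)
    assert mp_same(t((2, 256, 16, 16), rng)).shape == (2, 256, 8, 8)
    with pytest.raises(ValueError):
        mp_same(t((1, 256, 15, 16), rng))


def test_maxpool_of_constant_is_constant():
    x = Tensor(np.full((1, 4, 8, 8), 3.25, np.float32))
    assert np.allclose(ag.maxpool2d(x, 2, 2).data, 3.25)


# ----------------------------------------------------------------- CoT block
def test_cot_block_preserves_shape(rng):
    blk = CoTBlock(CoTConfig(64))
    assert blk(t((1, 64, 20, 20), rng)).shape == (1, 64, 20, 20)


def test_cot_block_zero_weights_propagate_zero(rng):
    blk = CoTBlock(CoTConfig(16, heads=2)).eval()
    for _, p in blk.named_tensors():
        if p.requires_grad:
            p.data = np.zeros_like(p.data)
    out = blk(t((1, 16, 6, 6), rng))
    assert np.allclose(out.data, 0.0)


def test_cot_config_rejects_indivisible_heads():
    with pytest.raises(ValueError):
        CoTConfig(10, heads=3)


@pytest.mark.parametrize("shape,heads", [((1, 8, 5, 5), 2), ((2, 16, 8, 8), 4)])
def test_cot_block_matches_nested_loop_neighborhood_oracle(shape, heads, rng):
    """The dynamic branch equals an explicit nested-loop weighted sum over
    each 3x3 neighborhood of V (one weight map per head, shared across the
    head's channel group); the output is the sum of K1 and that aggregate."""
    c = shape[1]
    blk = CoTBlock(CoTConfig(c, heads=heads)).eval()
    x = t(shape, rng)
    out = blk(x).data

    k1 = ag.silu(blk.key_bn(blk.key_embed(x))).data
    v = blk.value_bn(blk.value(x)).data
    att = blk.attn2(
        ag.silu(blk.attn_bn(blk.attn1(ag.cat([Tensor(k1), x], axis=1))))
    ).data  # (N, 9*heads, H, W)
    n, _, h, w = shape
    vp = np.pad(v, ((0, 0), (0, 0), (1, 1), (1, 1)))
    k2 = np.zeros_like(v)
    group = c // heads
    for b in range(n):
        for ch in range(c):
            head = ch // group
            for y in range(h):
                for xx in range(w):
                    acc = 0.0
                    tap = 0
                    for dy in range(3):
                        for dx in range(3):
                            acc += (
                                att[b, head * 9 + tap, y, xx]
                                * vp[b, ch, y + dy, xx + dx]
                            )
                            tap += 1
                    k2[b, ch, y, xx] = acc
    assert np.allclose(out, k1 + k2, atol=1e-5)


# ------------------------------------------------------------------ CoordAtt
def test_coordatt_pooling_values():
    """Directional pools of [[1,2],[3,4]]: z^h = (1.5, 3.5), z^w = (2, 3)."""
    x = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]], np.float32))
    z_h = x.mean(axis=3, keepdims=True).data.reshape(-1)
    z_w = x.mean(axis=2, keepdims=True).data.reshape(-1)
    assert np.allclose(z_h, [1.5, 3.5])
    assert np.allclose(z_w, [2.0, 3.0])


def test_coordatt_constant_input_pools_to_constant(rng):
    x = Tensor(np.full((1, 4, 5, 7), 2.5, np.float32))
    assert np.allclose(x.mean(axis=3, keepdims=True).data, 2.5)
    assert np.allclose(x.mean(axis=2, keepdims=True).data, 2.5)


def test_coordatt_gates_bound_output(rng):
    blk = CoordAtt(CoordAttConfig(16)).eval()
    x = t((2, 16, 9, 11), rng, lo=-5, hi=5)
    out = blk(x)
    assert out.shape == x.shape
    assert (np.abs(out.data) <= np.abs(x.data) + 1e-6).all()


def test_coordatt_large_gate_logits_approach_identity(rng):
    blk = CoordAtt(CoordAttConfig(8)).eval()
    for conv in (blk.conv_h, blk.conv_w):
        conv.weight.data = np.zeros_like(conv.weight.data)
        conv.bias.data = np.full_like(conv.bias.data, 30.0)
    x = t((1, 8, 6, 6), rng)
    assert np.allclose(blk(x).data, x.data, atol=1e-5)


# -------------------------------------------------------------------- SPPCSP
def test_sppcsp_channel_reduction_and_shape(rng):
    blk = SPPCSP(128, 64)
    out = blk(t((1, 128, 10, 12), rng))
    assert out.shape == (1, 64, 10, 12)
    with pytest.raises(ValueError):
        blk(t((1, 64, 10, 10), rng))


def test_cascaded_stride1_pools_compose_windows():
    rng = np.random.default_rng(3)
    x = Tensor(rng.normal(0, 1, (1, 2, 9, 9)).astype(np.float32))
    p5 = ag.maxpool2d(x, 5, 1, 2)
    p9 = ag.maxpool2d(p5, 5, 1, 2)
    assert np.allclose(p9.data, ag.maxpool2d(x, 9, 1, 4).data)


# ---------------------------------------------------------------------- ELAN
def test_cotlan_and_elan_share_shape_contract(rng):
    x = t((1, 128, 20, 20), rng)
    assert CoTLAN(128, 64, 256)(x).shape == ELAN(128, 64, 256)(x).shape == (1, 256, 20, 20)


def test_cotlan_preserves_spatial_dims(rng):
    blk = CoTLAN(32, 16, 64)
    for h, w in ((12, 20), (8, 8)):
        assert blk(t((1, 32, h, w), rng)).shape == (1, 64, h, w)


# ---------------------------------------------------------------------- RepC
def test_repc_fused_matches_training_topology(rng):
    for c1, c2 in ((8, 8), (8, 16)):
        blk = RepC(c1, c2)
        blk(t((4, c1, 7, 7), rng))  # one training batch populates BN statistics
        blk.eval()
        x = t((2, c1, 7, 7), rng)
        ref = blk(x).data
        fused = blk.fuse()(x).data
        assert np.allclose(fused, ref, rtol=1e-5, atol=1e-5)


def test_repc_identity_branch_only_when_channels_match():
    assert RepC(8, 8).id_bn is not None
    assert RepC(8, 16).id_bn is None


def test_repc_fusion_state_errors(rng):
    blk = RepC(4, 4)
    with pytest.raises(RuntimeError):  # no batch-norm statistics yet
        blk.fuse()
    blk(t((2, 4, 5, 5), rng))
    blk.fuse()
    with pytest.raises(RuntimeError):  # already fused
        blk.fuse()


# ----------------------------------------------------------------- finiteness
@pytest.mark.parametrize(
    "factory,cin",
    [
        (lambda: CBS(8, 16, 3, 1), 8),
        (lambda: MP(8), 8),
        (lambda: CoTBlock(CoTConfig(8, heads=2)), 8),
        (lambda: CoordAtt(CoordAttConfig(8)), 8),
        (lambda: SPPCSP(16, 8), 16),
        (lambda: RepC(8, 8), 8),
    ],
)
def test_blocks_map_finite_inputs_to_finite_outputs(factory, cin, rng):
    blk = factory().eval()
    x = t((1, cin, 8, 8), rng, lo=-10, hi=10)
    assert np.isfinite(blk(x).data).all()
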