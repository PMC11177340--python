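"""Architecture contracts: attention math, residual identities, pyramid."""

import numpy as np
import pytest

from dosecast import autodiff as ad
from dosecast.model import (
    CBAM,
    ChannelAttention,
    DosePredictionNet,
    EnhancedWindowAttention,
    ModelConfig,
    SpatialAttention,
    TransformerBlock,
    shifted_window_mask,
    window_partition,
    window_reverse,
)

RNG = np.random.default_rng(3)
SMALL = ModelConfig()  # grid 64, patch 2, embed 32, heads 4, window 4


def zero_(t: ad.Tensor):
    t.data = np.zeros_like(t.data)


# -- attention -------------------------------------------------------------

def test_attention_rows_are_probability_vectors():
    attn = EnhancedWindowAttention(RNG, dim=8, heads=2, n_w=4)
    x = ad.Tensor(RNG.normal(size=(2, 3, 4, 8)).astype(np.float32))
    weights = attn.attention_weights(x)
    assert weights.min() >= 0
    np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)


def test_zero_walpha_gives_uniform_attention_mean_of_values():
    attn = EnhancedWindowAttention(RNG, dim=4, heads=2, n_w=5)
    zero_(attn.w_alpha)
    x = RNG.normal(size=(1, 2, 5, 4)).astype(np.float32)
    out = attn(ad.Tensor(x)).data
    # uniform attention: every output token equals the mean of the V rows
    for h in range(2):
        v = x @ attn.w_v.data[h]                      # (1, 2, 5, 2)
        expected = v.mean(axis=2, keepdims=True)
        np.testing.assert_allclose(out[..., 2 * h:2 * h + 2],
                                   np.broadcast_to(expected, v.shape), atol=1e-6)


def test_attention_matches_hand_worked_scalar_case():
    """N_w=2, dk=dv=1, one head: evaluate the score/softmax/value chain by hand."""
    attn = EnhancedWindowAttention(RNG, dim=1, heads=1, n_w=2)
    wq, wk, wv = 0.7, -0.3, 1.1
    walpha = np.array([[0.5, -0.2]])
    attn.w_q.data = np.array([[[wq]]], dtype=np.float32)
    attn.w_k.data = np.array([[[wk]]], dtype=np.float32)
    attn.w_v.data = np.array([[[wv]]], dtype=np.float32)
    attn.w_alpha.data = walpha[None].astype(np.float32)

    x = np.array([0.4, -1.2])
    out = attn(ad.Tensor(x.reshape(1, 1, 2, 1).astype(np.float32))).data.ravel()

    q, k, v = x * wq, x * wk, x * wv
    scores = np.tanh(q + k)[:, None] @ walpha / np.sqrt(1.0)   # (2, 2)
    e = np.exp(scores - scores.max(axis=1, keepdims=True))
    soft = e / e.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(out, soft @ v, atol=1e-6)


def test_token_mismatch_with_walpha_rejected():
    attn = EnhancedWindowAttention(RNG, dim=4, heads=1, n_w=4)
    with pytest.raises(ValueError, match="W_alpha"):
        attn(ad.Tensor(np.zeros((1, 1, 9, 4), dtype=np.float32)))


# -- window partition / shift ---------------------------------------------

def test_window_partition_reverse_roundtrip():
    x = ad.Tensor(RNG.normal(size=(2, 8, 8, 3)).astype(np.float32))
    back = window_reverse(window_partition(x, 4), 4, 8, 8)
    np.testing.assert_array_equal(back.data, x.data)


def test_cyclic_shift_is_a_bijection():
    x = np.arange(64).reshape(1, 8, 8, 1)
    rolled = ad.roll(ad.Tensor(x), (-2, -2), axis=(1, 2))
    unrolled = ad.roll(rolled, (2, 2), axis=(1, 2))
    np.testing.assert_array_equal(unrolled.data, x)
    assert sorted(rolled.data.ravel()) == sorted(x.ravel())


def test_shifted_partition_changes_attention_support_at_window_corner():
    """A token at a window corner must see different neighbors under the
    shifted partition than under the constant partition."""
    side, w, shift = 8, 4, 2
    idx = np.arange(side * side).reshape(side, side)

    def window_sets(grid):
        wins = grid.reshape(side // w, w, side // w, w).transpose(0, 2, 1, 3)
        return [set(win.ravel()) for win in wins.reshape(-1, w * w)]

    constant = window_sets(idx)
    shifted = window_sets(np.roll(idx, (-shift, -shift), axis=(0, 1)))
    corner = idx[3, 3]  # corner of the first constant window
    support_const = next(s for s in constant if corner in s)
    support_shift = next(s for s in shifted if corner in s)
    assert support_const != support_shift


def test_wrap_mask_blocks_only_cross_region_pairs():
    mask = shifted_window_mask(side=8, w=4, shift=2)
    assert mask.shape == (4, 16, 16)
    assert np.all(mask[0] == 0)                # first window is contiguous
    assert (mask == 0).sum() + (mask < -1e8).sum() == mask.size
    assert (mask < -1e8).any()                 # wrapped windows get masking


# -- residual identities ---------------------------------------------------

@pytest.mark.parametrize("shift", [0, 2], ids=["w_msa", "sw_msa"])
def test_zeroed_block_is_identity(shift):
    block = TransformerBlock(RNG, dim=8, heads=2, window=4, side=8,
                             shift=shift, mlp_ratio=2.0)
    zero_(block.attn.w_v)
    zero_(block.mlp.fc2.weight)
    zero_(block.mlp.fc2.bias)
    x = RNG.normal(size=(1, 8, 8, 8)).astype(np.float32)
    out = block(ad.Tensor(x)).data
    np.testing.assert_allclose(out, x, atol=1e-6)
    assert out.shape == x.shape


def test_block_gradient_flows_to_input():
    block = TransformerBlock(RNG, dim=8, heads=2, window=4, side=8,
                             shift=0, mlp_ratio=2.0)
    x = ad.Tensor(RNG.normal(size=(1, 8, 8, 8)).astype(np.float32), requires_grad=True)
    ad.tsum(block(x)).backward()
    assert x.grad is not None and np.isfinite(x.grad).all() and np.abs(x.grad).sum() > 0


# -- CBAM ------------------------------------------------------------------

def test_channel_attention_zero_weights_halve_input():
    mod = ChannelAttention(RNG, dim=8, reduction=4)
    zero_(mod.fc1.weight), zero_(mod.fc1.bias)
    zero_(mod.fc2.weight), zero_(mod.fc2.bias)
    x = RNG.normal(size=(2, 8, 4, 4)).astype(np.float32)
    np.testing.assert_allclose(mod(ad.Tensor(x)).data, 0.5 * x, atol=1e-6)


def test_spatial_attention_zero_weights_halve_input_and_bounded():
    mod = SpatialAttention(RNG)
    zero_(mod.conv.weight), zero_(mod.conv.bias)
    x = RNG.normal(size=(1, 3, 8, 8)).astype(np.float32)
    np.testing.assert_allclose(mod(ad.Tensor(x)).data, 0.5 * x, atol=1e-6)
    # generic weights: per-pixel gain strictly inside (0, 1)
    mod2 = SpatialAttention(RNG)
    out = mod2(ad.Tensor(np.abs(x) + 0.1)).data
    assert np.all(np.abs(out) < np.abs(np.abs(x) + 0.1))


def test_cbam_zero_weights_give_1p25_residual_and_saturate_safely():
    mod = CBAM(RNG, dim=4, reduction=2)
    for lin in (mod.channel.fc1, mod.channel.fc2):
        zero_(lin.weight), zero_(lin.bias)
    zero_(mod.spatial.conv.weight), zero_(mod.spatial.conv.bias)
    x = RNG.normal(size=(1, 4, 8, 8)).astype(np.float32)
    np.testing.assert_allclose(mod(ad.Tensor(x)).data, 1.25 * x, atol=1e-6)

    extreme = np.full((1, 4, 8, 8), 1e6, dtype=np.float32)
    assert np.isfinite(CBAM(RNG, 4, 2)(ad.Tensor(extreme)).data).all()


# -- full network ----------------------------------------------------------

@pytest.fixture(scope="module")
def net():
    return DosePredictionNet(SMALL, seed=0)


def test_forward_emits_four_doubling_resolutions(net):
    x = RNG.normal(size=(1, 33, 64, 64)).astype(np.float32)
    with ad.no_grad():
        pyramid = net.eval()(x)
    sizes = [lvl.shape[-1] for lvl in pyramid.levels]
    assert sizes == [8, 16, 32, 64]
    assert [lvl.shape[-2] for lvl in pyramid.levels] == [8, 16, 32, 64]


def test_forward_deterministic_in_eval_mode(net):
    x = RNG.normal(size=(1, 33, 64, 64)).astype(np.float32)
    net.eval()
    with ad.no_grad():
        a = net(x).full.data
        b = net(x).full.data
    np.testing.assert_array_equal(a, b)


def test_zeroed_generation_heads_zero_the_pyramid():
    model = DosePredictionNet(SMALL, seed=1).eval()
    for head in model.heads_:
        zero_(head.out.weight), zero_(head.out.bias)
    with ad.no_grad():
        pyramid = model(RNG.normal(size=(1, 33, 64, 64)).astype(np.float32))
    for lvl in pyramid.levels:
        np.testing.assert_array_equal(lvl.data, 0.0)


def test_refinement_telescopes_when_finer_heads_are_zero():
    model = DosePredictionNet(SMALL, seed=2).eval()
    for head in model.heads_[1:]:
        zero_(head.out.weight), zero_(head.out.bias)
    with ad.no_grad():
        pyramid = model(RNG.normal(size=(1, 33, 64, 64)).astype(np.float32))
        p1 = pyramid.levels[0]
        up8 = ad.upsample_bilinear_2x(ad.upsample_bilinear_2x(ad.upsample_bilinear_2x(p1)))
    np.testing.assert_allclose(pyramid.full.data, up8.data, atol=1e-6)


def test_gradient_reaches_every_parameter_group(net):
    net.train()
    net.zero_grad()
    x = ad.Tensor(RNG.normal(size=(1, 33, 64, 64)).astype(np.float32))
    pyramid = net(x)
    total = sum((ad.tsum(lvl) for lvl in pyramid.levels), ad.Tensor(np.zeros(())))
    total.backward()
    groups: dict[str, float] = {}
    for name, p in net.named_parameters():
        assert p.grad is not None, name
        group = name.split(".")[0]
        groups[group] = groups.get(group, 0.0) + float(np.abs(p.grad).sum())
    for group, total_grad in groups.items():
        assert total_grad > 0, f"no gradient reached group {group}"
    # all four refinement heads individually receive gradient
    for i, head in enumerate(net.heads_):
        assert np.abs(head.out.weight.grad).sum() > 0, f"head {i}"
    net.zero_grad()


def test_config_validation():
    with pytest.raises(ValueError, match="divisible by heads"):
        ModelConfig(embed_dim=30, heads=4)
    with pytest.raises(ValueError, match="window"):
        ModelConfig(grid_size=48, patch_size=2, window=4)  # stage-4 side 3
    with pytest.raises(ValueError, match="input channels"):
        DosePredictionNet(SMALL, seed=0)(np.zeros((1, 5, 64, 64), dtype=np.float32))


def test_parameter_count_matches_closed_form(net):
    """Closed-form parameter count derived independently from the config."""
    cfg = SMALL
    P, Ce, h, w = cfg.patch_size, cfg.embed_dim, cfg.heads, cfg.window
    N = w * w
    dims = [Ce * 2 ** i for i in range(4)]
    dc = list(cfg.decoder_channels)

    def block_params(D):
        dk = D // h
        attn = 3 * h * D * dk + h * dk * N          # W_Q, W_K, W_V, W_alpha
        lns = 2 * (2 * D)                           # two LayerNorms
        hid = int(D * cfg.mlp_ratio)
        mlp = D * hid + hid + hid * D + D
        return attn + lns + mlp

    def cbam_params(D):
        hidc = max(D // cfg.cbam_reduction, 1)
        channel = D * hidc + hidc + hidc * D + D
        spatial = 1 * 2 * 7 * 7 + 1
        return channel + spatial

    def conv_bn(cin, cout):
        return cin * cout * 9 + cout + 2 * cout

    expected = (33 * P * P) * Ce + Ce + N * Ce       # patch embed + positions
    for i, D in enumerate(dims):
        expected += cfg.stage_depths[i] * block_params(D) + cbam_params(D)
        if i < 3:
            expected += 4 * D * 2 * D + 2 * D        # patch merging
    expected += conv_bn(33, dc[3])               # full-resolution stem skip
    skips = [dims[2], dims[1], dims[0], dc[3]]
    ins = [dims[3], dc[0], dc[1], dc[2]]
    for cin, skip, cout in zip(ins, skips, dc):
        expected += conv_bn(cin + skip, cout) + conv_bn(cout, cout)
    for c in dc:
        expected += 2 * conv_bn(c, c) + (c * 1 * 9 + 1)

    actual = sum(p.size for p in net.parameters())
    assert actual == expected
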