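"""Multi-scale encoder: patchify, ViT attention contracts, FPN shape laws,
bilinear upsampling oracle, fusion identities."""

import numpy as np
import pytest

from msssl import nn
from msssl.mfee import (
    FeaturePyramid,
    MultiScaleFusion,
    ProjectionHead,
    ResNetFPN,
    ViTConfig,
    ViTEncoder,
    fuse_stacks,
    patchify,
    unpatchify,
    upsample_to_p2,
)
from msssl.nn import Tensor


def tiny_vit(input_size=64, rng=None):
    cfg = ViTConfig(input_size=input_size, patch_size=16, embed_dim=64, depth=2, num_heads=4)
    return ViTEncoder(cfg, rng or np.random.default_rng(0))


# -- patchify -----------------------------------------------------------------

def test_patchify_token_counts():
    assert patchify(np.zeros((1, 3, 1024, 1024), np.float32), 16).shape[1] == 64 * 64
    assert patchify(np.zeros((1, 3, 224, 224), np.float32), 32).shape[1] == 49


def test_patchify_roundtrip(rng):
    x = rng.standard_normal((2, 3, 32, 32)).astype(np.float32)
    tokens = patchify(x, 16)
    back = unpatchify(tokens, (2, 2), 16, channels=3)
    np.testing.assert_array_equal(back.data, x)


def test_patchify_rejects_indivisible():
    with pytest.raises(ValueError):
        patchify(np.zeros((1, 3, 30, 30), np.float32), 16)


# -- ViT ----------------------------------------------------------------------

def test_vit_variant_presets():
    s = ViTConfig.from_variant("S", 16)
    b = ViTConfig.from_variant("B", 32)
    assert (s.embed_dim, s.depth, s.num_heads) == (384, 12, 6)
    assert (b.embed_dim, b.depth, b.num_heads) == (768, 12, 12)
    with pytest.raises(ValueError):
        ViTConfig.from_variant("L", 16)
    with pytest.raises(ValueError):
        ViTConfig(input_size=224, patch_size=13)


def test_vit_token_count_and_attention_contracts(rng):
    vit = tiny_vit(64)
    x = rng.standard_normal((2, 3, 64, 64)).astype(np.float32)
    emb = vit(x, store_attention=True)
    n_patches = (64 // 16) ** 2
    assert emb.tokens.shape == (2, 1 + n_patches, 64)
    attn = emb.attention_tensor(0)
    assert attn.shape == (2, 4, 1 + n_patches, 1 + n_patches)
    np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-5)
    assert (attn >= 0).all()


def test_vit_forward_is_deterministic(rng):
    vit = tiny_vit(64)
    x = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
    a = vit(x).tokens.data
    b = vit(x).tokens.data
    assert np.array_equal(a, b)


# -- projection head ----------------------------------------------------------

def test_projection_head_shapes_and_zero_case(rng):
    head = ProjectionHead(64, rng, hidden_dim=32, out_dim=16)
    out = head(Tensor(rng.standard_normal((5, 64)).astype(np.float32)))
    assert out.shape == (5, 16)
    for p in head.parameters():
        p.data = np.zeros_like(p.data)
    out = head(Tensor(rng.standard_normal((2, 64)).astype(np.float32)))
    assert np.array_equal(out.data, np.zeros((2, 16), np.float32))


def test_linear_layer_matches_pencil_and_paper():
    lin = nn.Linear(2, 2, np.random.default_rng(0))
    lin.weight.data = np.array([[1.0, 2.0], [3.0, 4.0]], np.float32)
    lin.bias.data = np.array([0.5, -0.5], np.float32)
    out = lin(Tensor(np.array([[1.0, 1.0]], np.float32)))
    # [1,1] @ [[1,2],[3,4]] + [0.5,-0.5] = [4.5, 5.5]
    np.testing.assert_allclose(out.data, [[4.5, 5.5]])


# -- FPN ------------------------------------------------------------------------

@pytest.mark.parametrize("size", [64, 96, 160, 224])
def test_fpn_stride_law(size, rng):
    ffe = ResNetFPN("resnet18", rng, base_width=8, fpn_channels=16)
    pyr = ffe(rng.standard_normal((1, 3, size, size)).astype(np.float32))
    assert pyr.p2.shape[2:] == (size // 4, size // 4)
    assert pyr.p3.shape[2:] == (size // 8, size // 8)
    assert pyr.p5.shape[2:] == (size // 32, size // 32)
    assert pyr.p2.shape[1] == pyr.p3.shape[1] == pyr.p5.shape[1] == 16


def test_fpn_rejects_indivisible_and_unknown_backbone(rng):
    ffe = ResNetFPN("resnet18", rng, base_width=8, fpn_channels=16)
    with pytest.raises(ValueError):
        ffe(np.zeros((1, 3, 60, 60), np.float32))
    with pytest.raises(ValueError):
        ResNetFPN("resnet34", rng)


def test_fpn_zero_lateral_weights_give_zero_pyramid(rng):
    ffe = ResNetFPN("resnet18", rng, base_width=8, fpn_channels=16)
    for mod in list(ffe.laterals) + list(ffe.smooth):
        mod.weight.data = np.zeros_like(mod.weight.data)
        mod.bias.data = np.zeros_like(mod.bias.data)
    pyr = ffe(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
    for level in (pyr.p2, pyr.p3, pyr.p5):
        assert np.abs(level.data).max() == 0.0


def test_resnet50_bottleneck_shapes(rng):
    ffe = ResNetFPN("resnet50", rng, base_width=8, fpn_channels=16)
    pyr = ffe(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
    assert pyr.p2.shape == (1, 16, 16, 16)


# -- upsample_to_p2 -------------------------------------------------------------

def test_upsample_to_p2_sizes_and_constant(rng):
    pyr = FeaturePyramid(
        p2=Tensor(rng.standard_normal((1, 4, 16, 16)).astype(np.float32)),
        p3=Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32)),
        p5=Tensor(np.full((1, 4, 2, 2), 3.25, np.float32)),
    )
    p2, p3u, p5u = upsample_to_p2(pyr)
    assert p3u.shape == p5u.shape == (1, 4, 16, 16)
    np.testing.assert_allclose(p5u.data, 3.25, atol=1e-6)  # constant stays constant


def test_bilinear_upsample_matches_hand_computed_ramp():
    # 2x2 ramp -> 4x4, align_corners=False: sample centers at
    # src = (i+0.5)/2 - 0.5 = {-0.25, 0.25, 0.75, 1.25} clipped to [0,1]
    x = Tensor(np.array([[[[0.0, 1.0], [2.0, 3.0]]]], np.float32))
    out = nn.bilinear_resize(x, 4, 4).data[0, 0]
    w = np.array([0.0, 0.25, 0.75, 1.0])  # effective fractional positions
    expected = np.add.outer(2 * w, 1 * w)
    np.testing.assert_allclose(out, expected, atol=1e-6)


# -- fusion ---------------------------------------------------------------------

def test_fusion_identities_and_channel_laws(rng):
    ffe_stack = Tensor(rng.standard_normal((1, 12, 8, 8)).astype(np.float32))
    zero = Tensor(np.zeros((1, 12, 8, 8), np.float32))
    one = Tensor(np.ones((1, 12, 8, 8), np.float32))
    np.testing.assert_array_equal(fuse_stacks(ffe_stack, zero, "addition").data, ffe_stack.data)
    np.testing.assert_array_equal(fuse_stacks(ffe_stack, one, "multiplication").data,
                                  ffe_stack.data)
    assert fuse_stacks(ffe_stack, zero, "concatenation").shape[1] == 24
    with pytest.raises(ValueError):
        fuse_stacks(ffe_stack, zero, "averaging")


def test_fusion_addition_matches_loop_oracle_and_is_symmetric(rng):
    a = rng.standard_normal((1, 3, 4, 4)).astype(np.float32)
    b = rng.standard_normal((1, 3, 4, 4)).astype(np.float32)
    out = fuse_stacks(Tensor(a), Tensor(b), "addition").data
    expected = np.empty_like(a)
    for c in range(3):
        for i in range(4):
            for j in range(4):
                expected[0, c, i, j] = a[0, c, i, j] + b[0, c, i, j]
    np.testing.assert_allclose(out, expected)
    swapped = fuse_stacks(Tensor(b), Tensor(a), "addition").data
    np.testing.assert_array_equal(out, swapped)


def test_full_fusion_module_shapes(rng):
    vit = tiny_vit(64, rng)
    ffe = ResNetFPN("resnet18", rng, base_width=8, fpn_channels=16)
    fusion = MultiScaleFusion(64, 16, rng, method="addition")
    x = rng.standard_normal((2, 3, 64, 64)).astype(np.float32)
    fused = fusion(ffe(x), vit(x))
    assert fused.values.shape == (2, 48, 16, 16)  # 3*C_fpn at P2 resolution
    fused_cat = fusion(ffe(x), vit(x), method="concatenation")
    assert fused_cat.values.shape[1] == 96  # 6*C_fpn
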