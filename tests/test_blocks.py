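"""Attention mechanisms and the DSPC block: contracts, gates, parameter oracle."""

import numpy as np
import pytest

from nlinet import nn
from nlinet.blocks import (
    BlockConfig,
    CBAM3d,
    ChannelAttention3d,
    CoordinateAttention3d,
    DSPCBlock,
    SpatialAttention3d,
    StandardConvBlock,
    make_attention,
    make_block,
)
from nlinet.nn import Tensor


def _rand(shape, seed=0, scale=1.0):
    return (np.random.default_rng(seed).normal(size=shape) * scale).astype(np.float32)


@pytest.mark.parametrize("att_factory,shape", [
    (lambda rng: ChannelAttention3d(8, 4, rng=rng), (1, 8, 4, 4, 4)),
    (lambda rng: SpatialAttention3d(7, rng=rng), (1, 4, 8, 8, 8)),
    (lambda rng: CBAM3d(4, 2, 3, rng=rng), (2, 4, 6, 6, 6)),
    (lambda rng: CoordinateAttention3d(8, 4, rng=rng), (1, 8, 4, 6, 8)),
])
def test_attention_preserves_shape_and_contracts(att_factory, shape):
    """Every attention op keeps the shape and is an elementwise contraction."""
    att = att_factory(np.random.default_rng(3))
    x = _rand(shape, seed=7)
    out = att(Tensor(x)).numpy()
    assert out.shape == shape
    assert np.all(np.abs(out) <= np.abs(x) + 1e-6)
    assert np.sum(out ** 2) <= np.sum(x ** 2) + 1e-4


def test_channel_attention_symmetric_weights_give_equal_gates():
    """Identical constant channels + symmetric MLP weights -> identical gates."""
    att = ChannelAttention3d(8, 4, rng=np.random.default_rng(0))
    att.fc1.weight.data = np.full_like(att.fc1.weight.data, 0.1)
    att.fc2.weight.data = np.full_like(att.fc2.weight.data, 0.1)
    x = Tensor(np.full((1, 8, 4, 4, 4), 3.0, dtype=np.float32))
    g = att.gates(x).numpy()
    assert g.max() - g.min() < 1e-6
    assert np.all((g > 0) & (g < 1))


def test_channel_attention_rejects_nonfinite_and_reduction_clamps():
    att = ChannelAttention3d(4, reduction=100)  # clamped to C
    assert att.fc1.out_features == 1
    bad = np.full((1, 4, 2, 2, 2), np.nan, dtype=np.float32)
    with pytest.raises(ValueError, match="non-finite"):
        att(Tensor(bad))
    with pytest.raises(ValueError):
        ChannelAttention3d(0)


def test_spatial_attention_constant_input_gives_constant_gate():
    att = SpatialAttention3d(3, rng=np.random.default_rng(0))
    x = Tensor(np.full((1, 4, 6, 6, 6), 1.7, dtype=np.float32))
    g = att.gates(x).numpy()
    assert g.var() < 1e-10
    assert np.all((g > 0) & (g < 1))
    with pytest.raises(ValueError, match="odd"):
        SpatialAttention3d(4)


def test_cbam_equals_manual_composition():
    rng = np.random.default_rng(5)
    cbam = CBAM3d(4, 2, 3, rng=rng)
    x = Tensor(_rand((1, 4, 5, 5, 5), seed=9))
    manual = cbam.spatial(cbam.channel(x)).numpy()
    np.testing.assert_array_equal(cbam(x).numpy(), manual)


def test_coordinate_attention_axis_constant_input_gives_axis_constant_gates():
    att = CoordinateAttention3d(4, 2, rng=np.random.default_rng(2))
    x = Tensor(np.full((1, 4, 4, 6, 8), 0.5, dtype=np.float32))
    gh, gw, gd = att.axis_gates(x)
    for g in (gh, gw, gd):
        arr = g.numpy()
        # constant input -> gate constant along its own axis
        assert arr.std(axis=tuple(range(2, arr.ndim))).max() < 1e-6


def test_dspc_contract_shape_and_channels():
    cfg = BlockConfig(in_channels=8, out_channels=16, spatial_kernel=3)
    blk = DSPCBlock(cfg, rng=np.random.default_rng(0))
    out = blk(Tensor(_rand((1, 8, 8, 8, 8)))).numpy()
    assert out.shape == (1, 16, 8, 8, 8)
    with pytest.raises(ValueError, match="channels"):
        blk(Tensor(_rand((1, 4, 8, 8, 8))))
    with pytest.raises(ValueError, match="unknown attention"):
        BlockConfig(att1="transformer")


def test_dsc_ablation_has_no_attention_parameters():
    cfg = BlockConfig(in_channels=8, out_channels=8)
    dsc = make_block(cfg, kind="dsc")
    names = [n for n, _ in dsc.named_parameters()]
    assert not any("att" in n for n in names)
    assert isinstance(dsc.att1, nn.Identity) and isinstance(dsc.att2, nn.Identity)


def test_dspc_parameter_count_matches_layerwise_enumeration():
    """Oracle: enumerate learnable scalars one layer at a time by hand."""
    cfg = BlockConfig(in_channels=8, out_channels=16, depthwise_kernel=3,
                      att1="spatial", att2="channel", spatial_kernel=7,
                      channel_reduction=4)
    blk = DSPCBlock(cfg, rng=np.random.default_rng(0))
    expected = 0
    expected += 8 * 27                      # depthwise, no bias (pre-GroupNorm)
    expected += 2 * 8                       # GroupNorm 1 affine
    expected += 2 * 343 + 1                 # spatial attention conv (2->1, 7^3, bias)
    expected += 8 * 16                      # pointwise, no bias
    expected += 2 * 16                      # GroupNorm 2 affine
    expected += 16 * 4 + 4                  # channel attention fc1 (16 -> 4, bias)
    expected += 4 * 16 + 16                 # channel attention fc2 (4 -> 16, bias)
    expected += 8 * 16 + 16                 # residual projection 1x1x1 with bias
    assert blk.num_parameters() == expected


def test_dspc_with_saturated_gates_equals_dsc_on_same_weights():
    """Forcing both sigmoid gates to 1 reproduces the attention-free block."""
    cfg = BlockConfig(in_channels=6, out_channels=6, spatial_kernel=3,
                      att1="spatial", att2="channel")
    blk = DSPCBlock(cfg, rng=np.random.default_rng(4))
    x = Tensor(_rand((1, 6, 6, 6, 6), seed=2))
    # saturate: huge positive bias on the gate producers
    blk.att1.conv.weight.data[:] = 0.0
    blk.att1.conv.bias.data[:] = 50.0
    blk.att2.fc1.weight.data[:] = 0.0
    blk.att2.fc1.bias.data[:] = 0.0
    blk.att2.fc2.weight.data[:] = 0.0
    blk.att2.fc2.bias.data[:] = 50.0
    out = blk(x).numpy()

    dsc = DSPCBlock(BlockConfig(in_channels=6, out_channels=6, att1="none",
                                att2="none"), rng=np.random.default_rng(0))
    dsc.depthwise.weight.data = blk.depthwise.weight.data.copy()
    dsc.norm1.weight.data = blk.norm1.weight.data.copy()
    dsc.norm1.bias.data = blk.norm1.bias.data.copy()
    dsc.pointwise.weight.data = blk.pointwise.weight.data.copy()
    dsc.norm2.weight.data = blk.norm2.weight.data.copy()
    dsc.norm2.bias.data = blk.norm2.bias.data.copy()
    ref = dsc(x).numpy()
    np.testing.assert_allclose(out, ref, rtol=1e-5, atol=1e-6)


@pytest.mark.parametrize("kind", ["dspc", "dsc", "standard"])
def test_block_gradient_reaches_every_parameter(kind):
    cfg = BlockConfig(in_channels=4, out_channels=8, spatial_kernel=3,
                      channel_reduction=2)
    blk = make_block(cfg, kind=kind, rng=np.random.default_rng(1))
    out = blk(Tensor(_rand((1, 4, 6, 6, 6), seed=3)))
    out.sigmoid().sum().backward()
    for name, p in blk.named_parameters():
        assert p.grad is not None and np.any(p.grad != 0), f"dead gradient: {name}"


def test_standard_block_preserves_shape():
    blk = StandardConvBlock(BlockConfig(in_channels=4, out_channels=8),
                            rng=np.random.default_rng(0))
    assert blk(Tensor(_rand((1, 4, 5, 7, 3)))).shape == (1, 8, 5, 7, 3)


def test_groupnorm_group_fallback_divides_channels():
    for c in (1, 3, 5, 6, 7, 8, 12, 20):
        g = nn.groupnorm_groups(c, 8)
        assert c % g == 0 and g <= 8


def test_make_attention_rejects_unknown_name():
    with pytest.raises(ValueError, match="unknown attention"):
        make_attention("squeeze", 8, BlockConfig())
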