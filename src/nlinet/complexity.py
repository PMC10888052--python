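"""Analytic parameter and multiply-accumulate (MAC) accounting.

Counts are derived from the layer inventory, never from a forward pass, so the
full-resolution budget (192 x 192 x 128 input) is available in well under a
second.  Conventions:

* 1 MAC = one multiply plus one add.  Convolutions contribute
  kernel_elements x in_channels_per_group x out_channels x output_voxels;
  linear layers contribute in x out x positions.
* GroupNorm, ELU, sigmoid, bias adds, elementwise gating and trilinear
  interpolation are excluded from MACs (the dominant convention of
  FLOP-counting tools).  GroupNorm's affine scale/shift *parameters* are
  counted.
* Parameter counts are independent of input shape; MACs of the convolutional
  sub-network scale linearly with voxel count.

The lightweight comparison pits the DSPC-based network against the identical
topology with every DSPC block replaced by one dense bias-free 3x3x3
convolution (+ GroupNorm/ELU/residual), all attention removed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from . import nn
from .blocks import (
    CBAM3d,
    ChannelAttention3d,
    CoordinateAttention3d,
    DSPCBlock,
    SpatialAttention3d,
    StandardConvBlock,
)
from .network import ModelConfig, NLiNet, build_model

Entry = tuple[str, int, int]  # (layer name, params, macs)


@dataclass
class ComplexityReport:
    total_params: int
    total_macs: int
    breakdown: list[Entry]
    input_shape: tuple[int, int, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.breakdown, columns=["layer", "params", "macs"])


def count_parameters(model: nn.Module) -> int:
    """Exact count of learnable scalars in a built model."""
    return sum(p.size for p in model.parameters())


# --------------------------------------------------------------- layer entries
def _conv_entry(name: str, conv: nn.Conv3d, voxels: int) -> Entry:
    params = conv.weight.size + (0 if conv.bias is None else conv.bias.size)
    macs = ((conv.in_channels // conv.groups) * conv.out_channels
            * conv.kernel_size ** 3 * voxels)
    return (name, params, macs)


def _linear_entry(name: str, lin: nn.Linear, positions: int) -> Entry:
    params = lin.weight.size + (0 if lin.bias is None else lin.bias.size)
    return (name, params, lin.in_features * lin.out_features * positions)


def _gn_entry(name: str, gn: nn.GroupNorm) -> Entry:
    return (name, 2 * gn.num_channels, 0)


def _attention_entries(name: str, att: nn.Module,
                       spatial: tuple[int, int, int]) -> list[Entry]:
    H, W, D = spatial
    if isinstance(att, nn.Identity):
        return []
    if isinstance(att, ChannelAttention3d):
        return [_linear_entry(f"{name}.fc1", att.fc1, 1),
                _linear_entry(f"{name}.fc2", att.fc2, 1)]
    if isinstance(att, SpatialAttention3d):
        return [_conv_entry(f"{name}.conv", att.conv, H * W * D)]
    if isinstance(att, CBAM3d):
        return (_attention_entries(f"{name}.channel", att.channel, spatial)
                + _attention_entries(f"{name}.spatial", att.spatial, spatial))
    if isinstance(att, CoordinateAttention3d):
        return [_linear_entry(f"{name}.shared", att.shared, H + W + D),
                _linear_entry(f"{name}.head_h", att.head_h, H),
                _linear_entry(f"{name}.head_w", att.head_w, W),
                _linear_entry(f"{name}.head_d", att.head_d, D)]
    raise TypeError(f"no complexity rule for attention {type(att).__name__}")


def _block_entries(name: str, blk: nn.Module,
                   spatial: tuple[int, int, int]) -> list[Entry]:
    voxels = spatial[0] * spatial[1] * spatial[2]
    entries: list[Entry] = []
    if isinstance(blk, DSPCBlock):
        entries.append(_conv_entry(f"{name}.depthwise", blk.depthwise, voxels))
        entries.append(_gn_entry(f"{name}.norm1", blk.norm1))
        entries.extend(_attention_entries(f"{name}.att1", blk.att1, spatial))
        entries.append(_conv_entry(f"{name}.pointwise", blk.pointwise, voxels))
        entries.append(_gn_entry(f"{name}.norm2", blk.norm2))
        entries.extend(_attention_entries(f"{name}.att2", blk.att2, spatial))
        if isinstance(blk.project, nn.Conv3d):
            entries.append(_conv_entry(f"{name}.project", blk.project, voxels))
        return entries
    if isinstance(blk, StandardConvBlock):
        entries.append(_conv_entry(f"{name}.conv", blk.conv, voxels))
        entries.append(_gn_entry(f"{name}.norm", blk.norm))
        if isinstance(blk.project, nn.Conv3d):
            entries.append(_conv_entry(f"{name}.project", blk.project, voxels))
        return entries
    raise TypeError(f"no complexity rule for block {type(blk).__name__}")


# ---------------------------------------------------------------- model walk
def _scaled(shape: tuple[int, int, int], i: int) -> tuple[int, int, int]:
    f = 2 ** i
    return tuple(s // f for s in shape)


def model_complexity(model: NLiNet,
                     input_shape: tuple[int, int, int]) -> ComplexityReport:
    """Per-layer analytic breakdown for a built network at a stated input shape."""
    cfg = model.cfg
    f = 2 ** cfg.levels
    for name, s in zip("HWD", input_shape):
        if s % f:
            raise ValueError(f"axis {name}={s} must be divisible by 2^levels={f}")
    H, W, D = input_shape
    v0 = H * W * D
    entries: list[Entry] = []
    entries.append(_conv_entry("stem.conv", model.stem_conv, v0))
    entries.append(_gn_entry("stem.norm", model.stem_norm))
    entries.append(_conv_entry("stem.project", model.stem_proj, v0))

    if cfg.use_mfp:
        for i, path in enumerate(model.mfp.paths, start=1):
            sp = _scaled(input_shape, i)
            for j, blk in enumerate(path.blocks, start=1):
                entries.extend(_block_entries(f"mfp{i}.block{j}", blk, sp))

    for i in range(1, cfg.levels + 1):
        sp = _scaled(input_shape, i)
        if cfg.use_mfp:
            entries.extend(_attention_entries(
                f"enc{i}.skip_att", model.enc_skip_atts[i - 1], sp))
        entries.extend(_block_entries(f"enc{i}.block", model.enc_blocks[i - 1], sp))

    for i in range(1, cfg.levels + 1):
        sp = _scaled(input_shape, i - 1)  # decoder step i works at scale 1/2^(i-1)
        entries.extend(_attention_entries(
            f"dec{i}.skip_att", model.dec_skip_atts[i - 1], sp))
        entries.extend(_block_entries(f"dec{i}.block", model.dec_blocks[i - 1], sp))

    entries.append(_conv_entry("head", model.head, v0))

    return ComplexityReport(
        total_params=sum(e[1] for e in entries),
        total_macs=sum(e[2] for e in entries),
        breakdown=entries,
        input_shape=tuple(input_shape),
    )


def count_macs(model: NLiNet, input_shape: tuple[int, int, int]) -> int:
    return model_complexity(model, input_shape).total_macs


def standard_baseline(cfg: ModelConfig) -> ModelConfig:
    """The dense-convolution counterpart of a config (the 'original configuration')."""
    return replace(cfg, block_kind="standard", skip_attention="none",
                   block=replace(cfg.block, att1="none", att2="none"))


@dataclass
class ComparisonResult:
    param_ratio: float
    mac_ratio: float
    report_a: ComplexityReport
    report_b: ComplexityReport


def compare_configs(cfg_a: ModelConfig, cfg_b: ModelConfig,
                    input_shape: tuple[int, int, int]) -> ComparisonResult:
    """Build both configs and return a/b ratios of parameters and MACs."""
    rep_a = model_complexity(build_model(cfg_a), input_shape)
    rep_b = model_complexity(build_model(cfg_b), input_shape)
    return ComparisonResult(
        param_ratio=rep_a.total_params / rep_b.total_params,
        mac_ratio=rep_a.total_macs / rep_b.total_macs,
        report_a=rep_a,
        report_b=rep_b,
    )


def lightweight_comparison(cfg: ModelConfig,
                           input_shape: tuple[int, int, int] = (192, 192, 128)
                           ) -> ComparisonResult:
    """DSPC network vs its dense-convolution baseline at `input_shape`."""
    return compare_configs(cfg, standard_baseline(cfg), input_shape)
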