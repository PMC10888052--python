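"""Building blocks: 3D attention mechanisms and the DSPC convolution module.

The DSPC block is a depth-wise separable convolution with attention woven into
it, in this exact order: depthwise conv -> GroupNorm -> spatial attention ->
ELU -> pointwise conv -> GroupNorm -> ELU -> residual add -> channel attention.
Placing spatial attention right after the (spatial) depthwise stage and channel
attention after the (channel-mixing) pointwise stage is what distinguishes it
from a plain DSC block with attention appended at the end.

All attention variants end in a sigmoid gate multiplied into the feature map,
so each one is an elementwise contraction: |out| <= |in| everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .nn import Tensor

ATTENTION_KINDS = ("none", "spatial", "channel", "coordinate", "cbam")


@dataclass
class BlockConfig:
    """Configuration of one convolution block (the Att_1 / Att_2 slots included)."""

    in_channels: int = 8
    out_channels: int = 8
    depthwise_kernel: int = 3
    att1: str = "spatial"
    att2: str = "channel"
    spatial_kernel: int = 7
    groupnorm_groups: int = 8          # preferred; clamped to a divisor of C
    channel_reduction: int = 4

    def __post_init__(self):
        if self.depthwise_kernel % 2 == 0:
            raise ValueError("depthwise kernel must be odd")
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial attention kernel must be odd")
        if self.channel_reduction < 1:
            raise ValueError("channel reduction must be >= 1")
        for att in (self.att1, self.att2):
            if att not in ATTENTION_KINDS:
                raise ValueError(f"unknown attention {att!r}; choose from {ATTENTION_KINDS}")

    def with_channels(self, cin: int, cout: int) -> "BlockConfig":
        return replace(self, in_channels=cin, out_channels=cout)


def _check_finite(x: Tensor):
    if not np.all(np.isfinite(x.data)):
        raise ValueError("feature map contains non-finite values")


class ChannelAttention3d(nn.Module):
    """Squeeze-and-excitation style gate: global average pool -> MLP -> sigmoid."""

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels < 1:
            raise ValueError("channel attention needs at least one channel")
        reduction = min(reduction, channels)
        hidden = max(channels // reduction, 1)
        self.channels = channels
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def gates(self, x: Tensor) -> Tensor:
        _check_finite(x)
        pooled = x.mean(axis=(2, 3, 4))            # (B, C)
        return self.fc2(self.fc1(pooled).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        g = self.gates(x)
        return x * g.reshape(g.shape[0], g.shape[1], 1, 1, 1)


class SpatialAttention3d(nn.Module):
    """Channel-pooled (mean || max) maps -> k^3 conv -> sigmoid, one gate per voxel."""

    def __init__(self, kernel: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("spatial attention kernel must be odd")
        self.kernel = kernel
        # replicate padding: a spatially constant field gets a constant gate
        self.conv = nn.Conv3d(2, 1, kernel, bias=True, pad_mode="edge", rng=rng)

    def gates(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(nn.concatenate([avg, mx], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gates(x)


class CBAM3d(nn.Module):
    """Channel attention followed by spatial attention."""

    def __init__(self, channels: int, reduction: int = 4, kernel: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channel = ChannelAttention3d(channels, reduction, rng=rng)
        self.spatial = SpatialAttention3d(kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.spatial(self.channel(x))


class CoordinateAttention3d(nn.Module):
    """Per-axis pooled descriptors through a shared bottleneck; one sigmoid gate per axis.

    Each spatial axis keeps its own positional profile (pooled over the other
    two axes); the three gate fields multiply back into the input, so the gate
    at voxel (h, w, d) factorizes as g_H(h) * g_W(w) * g_D(d) per channel.
    """

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        reduction = min(reduction, channels)
        hidden = max(channels // reduction, 1)
        self.channels = channels
        self.shared = nn.Linear(channels, hidden, rng=rng)
        self.head_h = nn.Linear(hidden, channels, rng=rng)
        self.head_w = nn.Linear(hidden, channels, rng=rng)
        self.head_d = nn.Linear(hidden, channels, rng=rng)

    def axis_gates(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        B, C, H, W, D = x.shape
        if min(H, W, D) < 1:
            raise ValueError("degenerate spatial axis")
        ph = x.mean(axis=(3, 4)).transpose(0, 2, 1)   # (B, H, C)
        pw = x.mean(axis=(2, 4)).transpose(0, 2, 1)   # (B, W, C)
        pd = x.mean(axis=(2, 3)).transpose(0, 2, 1)   # (B, D, C)
        joint = self.shared(nn.concatenate([ph, pw, pd], axis=1)).elu()
        yh = joint[:, :H, :]
        yw = joint[:, H:H + W, :]
        yd = joint[:, H + W:, :]
        gh = self.head_h(yh).sigmoid().transpose(0, 2, 1).reshape(B, C, H, 1, 1)
        gw = self.head_w(yw).sigmoid().transpose(0, 2, 1).reshape(B, C, 1, W, 1)
        gd = self.head_d(yd).sigmoid().transpose(0, 2, 1).reshape(B, C, 1, 1, D)
        return gh, gw, gd

    def forward(self, x: Tensor) -> Tensor:
        gh, gw, gd = self.axis_gates(x)
        return x * gh * gw * gd


def make_attention(kind: str, channels: int, cfg: BlockConfig,
                   rng: np.random.Generator | None = None) -> nn.Module:
    if kind == "none":
        return nn.Identity()
    if kind == "channel":
        return ChannelAttention3d(channels, cfg.channel_reduction, rng=rng)
    if kind == "spatial":
        return SpatialAttention3d(cfg.spatial_kernel, rng=rng)
    if kind == "cbam":
        return CBAM3d(channels, cfg.channel_reduction, cfg.spatial_kernel, rng=rng)
    if kind == "coordinate":
        return CoordinateAttention3d(channels, cfg.channel_reduction, rng=rng)
    raise ValueError(f"unknown attention {kind!r}; choose from {ATTENTION_KINDS}")


class DSPCBlock(nn.Module):
    """Depth-wise separable convolution with hybrid attention (see module docstring).

    With ``att1 = att2 = "none"`` this degenerates to the plain DSC block.
    When in/out widths differ the residual identity path is a 1x1x1 projection.
    Convolutions immediately followed by GroupNorm carry no bias.
    """

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        cin, cout = cfg.in_channels, cfg.out_channels
        self.cfg = cfg
        self.depthwise = nn.Conv3d(cin, cin, cfg.depthwise_kernel, groups=cin,
                                   bias=False, rng=rng)
        self.norm1 = nn.GroupNorm(nn.groupnorm_groups(cin, cfg.groupnorm_groups), cin)
        self.att1 = make_attention(cfg.att1, cin, cfg, rng=rng)
        self.pointwise = nn.Conv3d(cin, cout, 1, bias=False, rng=rng)
        self.norm2 = nn.GroupNorm(nn.groupnorm_groups(cout, cfg.groupnorm_groups), cout)
        self.att2 = make_attention(cfg.att2, cout, cfg, rng=rng)
        self.project = (nn.Identity() if cin == cout
                        else nn.Conv3d(cin, cout, 1, bias=True, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} channels, got {x.shape[1]}")
        h = self.norm1(self.depthwise(x))
        h = self.att1(h).elu()
        h = self.norm2(self.pointwise(h))
        h = self.project(x) + h.elu()
        return self.att2(h)


class StandardConvBlock(nn.Module):
    """Dense 3x3x3 convolution block with the same residual topology, no attention.

    This is the baseline the DSPC block is weighed against when quantifying the
    lightweight claim: one full convolution replaces the depthwise+pointwise
    pair, GroupNorm/ELU/residual stay in place, both attention slots are empty.
    """

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        cin, cout = cfg.in_channels, cfg.out_channels
        self.cfg = cfg
        self.conv = nn.Conv3d(cin, cout, cfg.depthwise_kernel, bias=False, rng=rng)
        self.norm = nn.GroupNorm(nn.groupnorm_groups(cout, cfg.groupnorm_groups), cout)
        self.project = (nn.Identity() if cin == cout
                        else nn.Conv3d(cin, cout, 1, bias=True, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} channels, got {x.shape[1]}")
        h = self.norm(self.conv(x))
        return self.project(x) + h.elu()


BLOCK_KINDS = ("dspc", "dsc", "standard")


def make_block(cfg: BlockConfig, kind: str = "dspc",
               rng: np.random.Generator | None = None) -> nn.Module:
    """Build a block: 'dspc' (hybrid attention), 'dsc' (no attention), or 'standard'."""
    if kind == "dspc":
        return DSPCBlock(cfg, rng=rng)
    if kind == "dsc":
        return DSPCBlock(replace(cfg, att1="none", att2="none"), rng=rng)
    if kind == "standard":
        return StandardConvBlock(replace(cfg, att1="none", att2="none"), rng=rng)
    raise ValueError(f"unknown block kind {kind!r}; choose from {BLOCK_KINDS}")
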