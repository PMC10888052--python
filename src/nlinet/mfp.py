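"""Multiple Feature Pyramid (MFP) paths.

Path i downsamples the raw multi-sequence input by 1/2^i with trilinear
interpolation and then applies i chained DSPC blocks, producing the feature
map that is fused into encoder level i.  Paths are independent of one another
and all read the raw input, so each level of the encoder receives a freshly
extracted view of the original volume at its own scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .blocks import BlockConfig, make_block
from .nn import Tensor


@dataclass
class MfpConfig:
    num_paths: int = 5
    input_channels: int = 4
    per_path_out_channels: tuple[int, ...] = (32, 64, 128, 256, 320)
    block: BlockConfig = field(default_factory=BlockConfig)

    def __post_init__(self):
        if self.num_paths < 1:
            raise ValueError("num_paths must be >= 1")
        if len(self.per_path_out_channels) != self.num_paths:
            raise ValueError("per_path_out_channels must have num_paths entries")


def path_channel_ramp(cin: int, cout: int, n_blocks: int) -> list[int]:
    """Geometric channel widths from cin to cout over n_blocks blocks (endpoints exact)."""
    widths = [cin]
    for j in range(1, n_blocks):
        widths.append(max(1, round(cin * (cout / cin) ** (j / n_blocks))))
    widths.append(cout)
    return widths


def _check_divisible(shape: tuple[int, int, int], i: int):
    f = 2 ** i
    for name, s in zip("HWD", shape):
        if s % f:
            raise ValueError(
                f"spatial axis {name}={s} not divisible by 2^{i}={f} for MFP path {i}")


class MfpPath(nn.Module):
    """The i-th pyramid path: trilinear 1/2^i downsample, then i blocks."""

    def __init__(self, i: int, cfg: MfpConfig, block_kind: str = "dspc",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if not 1 <= i <= cfg.num_paths:
            raise ValueError(f"path index {i} outside 1..{cfg.num_paths}")
        self.index = i
        self.cfg = cfg
        widths = path_channel_ramp(cfg.input_channels,
                                   cfg.per_path_out_channels[i - 1], i)
        self.blocks = nn.ModuleList([
            make_block(cfg.block.with_channels(widths[j], widths[j + 1]),
                       kind=block_kind, rng=rng)
            for j in range(i)
        ])

    def forward(self, x: Tensor) -> Tensor:
        _check_divisible(x.shape[2:], self.index)
        f = 2 ** self.index
        target = tuple(s // f for s in x.shape[2:])
        h = nn.interpolate_trilinear(x, target)
        for blk in self.blocks:
            h = blk(h)
        return h


class Mfp(nn.Module):
    """All pyramid paths; returns feature maps in encoder-level order."""

    def __init__(self, cfg: MfpConfig, block_kind: str = "dspc",
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        self.paths = nn.ModuleList([
            MfpPath(i, cfg, block_kind=block_kind, rng=rng)
            for i in range(1, cfg.num_paths + 1)
        ])

    def forward(self, x: Tensor) -> list[Tensor]:
        return [path(x) for path in self.paths]
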