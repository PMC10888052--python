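"""The N-shaped segmentation network.

Three vertical strands give the model its N shape: the pyramid paths on the
left (each one reading the raw input), the encoder in the middle, and the
decoder on the right.  Encoder level i fuses its downsampled stream with the
matching pyramid feature; decoder level i fuses its upsampled stream with the
matching encoder (or stem) feature.  Both fusions pass the lateral feature
through channel attention before concatenation (the HCA skip).  The head is a
1x1x1 convolution with three independent sigmoids, one per nested sub-region
(ET, TC, WT); thresholding at 0.5 (ties -> 1) produces binary masks.

All resolution changes are trilinear with half-pixel-center convention, so the
output always has the input's spatial resolution.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .blocks import ATTENTION_KINDS, BLOCK_KINDS, BlockConfig, make_attention, make_block
from .mfp import Mfp, MfpConfig
from .nn import Tensor

REGION_CHANNELS = ("ET", "TC", "WT")


@dataclass
class ModelConfig:
    """Complete architectural description; every ablation row is a config edit."""

    levels: int = 5
    stem_channels: int = 32
    encoder_channels: tuple[int, ...] = (64, 128, 256, 320, 384)
    decoder_channels: tuple[int, ...] | None = None
    input_channels: int = 4
    output_channels: int = 3
    skip_attention: str = "channel"
    block: BlockConfig = field(default_factory=BlockConfig)
    block_kind: str = "dspc"
    use_mfp: bool = True
    seed: int = 0

    def __post_init__(self):
        self.encoder_channels = tuple(self.encoder_channels)
        if len(self.encoder_channels) != self.levels:
            raise ValueError(
                f"encoder_channels needs {self.levels} entries, got "
                f"{len(self.encoder_channels)}")
        if self.decoder_channels is None:
            # mirror: decoder level i returns to the width entering encoder level i
            self.decoder_channels = (self.stem_channels,) + self.encoder_channels[:-1]
        self.decoder_channels = tuple(self.decoder_channels)
        if len(self.decoder_channels) != self.levels:
            raise ValueError(
                f"decoder_channels needs {self.levels} entries, got "
                f"{len(self.decoder_channels)}")
        if self.skip_attention not in ATTENTION_KINDS:
            raise ValueError(f"unknown skip attention {self.skip_attention!r}")
        if self.block_kind not in BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.block_kind!r}")
        if self.output_channels != len(REGION_CHANNELS):
            raise ValueError("output_channels must equal the number of sub-regions (3)")

    # width of the encoder-side stream entering level i (1-based)
    def stream_width(self, i: int) -> int:
        return self.stem_channels if i == 1 else self.encoder_channels[i - 2]

    def mfp_config(self) -> MfpConfig:
        widths = tuple(self.stream_width(i) for i in range(1, self.levels + 1))
        return MfpConfig(num_paths=self.levels, input_channels=self.input_channels,
                         per_path_out_channels=widths, block=self.block)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if isinstance(d.get("block"), dict):
            d["block"] = BlockConfig(**d["block"])
        for key in ("encoder_channels", "decoder_channels"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def tiny_config(**overrides) -> ModelConfig:
    """Desk-scale plan used throughout the tests (3 levels, widths 8/16/32)."""
    base = dict(levels=3, stem_channels=8, encoder_channels=(8, 16, 32),
                block=BlockConfig(channel_reduction=4, spatial_kernel=3))
    base.update(overrides)
    return ModelConfig(**base)


def reference_config(**overrides) -> ModelConfig:
    """The full-scale plan (5 levels, stem 32, widths up to 384, reduction 16)."""
    base = dict(block=BlockConfig(channel_reduction=16))
    base.update(overrides)
    return ModelConfig(**base)


@dataclass
class Prediction:
    probabilities: np.ndarray  # (B, 3, H, W, D) in [0, 1]
    masks: np.ndarray          # same shape, {0, 1}
    threshold: float


class NLiNet(nn.Module):
    """See module docstring; built from a ModelConfig by build_model()."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        L = cfg.levels
        cin, stem = cfg.input_channels, cfg.stem_channels
        blk = cfg.block

        # stem: conv -> GroupNorm, residual-added to the projected input, then ELU
        self.stem_conv = nn.Conv3d(cin, stem, 3, bias=False, rng=rng)
        self.stem_norm = nn.GroupNorm(nn.groupnorm_groups(stem, blk.groupnorm_groups), stem)
        self.stem_proj = nn.Conv3d(cin, stem, 1, bias=True, rng=rng)

        if cfg.use_mfp:
            self.mfp = Mfp(cfg.mfp_config(), block_kind=cfg.block_kind, rng=rng)
            self.enc_skip_atts = nn.ModuleList([
                make_attention(cfg.skip_attention, cfg.stream_width(i), blk, rng=rng)
                for i in range(1, L + 1)])

        self.enc_blocks = nn.ModuleList()
        for i in range(1, L + 1):
            width = cfg.stream_width(i)
            in_ch = width * 2 if cfg.use_mfp else width
            self.enc_blocks.append(make_block(
                blk.with_channels(in_ch, cfg.encoder_channels[i - 1]),
                kind=cfg.block_kind, rng=rng))

        self.dec_skip_atts = nn.ModuleList([
            make_attention(cfg.skip_attention, cfg.stream_width(i), blk, rng=rng)
            for i in range(1, L + 1)])
        self.dec_blocks = nn.ModuleList()
        for i in range(1, L + 1):  # index i-1 holds decoder step i
            up_ch = (cfg.encoder_channels[-1] if i == L else cfg.decoder_channels[i])
            in_ch = up_ch + cfg.stream_width(i)
            self.dec_blocks.append(make_block(
                blk.with_channels(in_ch, cfg.decoder_channels[i - 1]),
                kind=cfg.block_kind, rng=rng))

        self.head = nn.Conv3d(cfg.decoder_channels[0], cfg.output_channels, 1,
                              bias=True, rng=rng)

    # ------------------------------------------------------------------ forward
    def _validate_input(self, x: Tensor):
        if x.ndim != 5:
            raise ValueError(f"expected (B, C, H, W, D) input, got shape {x.shape}")
        if x.shape[1] != self.cfg.input_channels:
            raise ValueError(f"expected {self.cfg.input_channels} input channels, "
                             f"got {x.shape[1]}")
        f = 2 ** self.cfg.levels
        for name, s in zip("HWD", x.shape[2:]):
            if s % f:
                raise ValueError(f"axis {name}={s} must be divisible by 2^levels={f}")

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        self._validate_input(x)
        L = self.cfg.levels

        f0 = (self.stem_proj(x) + self.stem_norm(self.stem_conv(x))).elu()

        mfp_feats = self.mfp(x) if self.cfg.use_mfp else None

        encs: list[Tensor] = []
        prev = f0
        for i in range(1, L + 1):
            down = nn.interpolate_trilinear(prev, tuple(s // 2 for s in prev.shape[2:]))
            if self.cfg.use_mfp:
                lateral = self.enc_skip_atts[i - 1](mfp_feats[i - 1])
                h = nn.concatenate([down, lateral], axis=1)
            else:
                h = down
            prev = self.enc_blocks[i - 1](h)
            encs.append(prev)

        cur = None
        for i in range(L, 0, -1):
            src = encs[L - 1] if i == L else cur
            skip_feat = f0 if i == 1 else encs[i - 2]
            up = nn.interpolate_trilinear(src, skip_feat.shape[2:])
            lateral = self.dec_skip_atts[i - 1](skip_feat)
            cur = self.dec_blocks[i - 1](nn.concatenate([up, lateral], axis=1))

        return self.head(cur).sigmoid()


def build_model(cfg: ModelConfig) -> NLiNet:
    return NLiNet(cfg)


def enforce_nesting(masks: np.ndarray) -> np.ndarray:
    """Post-process independent (ET, TC, WT) masks into nested ones."""
    out = masks.astype(bool).copy()
    out[:, 1] &= out[:, 2]                 # TC inside WT
    out[:, 0] &= out[:, 1]                 # ET inside TC (hence WT)
    return out.astype(masks.dtype)


def predict(model: NLiNet, volume, threshold: float = 0.5,
            nested: bool = False) -> Prediction:
    """Forward pass plus thresholding; ties (p == threshold) map to foreground."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    with nn.no_grad():
        probs = model(volume).numpy()
    masks = (probs >= threshold).astype(np.uint8)
    if nested:
        masks = enforce_nesting(masks)
    return Prediction(probabilities=probs, masks=masks, threshold=threshold)


# ------------------------------------------------------------------ checkpoints
def save_checkpoint(model: NLiNet, path: str) -> None:
    state = model.state_dict()
    cfg_json = json.dumps(model.cfg.to_dict())
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str) -> NLiNet:
    with np.load(path) as data:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(data["__config__"].tobytes()).decode()))
        state = {k: data[k] for k in data.files if k != "__config__"}
    model = build_model(cfg)
    model.load_state_dict(state)
    return model
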