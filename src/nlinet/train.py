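"""Training and evaluation loops tying the library together.

Defaults follow the training protocol of the method: AdamW with learning rate
1e-4 and weight decay 1e-5, batch size 1, 200 epochs, combo (Dice + weighted
cross-entropy) loss.  The best-validation-Dice checkpoint is retained.  Every
source of randomness (initialization, augmentation, shuffling) derives from
one seed, so two runs with the same seed produce identical losses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .data_io import Case, SplitManifest, augment, center_crop, load_case_dir, zscore_normalize
from .losses import LOSSES, subregion_masks
from .metrics import MetricsReport, evaluate_case, reports_to_table
from .network import ModelConfig, NLiNet, build_model, load_checkpoint, predict, save_checkpoint
from .nn import Tensor


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 1
    epochs: int = 200
    loss: str = "dice_wce"
    seed: int = 0
    crop_shape: tuple[int, int, int] = (192, 192, 128)
    rotate_deg: float = 15.0
    noise_sigma: float = 0.1
    checkpoint_path: str = "checkpoint.npz"
    log_path: str | None = None
    device: str = "cpu"

    def __post_init__(self):
        if self.lr <= 0 or self.weight_decay < 0:
            raise ValueError("lr must be > 0 and weight_decay >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}; choose from {sorted(LOSSES)}")


@dataclass
class TrainResult:
    checkpoint_path: str
    history: list[dict]          # per-epoch {"epoch", "train_loss", "val_dice"}
    best_val_dice: float
    best_epoch: int


def _load_split_cases(data_dir: str | Path, ids: list[str]) -> list[Case]:
    missing = [cid for cid in ids if not (Path(data_dir) / cid).is_dir()]
    if missing:
        raise FileNotFoundError(f"cases missing from {data_dir}: {missing}")
    return [zscore_normalize(load_case_dir(Path(data_dir) / cid)) for cid in ids]


def _val_dice(model: NLiNet, cases: list[Case], crop: tuple[int, int, int]) -> float:
    scores = []
    for case in cases:
        cc = center_crop(case, crop)
        pred = predict(model, cc.sequences)
        report = evaluate_case(pred.masks[0], subregion_masks(cc.labels).masks[0],
                               cc.spacing)
        scores.append(report.mean_dice)
    return float(np.mean(scores))


def train(model_cfg: ModelConfig, train_cfg: TrainConfig, manifest: SplitManifest,
          data_dir: str | Path, log=print) -> TrainResult:
    """Train on the manifest's train split, select on validation mean Dice."""
    if not manifest.train or not manifest.val:
        raise ValueError("manifest must provide nonempty train and val splits")
    loss_fn = LOSSES[train_cfg.loss]
    rng = np.random.default_rng(train_cfg.seed)

    train_cases = _load_split_cases(data_dir, manifest.train)
    val_cases = _load_split_cases(data_dir, manifest.val)

    model = build_model(model_cfg)
    opt = nn.AdamW(model.parameters(), lr=train_cfg.lr,
                   weight_decay=train_cfg.weight_decay)

    history: list[dict] = []
    best_val, best_epoch, best_state = -np.inf, -1, None
    log_lines = []
    for epoch in range(1, train_cfg.epochs + 1):
        order = rng.permutation(len(train_cases))
        losses = []
        for idx in order:
            case = augment(train_cases[idx], int(rng.integers(2 ** 31)),
                           target_shape=train_cfg.crop_shape,
                           rotate_deg=train_cfg.rotate_deg,
                           noise_sigma=train_cfg.noise_sigma)
            x = Tensor(case.sequences)
            y = subregion_masks(case.labels)
            probs = model(x)
            lv = loss_fn(probs, y)
            if not np.isfinite(lv.total):
                raise RuntimeError(
                    f"non-finite loss {lv.total} at epoch {epoch}, case "
                    f"{case.case_id}; aborting")
            opt.zero_grad()
            lv.tensor.backward()
            opt.step()
            losses.append(lv.total)
        train_loss = float(np.mean(losses))
        val_dice = _val_dice(model, val_cases, train_cfg.crop_shape)
        record = {"epoch": epoch, "train_loss": train_loss, "val_dice": val_dice}
        history.append(record)
        log_lines.append(json.dumps(record))
        log(f"epoch {epoch:3d}  train_loss {train_loss:.4f}  val_dice {val_dice:.4f}")
        if val_dice > best_val:
            best_val, best_epoch = val_dice, epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    save_checkpoint(model, train_cfg.checkpoint_path)
    if train_cfg.log_path:
        Path(train_cfg.log_path).write_text("\n".join(log_lines) + "\n")
    return TrainResult(checkpoint_path=train_cfg.checkpoint_path, history=history,
                       best_val_dice=best_val, best_epoch=best_epoch)


def evaluate_split(checkpoint: str | Path, manifest: SplitManifest,
                   data_dir: str | Path, out_csv: str | Path | None = None,
                   crop_shape: tuple[int, int, int] | None = None,
                   split: str = "test"):
    """Per-case and mean (ET, TC, WT) metrics on a manifest split, as a table."""
    model = load_checkpoint(str(checkpoint))
    ids = getattr(manifest, split)
    cases = _load_split_cases(data_dir, ids)
    reports: list[MetricsReport] = []
    for case in cases:
        cc = center_crop(case, crop_shape) if crop_shape else case
        pred = predict(model, cc.sequences)
        reports.append(evaluate_case(pred.masks[0],
                                     subregion_masks(cc.labels).masks[0], cc.spacing))
    table = reports_to_table(ids, reports)
    if out_csv:
        table.to_csv(out_csv, float_format="%.2f")
    return table


def fuse_label_map(masks: np.ndarray) -> np.ndarray:
    """Collapse nested (ET, TC, WT) masks into one BraTS-style label map.

    ED voxels get 2, NCR 1, ET 4 (the on-disk enhancing-tumor code).
    """
    et, tc, wt = (masks[0].astype(bool), masks[1].astype(bool), masks[2].astype(bool))
    out = np.zeros(et.shape, dtype=np.int16)
    out[wt & ~tc] = 2
    out[tc & ~et] = 1
    out[et] = 4
    return out
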