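"""Case ingestion, preprocessing, augmentation, and dataset splitting.

A *case* is one co-registered, skull-stripped multi-sequence acquisition (by
default T1, T1ce, T2, FLAIR) plus an integer label volume.  On disk each case
is one directory holding ``<case>_<seq>.nii.gz`` files and ``<case>_seg.nii.gz``
(the common BraTS layout); label code 4 (enhancing tumor) is remapped to the
internal code 3 at load time so labels are the contiguous set {0, 1, 2, 3}.

Preprocessing is per-volume z-scoring over nonzero (brain) voxels; background
stays at 0.  Training augmentation is, in order: random axis flips, a small
random in-plane rotation, pad-then-random-crop to the target shape, and
additive Gaussian noise on the images only.  Validation/test volumes are only
center-cropped/padded.  Splits are a seeded shuffle into 7:1:2 with
floor/floor/remainder rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

SEQUENCE_NAMES = ("t1", "t1ce", "t2", "flair")
BRATS_ET_CODE = 4
_INTERNAL_LABELS = frozenset((0, 1, 2, 3))


@dataclass
class Case:
    case_id: str
    sequences: np.ndarray              # (1, S, H, W, D) float32
    labels: np.ndarray                 # (1, H, W, D) int16
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.sequences.ndim != 5 or self.sequences.shape[0] != 1:
            raise ValueError(f"sequences must be (1, S, H, W, D), got "
                             f"{self.sequences.shape}")
        if self.labels.shape != (1,) + self.sequences.shape[2:]:
            raise ValueError(f"labels shape {self.labels.shape} inconsistent with "
                             f"sequences {self.sequences.shape}")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.sequences.shape[2:]


@dataclass
class SplitManifest:
    train: list[str]
    val: list[str]
    test: list[str]
    seed: int
    ratios: tuple[int, int, int] = (7, 1, 2)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"train": self.train, "val": self.val, "test": self.test,
             "seed": self.seed, "ratios": list(self.ratios)}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitManifest":
        d = json.loads(Path(path).read_text())
        return cls(train=d["train"], val=d["val"], test=d["test"],
                   seed=d["seed"], ratios=tuple(d["ratios"]))


# ----------------------------------------------------------------- NIfTI I/O
def _read_canonical(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.as_closest_canonical(nib.load(str(path)))
    return np.asarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])


def load_case(sequence_paths: list[str | Path], label_path: str | Path,
              case_id: str | None = None) -> Case:
    """Load one case; validates shape/spacing agreement and label codes."""
    volumes, spacings = [], []
    for p in sequence_paths:
        data, spacing = _read_canonical(p)
        volumes.append(data.astype(np.float32))
        spacings.append(spacing)
    labels, label_spacing = _read_canonical(label_path)
    shapes = {v.shape for v in volumes} | {labels.shape}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent volume shapes across files: {sorted(shapes)}")
    all_spacing = set(spacings) | {label_spacing}
    if len({tuple(np.round(s, 5)) for s in all_spacing}) != 1:
        raise ValueError(f"inconsistent voxel spacing across files: {all_spacing}")
    labels = np.asarray(labels)
    if not np.allclose(labels, np.round(labels)):
        raise ValueError("label volume contains non-integer values")
    labels = labels.astype(np.int16)
    labels[labels == BRATS_ET_CODE] = 3
    unknown = sorted(set(np.unique(labels).tolist()) - _INTERNAL_LABELS)
    if unknown:
        raise ValueError(f"unknown label codes {unknown}")
    cid = case_id or Path(label_path).name.split("_seg")[0]
    return Case(
        case_id=cid,
        sequences=np.stack(volumes)[None],
        labels=labels[None],
        spacing=spacings[0],
        provenance={"label": str(label_path),
                    **{f"seq{i}": str(p) for i, p in enumerate(sequence_paths)}},
    )


def load_case_dir(case_dir: str | Path,
                  sequence_names: tuple[str, ...] = SEQUENCE_NAMES) -> Case:
    case_dir = Path(case_dir)
    cid = case_dir.name
    seq_paths = [case_dir / f"{cid}_{s}.nii.gz" for s in sequence_names]
    return load_case(seq_paths, case_dir / f"{cid}_seg.nii.gz", case_id=cid)


def save_case(case: Case, out_dir: str | Path,
              sequence_names: tuple[str, ...] = SEQUENCE_NAMES) -> Path:
    """Write a case in the on-disk layout; returns the case directory."""
    case_dir = Path(out_dir) / case.case_id
    case_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(case.spacing) + [1.0])
    for i, name in enumerate(sequence_names[:case.sequences.shape[1]]):
        nib.save(nib.Nifti1Image(case.sequences[0, i].astype(np.float32), affine),
                 str(case_dir / f"{case.case_id}_{name}.nii.gz"))
    nib.save(nib.Nifti1Image(case.labels[0].astype(np.int16), affine),
             str(case_dir / f"{case.case_id}_seg.nii.gz"))
    return case_dir


def save_mask(mask: np.ndarray, spacing, path: str | Path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask).astype(np.uint8), affine), str(path))


# ------------------------------------------------------------- preprocessing
def zscore_normalize(case: Case) -> Case:
    """Per-sequence standardization over nonzero voxels; background stays 0."""
    seqs = case.sequences.copy()
    for s in range(seqs.shape[1]):
        vol = seqs[0, s]
        fg = vol != 0
        if not fg.any():
            raise ValueError(f"sequence {s} of case {case.case_id} is all background")
        mu, sd = float(vol[fg].mean()), float(vol[fg].std())
        if sd < 1e-8:
            raise ValueError(f"sequence {s} of case {case.case_id} has constant "
                             "foreground (zero variance)")
        vol[fg] = (vol[fg] - mu) / sd
    return Case(case_id=case.case_id, sequences=seqs, labels=case.labels.copy(),
                spacing=case.spacing, provenance=dict(case.provenance))


def _crop_or_pad(vol: np.ndarray, target: tuple[int, int, int],
                 offsets: tuple[int, int, int] | None) -> np.ndarray:
    """Pad symmetrically to at least `target`, then crop at `offsets` (center if None)."""
    pads = []
    for s, t in zip(vol.shape[-3:], target):
        extra = max(t - s, 0)
        pads.append((extra // 2, extra - extra // 2))
    pad_spec = [(0, 0)] * (vol.ndim - 3) + pads
    vol = np.pad(vol, pad_spec)
    slices = [slice(None)] * (vol.ndim - 3)
    for ax, t in enumerate(target):
        s = vol.shape[vol.ndim - 3 + ax]
        off = (s - t) // 2 if offsets is None else offsets[ax]
        slices.append(slice(off, off + t))
    return vol[tuple(slices)]


def center_crop(case: Case, target: tuple[int, int, int]) -> Case:
    """Deterministic crop/pad used at validation and test time (no augmentation)."""
    return Case(case_id=case.case_id,
                sequences=_crop_or_pad(case.sequences, target, None),
                labels=_crop_or_pad(case.labels, target, None),
                spacing=case.spacing, provenance=dict(case.provenance))


def augment(case: Case, rng_seed: int,
            target_shape: tuple[int, int, int] = (192, 192, 128),
            rotate_deg: float = 15.0, noise_sigma: float = 0.1) -> Case:
    """Seeded training augmentation (see module docstring for the pipeline order)."""
    rng = np.random.default_rng(rng_seed)
    seqs = case.sequences.copy()
    labels = case.labels.copy()

    for ax in range(3):  # flips, p = 0.5 per axis
        if rng.random() < 0.5:
            seqs = np.flip(seqs, axis=2 + ax)
            labels = np.flip(labels, axis=1 + ax)

    angle = float(rng.uniform(-rotate_deg, rotate_deg))
    if abs(angle) > 1e-6:
        # in-plane (H, W) rotation; trilinear for images, nearest for labels
        seqs = ndimage.rotate(seqs, angle, axes=(2, 3), reshape=False, order=1,
                              mode="constant", cval=0.0)
        labels = ndimage.rotate(labels, angle, axes=(1, 2), reshape=False, order=0,
                                mode="constant", cval=0)

    padded_shape = [max(s, t) for s, t in zip(seqs.shape[2:], target_shape)]
    offsets = tuple(int(rng.integers(0, ps - t + 1))
                    for ps, t in zip(padded_shape, target_shape))
    seqs = _crop_or_pad(seqs, target_shape, offsets)
    labels = _crop_or_pad(labels, target_shape, offsets)

    seqs = seqs + rng.normal(0.0, noise_sigma, size=seqs.shape).astype(np.float32)

    return Case(case_id=case.case_id,
                sequences=np.ascontiguousarray(seqs, dtype=np.float32),
                labels=np.ascontiguousarray(labels, dtype=np.int16),
                spacing=case.spacing, provenance=dict(case.provenance))


# ------------------------------------------------------------------ splitting
def split_dataset(case_ids: list[str], ratios: tuple[int, int, int] = (7, 1, 2),
                  seed: int = 0) -> SplitManifest:
    """Seeded shuffle into train/val/test with floor/floor/remainder sizes."""
    n = len(case_ids)
    if n < 10:
        raise ValueError(f"need at least 10 cases to split, got {n}")
    total = sum(ratios)
    n_train = int(n * ratios[0] / total)
    n_val = int(n * ratios[1] / total)
    order = list(case_ids)
    np.random.default_rng(seed).shuffle(order)
    return SplitManifest(train=order[:n_train],
                         val=order[n_train:n_train + n_val],
                         test=order[n_train + n_val:],
                         seed=seed, ratios=tuple(ratios))
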