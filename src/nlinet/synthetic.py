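"""Seed-reproducible multi-sequence phantoms with nested tumor sub-regions.

Each phantom is a brain ellipsoid on a zero background; inside it sit nested
tumor ellipsoids assigning the labels ET (innermost), NCR (core shell around
ET), and ED (outer shell), so the derived sub-regions satisfy ET c TC c WT by
construction.  The four image channels emulate T1/T1ce/T2/FLAIR contrast with
per-tissue intensity offsets (ET bright on the T1ce-like channel, ED bright
on the FLAIR-like channel) plus additive Gaussian noise inside the brain;
labels are noise-free.  These phantoms exercise nesting, class imbalance, and
boundary metrics — not MRI physics or anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import Case, SplitManifest, save_case, split_dataset
from .losses import subregion_masks

# per-sequence intensity offsets added to the brain base intensity (1.0)
DEFAULT_CONTRAST = {
    #           NCR     ED      ET
    "t1":    (-0.35, -0.15, +0.10),
    "t1ce":  (-0.30, -0.10, +0.90),
    "t2":    (+0.30, +0.50, +0.20),
    "flair": (+0.20, +0.90, +0.30),
}


@dataclass
class PhantomParams:
    shape: tuple[int, int, int] = (32, 32, 16)
    num_sequences: int = 4
    brain_radius_frac: float = 0.44        # of each half-extent
    tumor_count: int = 1
    wt_radius_frac: tuple[float, float] = (0.22, 0.30)  # of min(shape)
    tc_radius_ratio: float = 0.65          # TC radius / WT radius
    et_radius_ratio: float = 0.42          # ET radius / WT radius
    contrast: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTRAST))
    noise_sigma: float = 0.1
    seed: int = 0
    max_placement_retries: int = 100

    def __post_init__(self):
        if not (self.et_radius_ratio < self.tc_radius_ratio < 1.0):
            raise ValueError("radii must nest: et_ratio < tc_ratio < 1")
        if len(self.contrast) < self.num_sequences:
            raise ValueError("contrast table must cover every sequence")


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def _min_separation(params: PhantomParams) -> float:
    """Smallest pairwise tissue contrast (on each pair's best channel)."""
    rows = list(params.contrast.values())[:params.num_sequences]
    # columns: brain (offset 0), NCR, ED, ET; rows: sequences
    table = np.concatenate([np.zeros((len(rows), 1)), np.asarray(rows)], axis=1)
    sep = np.inf
    for a in range(table.shape[1]):
        for b in range(a + 1, table.shape[1]):
            sep = min(sep, float(np.max(np.abs(table[:, a] - table[:, b]))))
    return sep


def generate_phantom(params: PhantomParams, case_id: str | None = None) -> Case:
    """Generate one phantom case; deterministic in params.seed."""
    sep = _min_separation(params)
    if sep < 3.0 * params.noise_sigma:
        raise ValueError(
            f"contrast table not segmentable: min pairwise tissue contrast {sep:.3f}"
            f" < 3 x noise sigma {3 * params.noise_sigma:.3f}")
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.shape)
    center = np.array(shape) / 2.0 - 0.5
    brain_radii = params.brain_radius_frac * np.array(shape)
    brain = _ellipsoid(shape, center, brain_radii)

    labels = np.zeros(shape, dtype=np.int16)
    for _ in range(params.tumor_count):
        placed = False
        for _attempt in range(params.max_placement_retries):
            wt_r = rng.uniform(*params.wt_radius_frac) * min(shape)
            aniso = rng.uniform(0.8, 1.2, size=3)
            wt_radii = wt_r * aniso
            margin = brain_radii - wt_radii
            if np.any(margin <= 0):
                continue
            offset = rng.uniform(-1, 1, size=3) * margin * 0.6
            c = center + offset
            # tumor inside brain: ellipsoid-in-ellipsoid sufficient condition
            if np.sum((offset / (brain_radii - wt_radii)) ** 2) > 1.0:
                continue
            wt = _ellipsoid(shape, c, wt_radii)
            tc = _ellipsoid(shape, c, wt_radii * params.tc_radius_ratio)
            et = _ellipsoid(shape, c, wt_radii * params.et_radius_ratio)
            if not (et.any() and (tc & ~et).any() and (wt & ~tc).any()):
                continue
            labels[wt & ~tc] = 2   # ED
            labels[tc & ~et] = 1   # NCR
            labels[et] = 3         # ET
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place a tumor inside the brain after "
                               f"{params.max_placement_retries} retries")
    labels[~brain] = 0

    seq_names = list(params.contrast)[:params.num_sequences]
    images = np.zeros((params.num_sequences,) + shape, dtype=np.float32)
    for s, name in enumerate(seq_names):
        ncr_off, ed_off, et_off = params.contrast[name]
        vol = np.where(brain, 1.0, 0.0)
        vol = vol + np.where(labels == 1, ncr_off, 0.0)
        vol = vol + np.where(labels == 2, ed_off, 0.0)
        vol = vol + np.where(labels == 3, et_off, 0.0)
        noise = rng.normal(0.0, params.noise_sigma, size=shape)
        vol = vol + np.where(brain, noise, 0.0)
        images[s] = vol.astype(np.float32)

    cid = case_id or f"phantom_{params.seed:06d}"
    case = Case(case_id=cid, sequences=images[None], labels=labels[None],
                spacing=(1.0, 1.0, 1.0), provenance={"generator": "synthetic"})
    # constructed nesting must hold and all regions be nonempty
    masks = subregion_masks(case.labels)
    if not (masks.counts > 0).all():
        raise RuntimeError("generated phantom has an empty sub-region")
    return case


def analytic_region_volumes(params: PhantomParams, wt_radius: float) -> dict[str, float]:
    """Closed-form ellipsoid volumes for an isotropic tumor of WT radius wt_radius."""
    v = lambda r: 4.0 / 3.0 * np.pi * r ** 3
    return {"WT": v(wt_radius),
            "TC": v(wt_radius * params.tc_radius_ratio),
            "ET": v(wt_radius * params.et_radius_ratio)}


def generate_dataset(n: int, params: PhantomParams, out_dir: str | Path,
                     ratios: tuple[int, int, int] = (7, 1, 2)) -> SplitManifest:
    """Write n phantom cases as NIfTI plus a split manifest; seeded by params.seed."""
    if n < 10:
        raise ValueError(f"need n >= 10 cases, got {n}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    case_ids = []
    for i in range(n):
        case_params = PhantomParams(**{**params.__dict__,
                                       "seed": (params.seed * 100003 + i) % (2 ** 31)})
        case = generate_phantom(case_params, case_id=f"phantom_{i:03d}")
        save_case(case, out_dir)
        case_ids.append(case.case_id)
    manifest = split_dataset(case_ids, ratios=ratios, seed=params.seed)
    manifest.to_json(out_dir / "split.json")
    return manifest
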