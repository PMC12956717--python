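"""Validation harness: overlap metrics, agreement statistics, losses,
stratified splits and paired volume/mask augmentation.

These are the desk-scale pieces of a segmentation/regression validation
pipeline: Dice and IoU between masks, Pearson/Spearman/RMSE between value
series, soft-Dice and combined segmentation+regression losses, stratified
70/15/15 train/val/test splits with five-fold cross-validation, and the
standard augmentations (±10° in-plane rotation, in-plane flips, random
cropping at scale 0.8–1.0, intensity perturbation) applied identically to a
volume and its mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.transform import resize

from .core import CTVolume, LabelMask

__all__ = [
    "EvalMetrics",
    "SplitPlan",
    "Splits",
    "AugmentConfig",
    "dice_iou",
    "regression_agreement",
    "soft_dice_loss",
    "combined_loss",
    "make_splits",
    "augment",
]


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, LabelMask):
        return mask.binary()
    return np.asarray(mask).astype(bool)


@dataclass
class EvalMetrics:
    dice: float | None = None
    iou: float | None = None
    pearson_r: float | None = None
    spearman_rho: float | None = None
    rmse: float | None = None
    flags: list[str] = field(default_factory=list)


def dice_iou(pred, ref) -> EvalMetrics:
    """Dice = 2|A∩B|/(|A|+|B|), IoU = |A∩B|/|A∪B|.

    The degenerate both-empty pair is defined as perfect agreement
    (dice = iou = 1) and flagged; other conventions exist (see docs).
    """
    a, b = _as_bool(pred), _as_bool(ref)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(a & b))
    na, nb = int(a.sum()), int(b.sum())
    union = na + nb - inter
    if na == 0 and nb == 0:
        return EvalMetrics(dice=1.0, iou=1.0, flags=["both masks empty"])
    return EvalMetrics(dice=2.0 * inter / (na + nb), iou=inter / union)


def regression_agreement(pred: Sequence[float], ref: Sequence[float]) -> EvalMetrics:
    """Pearson r, Spearman ρ and RMSE between two aligned value series.

    Zero variance in either series leaves the correlations flagged
    undefined (``None``), not 0.
    """
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ValueError("pred and ref must be 1D series of equal length")
    if p.size < 3:
        raise ValueError(f"need at least 3 pairs, got {p.size}")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(r))):
        raise ValueError("series must be finite")
    rmse = float(np.sqrt(np.mean((p - r) ** 2)))
    out = EvalMetrics(rmse=rmse)
    if np.ptp(p) == 0 or np.ptp(r) == 0:
        out.flags.append("zero variance: correlations undefined")
        return out
    out.pearson_r = float(stats.pearsonr(p, r).statistic)
    out.spearman_rho = float(stats.spearmanr(p, r).statistic)
    return out


def soft_dice_loss(prob, ref, eps: float = 1e-7) -> float:
    """``1 − (2Σp·g + ε)/(Σp + Σg + ε)`` for a probability map vs a mask."""
    p = np.asarray(prob, dtype=float)
    g = _as_bool(ref).astype(float)
    if p.shape != g.shape:
        raise ValueError("probability map and mask are not aligned")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(1.0 - (2.0 * np.sum(p * g) + eps) / (np.sum(p) + np.sum(g) + eps))


def combined_loss(seg_pairs: Sequence[tuple] = (),
                  reg_pred: Sequence[float] = (),
                  reg_target: Sequence[float] = (),
                  seg_weight: float = 1.0,
                  mse_weight: float = 1.0,
                  eps: float = 1e-7) -> float:
    """Weighted sum of soft-Dice terms and an MSE regression term.

    ``seg_pairs`` is a sequence of ``(prob map, reference mask)`` pairs whose
    soft-Dice losses are summed.  With one weight at 0 the loss reduces to
    the other component.
    """
    if seg_weight < 0 or mse_weight < 0:
        raise ValueError("weights must be >= 0")
    total = 0.0
    if seg_weight > 0:
        total += seg_weight * sum(soft_dice_loss(p, g, eps) for p, g in seg_pairs)
    if mse_weight > 0 and len(reg_pred):
        p = np.asarray(reg_pred, dtype=float)
        t = np.asarray(reg_target, dtype=float)
        if p.shape != t.shape:
            raise ValueError("regression predictions and targets are not aligned")
        total += mse_weight * float(np.mean((p - t) ** 2))
    return total


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """70/15/15 train/val/test fractions with stratified 5-fold CV."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {self.fractions}")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class Splits:
    train: list
    val: list
    test: list
    folds: list[list]


def make_splits(items: Sequence, plan: SplitPlan,
                strata: Sequence[Hashable] | None = None) -> Splits:
    """Deterministic stratified train/val/test split plus k folds.

    Within each stratum items are shuffled by the plan seed and sliced by the
    rounded fractions; folds are dealt round-robin so every fold receives the
    same per-stratum share (exactly one item per stratum when the stratum
    size equals ``k``).
    """
    items = list(items)
    if strata is None:
        strata = [0] * len(items)
    if len(strata) != len(items):
        raise ValueError("strata must align with items")
    groups: dict[Hashable, list] = {}
    for it, s in zip(items, strata):
        groups.setdefault(s, []).append(it)

    rng = np.random.default_rng(plan.seed)
    train, val, test = [], [], []
    folds: list[list] = [[] for _ in range(plan.k)]
    for key in sorted(groups, key=repr):
        members = list(groups[key])
        if len(members) < plan.k:
            raise ValueError(
                f"stratum {key!r} has {len(members)} items < k={plan.k} folds")
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        n = len(shuffled)
        n_train = int(round(plan.fractions[0] * n))
        n_val = int(round(plan.fractions[1] * n))
        n_train = min(n_train, n)
        n_val = min(n_val, n - n_train)
        train += shuffled[:n_train]
        val += shuffled[n_train:n_train + n_val]
        test += shuffled[n_train + n_val:]
        for i, it in enumerate(shuffled):
            folds[i % plan.k].append(it)
    return Splits(train=train, val=val, test=test, folds=folds)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    """Paired volume/mask augmentation parameters.

    Geometric transforms (rotation, flips, cropping) are sampled once and
    applied to both grids — linear interpolation for the volume, nearest
    neighbor for the mask.  Flips are in-plane (y and x axes); through-plane
    flips are excluded.  Intensity perturbation (a uniform additive offset in
    HU) touches the volume only.
    """

    rotation_deg: float = 10.0
    flip_horizontal: bool = True
    flip_vertical: bool = True
    crop_scale: tuple[float, float] = (0.8, 1.0)
    intensity_amplitude_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_deg < 0 or self.intensity_amplitude_hu < 0:
            raise ValueError("ranges must be non-negative")
        lo, hi = self.crop_scale
        if not 0 < lo <= hi <= 1:
            raise ValueError(f"crop_scale must satisfy 0 < lo <= hi <= 1, got {self.crop_scale}")


def augment(volume: CTVolume, mask: LabelMask,
            cfg: AugmentConfig) -> tuple[CTVolume, LabelMask]:
    """Apply one randomly sampled augmentation to a volume/mask pair.

    The same seed reproduces the same transform; a config with all ranges
    collapsed (rotation 0, flips off, crop scale (1, 1), amplitude 0) returns
    the pair unchanged.
    """
    mask.check_aligned(volume)
    rng = np.random.default_rng(cfg.seed)
    vol = volume.data.astype(np.float64, copy=True)
    msk = mask.data.copy()

    angle = float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)) if cfg.rotation_deg > 0 else 0.0
    do_h = bool(rng.integers(0, 2)) if cfg.flip_horizontal else False
    do_v = bool(rng.integers(0, 2)) if cfg.flip_vertical else False
    scale = float(rng.uniform(*cfg.crop_scale)) if cfg.crop_scale != (1.0, 1.0) else 1.0
    shift = float(rng.uniform(-cfg.intensity_amplitude_hu, cfg.intensity_amplitude_hu)) \
        if cfg.intensity_amplitude_hu > 0 else 0.0

    if angle != 0.0:
        vol = ndimage.rotate(vol, angle, axes=(1, 2), reshape=False,
                             order=1, mode="nearest")
        msk = ndimage.rotate(msk, angle, axes=(1, 2), reshape=False,
                             order=0, mode="nearest")
    if do_h:
        vol, msk = vol[:, :, ::-1], msk[:, :, ::-1]
    if do_v:
        vol, msk = vol[:, ::-1, :], msk[:, ::-1, :]
    if scale < 1.0:
        nz, ny, nx = vol.shape
        cy, cx = max(1, int(round(scale * ny))), max(1, int(round(scale * nx)))
        oy = int(rng.integers(0, ny - cy + 1))
        ox = int(rng.integers(0, nx - cx + 1))
        vol = vol[:, oy:oy + cy, ox:ox + cx]
        msk = msk[:, oy:oy + cy, ox:ox + cx]
        vol = resize(vol, (nz, ny, nx), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
        msk = resize(msk.astype(np.float64), (nz, ny, nx), order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True).astype(mask.data.dtype)
    if shift != 0.0:
        vol = vol + shift

    out_vol = CTVolume(np.ascontiguousarray(vol), volume.spacing, volume.origin)
    out_msk = LabelMask(np.ascontiguousarray(msk), mask.spacing, mask.labels)
    return out_vol, out_msk
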