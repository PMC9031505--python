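"""Indirect (2D slice-wise) and direct (patch-based 3D) segmentation paths.

The indirect path converts each volume into per-slice samples whose three
channels are the previous, current and next slice (edges replicated), runs
them through a 2D encoder-decoder and restacks the binarized slice
predictions into a volume.  The direct path tiles the volume into fixed-size
3D patches, segments each patch with a 3D encoder-decoder and stitches the
probability patches back, averaging overlaps.

Both are trained on soft Dice loss

    L = 1 - 2 * sum(y * p) / (sum(y^2) + sum(p^2) + eps)

reduced per batch item and averaged over the batch.  Training splits the
cohort per patient (never per slice, to avoid leakage between adjacent
slices of one brain), augments with random flips and 90-degree rotations,
and keeps the parameters of the epoch with the lowest validation loss.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import product as _iterproduct
from pathlib import Path
from typing import Sequence

import numpy as np

from .dicom_io import DwiStudy, LesionMask
from .unet import UNet, UNetConfig

__all__ = [
    "SliceTriplet",
    "Patch3D",
    "TrainConfig",
    "TrainHistory",
    "make_triplets",
    "Flip90",
    "draw_transform",
    "augment",
    "extract_patches",
    "stitch_patches",
    "dice_loss",
    "dice_loss_grad",
    "split_cohort",
    "train",
    "predict_indirect",
    "predict_direct",
    "normalize_volume",
]


# ---------------------------------------------------------------------------
# slice triplets (2.5D input)


@dataclass(frozen=True)
class SliceTriplet:
    """Three adjacent slices as channels (previous, current, next)."""

    channels: np.ndarray  # (3, H, W)
    index: int

    def __post_init__(self) -> None:
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ValueError(f"triplet channels must be (3, H, W), got {self.channels.shape}")


def make_triplets(study: DwiStudy | np.ndarray) -> list[SliceTriplet]:
    """One triplet per slice; missing neighbors at the volume boundary are
    replaced by the replicated edge slice."""
    volume = study.voxels if isinstance(study, DwiStudy) else np.asarray(study)
    n = volume.shape[0]
    out = []
    for k in range(n):
        prev_k = max(k - 1, 0)
        next_k = min(k + 1, n - 1)
        out.append(SliceTriplet(
            channels=np.stack([volume[prev_k], volume[k], volume[next_k]]),
            index=k,
        ))
    return out


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class Flip90:
    """A flip/rotation draw: horizontal flip, vertical flip, k x 90 degrees.

    Acts on the trailing two (row, column) axes so the same transform applies
    to a slice, a triplet or a whole volume.
    """

    hflip: bool
    vflip: bool
    k_rot: int  # number of counterclockwise 90-degree rotations, 0..3

    def apply(self, arr: np.ndarray) -> np.ndarray:
        out = arr
        if self.hflip:
            out = np.flip(out, axis=-1)
        if self.vflip:
            out = np.flip(out, axis=-2)
        if self.k_rot:
            out = np.rot90(out, k=self.k_rot, axes=(-2, -1))
        return np.ascontiguousarray(out)

    def inverse(self) -> "Flip90":
        # apply() does hflip, then vflip, then rotation; the inverse undoes
        # them in reverse order.  Flips conjugated through a rotation stay
        # flips, so the inverse is expressible in the same family:
        # inv = rot(-k) . vflip . hflip, and rot(-k).vflip.hflip equals
        # hflip'.vflip'.rot(-k) with flips swapped when k is odd.
        if self.k_rot % 2 == 0:
            return Flip90(self.hflip, self.vflip, (-self.k_rot) % 4)
        return Flip90(self.vflip, self.hflip, (-self.k_rot) % 4)

    def __call__(self, arr: np.ndarray) -> np.ndarray:
        return self.apply(arr)


def draw_transform(rng: np.random.Generator) -> Flip90:
    """Sample flips and rotation independently (identity has probability 1/16)."""
    return Flip90(
        hflip=bool(rng.integers(0, 2)),
        vflip=bool(rng.integers(0, 2)),
        k_rot=int(rng.integers(0, 4)),
    )


def augment(
    image: np.ndarray, mask: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one randomly drawn flip/rotation to an aligned image-mask pair."""
    if image.shape[-2:] != mask.shape[-2:]:
        raise ValueError(f"image {image.shape} and mask {mask.shape} not aligned in-plane")
    t = draw_transform(rng)
    return t.apply(image), t.apply(mask)


# ---------------------------------------------------------------------------
# 3D patches


@dataclass(frozen=True)
class Patch3D:
    """A fixed-shape sub-volume and its offset in the (padded) parent volume."""

    voxels: np.ndarray
    origin: tuple[int, int, int]


def _patch_starts(size: int, patch: int, stride: int) -> list[int]:
    if size <= patch:
        return [0]
    starts = list(range(0, size - patch + 1, stride))
    if starts[-1] != size - patch:
        starts.append(size - patch)
    return starts


def extract_patches(
    volume: np.ndarray | DwiStudy,
    patch_shape: tuple[int, int, int],
    stride: tuple[int, int, int],
) -> list[Patch3D]:
    """Tile a volume (zero-padded up to the patch shape) into overlapping
    patches; a trailing patch is added per axis so every voxel is covered."""
    v = volume.voxels if isinstance(volume, DwiStudy) else np.asarray(volume)
    if any(s <= 0 for s in stride):
        raise ValueError(f"stride must be positive, got {stride}")
    if any(st > p for st, p in zip(stride, patch_shape)):
        raise ValueError(f"stride {stride} exceeds patch shape {patch_shape}")
    padded_shape = tuple(max(s, p) for s, p in zip(v.shape, patch_shape))
    if padded_shape != v.shape:
        pad = tuple((0, ps - s) for ps, s in zip(padded_shape, v.shape))
        v = np.pad(v, pad)
    patches = []
    for origin in _iterproduct(*[
        _patch_starts(s, p, st) for s, p, st in zip(padded_shape, patch_shape, stride)
    ]):
        sl = tuple(slice(o, o + p) for o, p in zip(origin, patch_shape))
        patches.append(Patch3D(voxels=v[sl].copy(), origin=origin))
    return patches


def stitch_patches(
    patches: Sequence[Patch3D], volume_shape: tuple[int, int, int]
) -> np.ndarray:
    """Reassemble probability patches into a volume, averaging overlapping
    voxels and cropping any padding beyond ``volume_shape``."""
    if not patches:
        raise ValueError("no patches to stitch")
    patch_shape = patches[0].voxels.shape
    padded_shape = tuple(max(s, p) for s, p in zip(volume_shape, patch_shape))
    acc = np.zeros(padded_shape, dtype=np.float64)
    cnt = np.zeros(padded_shape, dtype=np.int64)
    for p in patches:
        sl = tuple(slice(o, o + s) for o, s in zip(p.origin, p.voxels.shape))
        acc[sl] += p.voxels
        cnt[sl] += 1
    if (cnt == 0).any():
        raise ValueError("patches do not cover the volume")
    out = acc / cnt
    return out[tuple(slice(0, s) for s in volume_shape)].astype(np.float32)


# ---------------------------------------------------------------------------
# Dice loss


def _flatten_batch(a: np.ndarray) -> np.ndarray:
    return a.reshape(a.shape[0], -1)


def dice_loss(pred_probs: np.ndarray, labels: np.ndarray, eps: float = 1e-6) -> float:
    """Soft Dice loss, reduced per batch item then averaged over the batch.

    ``eps`` stabilizes the empty-vs-empty case (both sums zero); with
    ``eps=0`` the loss is exactly 0 for a perfect binary match and exactly 1
    for disjoint masks.
    """
    if pred_probs.shape != labels.shape:
        raise ValueError(f"pred {pred_probs.shape} and labels {labels.shape} differ")
    p = _flatten_batch(np.asarray(pred_probs, dtype=np.float64))
    y = _flatten_batch(np.asarray(labels, dtype=np.float64))
    inter = (p * y).sum(axis=1)
    denom = (y * y).sum(axis=1) + (p * p).sum(axis=1) + eps
    with np.errstate(invalid="ignore"):
        dice = np.where(denom > 0, 2.0 * inter / denom, 1.0)
    return float(np.mean(1.0 - dice))


def dice_loss_grad(pred_probs: np.ndarray, labels: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """dL/dp for the soft Dice loss above (same shape as the predictions)."""
    shape = pred_probs.shape
    p = _flatten_batch(np.asarray(pred_probs, dtype=np.float64))
    y = _flatten_batch(np.asarray(labels, dtype=np.float64))
    inter = (p * y).sum(axis=1, keepdims=True)
    denom = (y * y).sum(axis=1, keepdims=True) + (p * p).sum(axis=1, keepdims=True) + eps
    grad = -2.0 * (y * denom - inter * 2.0 * p) / denom**2
    return (grad / p.shape[0]).reshape(shape).astype(np.float32)


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and protocol settings.

    The cohort is split per patient into train/validation/test at
    ``split_ratios`` (default 8:1:1).  ``threshold`` binarizes predicted
    probabilities.  ``patch_shape``/``patch_stride`` only apply to the direct
    (3D) path.
    """

    epochs: int = 12
    batch_size: int = 8
    learning_rate: float = 1e-3
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    threshold: float = 0.5
    seed: int = 0
    patch_shape: tuple[int, int, int] = (16, 64, 64)  # (slices, rows, cols)
    patch_stride: tuple[int, int, int] = (8, 32, 32)  # 50% overlap
    oversample_foreground: bool = False
    augment: bool = True

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.split_ratios) or abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError(f"split_ratios must be positive and sum to 1, got {self.split_ratios}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size must be >= 1 and learning_rate > 0")


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def record(self, epoch: int, train_loss: float, val_loss: float) -> None:
        self.epochs.append(epoch)
        self.train_loss.append(train_loss)
        self.val_loss.append(val_loss)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "val_loss"])
            for row in zip(self.epochs, self.train_loss, self.val_loss):
                w.writerow(row)


def split_cohort(
    n_patients: int, ratios: tuple[float, float, float] = (0.8, 0.1, 0.1), seed: int = 0
) -> tuple[list[int], list[int], list[int]]:
    """Seeded per-patient shuffle split into train/validation/test indices.

    Validation and test sizes round to the nearest patient but never drop to
    zero; a cohort too small for three nonempty parts raises.
    """
    if n_patients < 3:
        raise ValueError(f"need >= 3 patients for a 3-way split, got {n_patients}")
    n_val = max(1, round(n_patients * ratios[1]))
    n_test = max(1, round(n_patients * ratios[2]))
    n_train = n_patients - n_val - n_test
    if n_train < 1:
        raise ValueError(f"cohort of {n_patients} leaves no training patients at ratios {ratios}")
    order = np.random.default_rng(seed).permutation(n_patients)
    return (
        sorted(int(i) for i in order[:n_train]),
        sorted(int(i) for i in order[n_train:n_train + n_val]),
        sorted(int(i) for i in order[n_train + n_val:]),
    )


def normalize_volume(volume: np.ndarray) -> np.ndarray:
    """Per-volume z-scoring of the intensities (the model input scale)."""
    v = np.asarray(volume, dtype=np.float32)
    std = float(v.std())
    if std == 0.0:
        return v - float(v.mean())
    return (v - float(v.mean())) / std


def _indirect_samples(
    cohort: Sequence[tuple[DwiStudy, LesionMask]], idx: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack all slice triplets and label slices of the selected patients."""
    xs, ys = [], []
    for i in idx:
        study, mask = cohort[i]
        vol = normalize_volume(study.voxels)
        for t in make_triplets(vol):
            xs.append(t.channels)
            ys.append(mask.voxels[t.index][None])
    return np.stack(xs).astype(np.float32), np.stack(ys).astype(np.float32)


def _direct_samples(
    cohort: Sequence[tuple[DwiStudy, LesionMask]],
    idx: Sequence[int],
    cfg: TrainConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract aligned image/label 3D patches for the selected patients.

    With ``oversample_foreground`` lesion-containing patches are duplicated
    to counter the class imbalance of small sparse lesions; the default
    leaves the imbalance in place, which is the documented weakness of the
    direct path.
    """
    xs, ys = [], []
    for i in idx:
        study, mask = cohort[i]
        vol = normalize_volume(study.voxels)
        img_patches = extract_patches(vol, cfg.patch_shape, cfg.patch_stride)
        lab_patches = extract_patches(mask.voxels, cfg.patch_shape, cfg.patch_stride)
        for ip, lp in zip(img_patches, lab_patches):
            xs.append(ip.voxels[None])
            ys.append(lp.voxels[None])
            if cfg.oversample_foreground and lp.voxels.any():
                xs.append(ip.voxels[None])
                ys.append(lp.voxels[None])
    return np.stack(xs).astype(np.float32), np.stack(ys).astype(np.float32)


def _run_epoch(model, opt, x, y, cfg, rng) -> float:
    """One optimization epoch; returns the mean training Dice loss."""
    order = rng.permutation(len(x))
    losses = []
    for start in range(0, len(order), cfg.batch_size):
        sel = order[start:start + cfg.batch_size]
        xb, yb = x[sel], y[sel]
        if cfg.augment:
            xb = xb.copy()
            yb = yb.copy()
            for j in range(len(sel)):
                t = draw_transform(rng)
                xb[j] = t.apply(xb[j])
                yb[j] = t.apply(yb[j])
        opt.zero_grad()
        probs = model.forward(xb, train=True)
        losses.append(dice_loss(probs, yb))
        model.backward(dice_loss_grad(probs, yb))
        opt.step()
    return float(np.mean(losses))


def _eval_loss(model, x, y, cfg) -> float:
    losses = []
    for start in range(0, len(x), cfg.batch_size):
        xb, yb = x[start:start + cfg.batch_size], y[start:start + cfg.batch_size]
        losses.append(dice_loss(model.forward(xb, train=False), yb))
    return float(np.mean(losses))


def train(
    model_config: UNetConfig,
    train_config: TrainConfig,
    cohort: Sequence[tuple[DwiStudy, LesionMask]],
) -> tuple[UNet, TrainHistory, tuple[list[int], list[int], list[int]]]:
    """Train one segmentation path on a cohort of (study, mask) pairs.

    Patients are split per the configured ratios with the training seed; the
    model minimizing validation Dice loss is returned, along with the
    per-epoch history and the split membership.
    """
    from .nn import Adam

    if len(cohort) < 3:
        raise ValueError("cohort must contain at least 3 studies")
    split = split_cohort(len(cohort), train_config.split_ratios, train_config.seed)
    train_idx, val_idx, _ = split

    if model_config.dimensionality == 2:
        x_tr, y_tr = _indirect_samples(cohort, train_idx)
        x_va, y_va = _indirect_samples(cohort, val_idx)
    else:
        x_tr, y_tr = _direct_samples(cohort, train_idx, train_config)
        x_va, y_va = _direct_samples(cohort, val_idx, train_config)

    model = UNet(model_config)
    opt = Adam(model.params(), lr=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed + 1)
    history = TrainHistory()

    best_val = np.inf
    best_state = model.state_arrays()
    history.record(0, np.nan, _eval_loss(model, x_va, y_va, train_config))
    for epoch in range(1, train_config.epochs + 1):
        tr_loss = _run_epoch(model, opt, x_tr, y_tr, train_config, rng)
        va_loss = _eval_loss(model, x_va, y_va, train_config)
        history.record(epoch, tr_loss, va_loss)
        if va_loss < best_val:
            best_val = va_loss
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            history.best_epoch = epoch
    model.load_state_arrays(best_state)
    return model, history, split


# ---------------------------------------------------------------------------
# prediction


def predict_indirect(
    model: UNet, study: DwiStudy, threshold: float = 0.5
) -> LesionMask:
    """Slice-wise prediction: triplets through the 2D model, binarized and
    restacked into a volume-shaped mask in the study's (resized) geometry."""
    if model.config.dimensionality != 2:
        raise ValueError("predict_indirect requires a 2D model")
    vol = normalize_volume(study.voxels)
    x = np.stack([t.channels for t in make_triplets(vol)]).astype(np.float32)
    probs = []
    for start in range(0, len(x), 16):
        probs.append(model.forward(x[start:start + 16], train=False))
    p = np.concatenate(probs)[:, 0]
    alignment = "native" if study.voxels.shape[1:] == tuple(study.original_size) else "resized"
    return LesionMask(voxels=(p >= threshold).astype(np.uint8), alignment=alignment)


def predict_direct(
    model: UNet,
    study: DwiStudy,
    threshold: float = 0.5,
    patch_shape: tuple[int, int, int] = (16, 64, 64),
    patch_stride: tuple[int, int, int] = (8, 32, 32),
) -> LesionMask:
    """Patch-based 3D prediction: overlapping patches through the 3D model,
    probability-averaged stitching, then binarization."""
    if model.config.dimensionality != 3:
        raise ValueError("predict_direct requires a 3D model")
    vol = normalize_volume(study.voxels)
    patches = extract_patches(vol, patch_shape, patch_stride)
    prob_patches = []
    for p in patches:
        probs = model.forward(p.voxels[None, None], train=False)[0, 0]
        prob_patches.append(Patch3D(voxels=probs, origin=p.origin))
    stitched = stitch_patches(prob_patches, vol.shape)
    alignment = "native" if study.voxels.shape[1:] == tuple(study.original_size) else "resized"
    return LesionMask(voxels=(stitched >= threshold).astype(np.uint8), alignment=alignment)
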