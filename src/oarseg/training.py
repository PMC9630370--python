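"""Patch sampling, augmentation, the optimization loop, and the convergence rule.

Training follows the patch-based recipe: mini-batches of fixed-size patches
are cropped from the resampled, intensity-normalized image around randomly
drawn centre points.  Two sampling schemes exist — *global* sampling draws
centres uniformly over the image foreground (normalized intensity above a
threshold), which suits the coarse localization model; *mask* sampling draws
centres uniformly inside the labelled region, which suits the fine model.
``scheme="both"`` mixes them 50/50.

Optimization uses Adam (betas (0.9, 0.999), decoupled weight decay 1e-4) with
a step learning-rate schedule from an initial 1e-4.  A fraction of the cases
(default 10%) is held out for validation; training is considered converged
when the validation loss stops decreasing (tolerance 1e-6) for
``patience_epochs`` (default 5) consecutive epochs.  The checkpoint stores
the best-validation parameters together with every configuration object.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import ndimage

from .autodiff import Adam, Tensor, no_grad
from .losses import LossConfig, segmentation_loss
from .vbnet import NetworkSpec, build_model, save_checkpoint
from .volume import LabelMask, Volume

__all__ = [
    "SamplerConfig",
    "AugmentConfig",
    "TrainConfig",
    "EarlyStopping",
    "sample_patch_centers",
    "extract_patch",
    "augment",
    "split_train_val",
    "train_model",
]

_TRANSFORMS = {"rotate", "scale", "flip", "shift", "noise"}
IMAGE_PAD_VALUE = -1.0  # edge intensity after [-1, 1] normalization


class SamplerConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    scheme: str = "global"
    patch_size: tuple[int, int, int] = (96, 96, 96)
    batch_size: int = Field(2, ge=2)  # multi-GPU-style constraint: at least 2
    foreground_threshold: float = -0.95
    seed: int = 0

    def model_post_init(self, _ctx):
        if self.scheme not in ("global", "mask", "both"):
            raise ValueError(f"unknown sampling scheme {self.scheme!r}")


class AugmentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    transforms: list[str] = []
    rotate_deg: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    shift_vox: int = 5
    noise_sd: float = 0.02

    def model_post_init(self, _ctx):
        unknown = set(self.transforms) - _TRANSFORMS
        if unknown:
            raise ValueError(f"unknown transforms {sorted(unknown)}; valid: {sorted(_TRANSFORMS)}")


class TrainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    epochs: int = Field(1000, ge=1)
    lr_initial: float = Field(1e-4, gt=0)
    lr_factor: float = Field(0.1, gt=0)
    lr_interval: int = Field(250, ge=1)
    weight_decay: float = Field(1e-4, ge=0)
    betas: tuple[float, float] = (0.9, 0.999)
    val_fraction: float = Field(0.10, gt=0, lt=1)
    patience_epochs: int = Field(5, ge=1)
    batches_per_case: int = Field(4, ge=1)
    augmentation: AugmentConfig = AugmentConfig()
    seed: int = 0


class EarlyStopping:
    """Patience rule: stop when the watched loss has not improved (strict
    decrease beyond ``tol``) for ``patience`` consecutive epochs."""

    def __init__(self, patience: int = 5, tol: float = 1e-6):
        self.patience = patience
        self.tol = tol
        self.best = math.inf
        self.best_epoch = 0
        self.stale = 0
        self.epoch = 0

    def update(self, loss: float) -> bool:
        """Record one epoch-end loss; returns True when training should stop."""
        self.epoch += 1
        if loss < self.best - self.tol:
            self.best = loss
            self.best_epoch = self.epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


# ---------------------------------------------------------------------------
# Sampling and patch extraction


def sample_patch_centers(image: Volume, mask: LabelMask, cfg: SamplerConfig,
                         n: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` patch-centre voxel indices under the configured scheme."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    def draw(scheme, count):
        if scheme == "global":
            cand = np.argwhere(image.data > cfg.foreground_threshold)
            if cand.size == 0:
                raise ValueError("global sampling: no voxels above the foreground threshold")
        else:
            cand = np.argwhere(mask.data > 0)
            if cand.size == 0:
                raise ValueError("mask sampling: the mask is empty")
        return cand[rng.integers(0, len(cand), size=count)]

    if cfg.scheme == "both":
        n_global = n // 2
        parts = [draw("global", n_global), draw("mask", n - n_global)]
        return np.concatenate(parts, axis=0)
    return draw(cfg.scheme, n)


def extract_patch(image: Volume, mask: LabelMask, center, patch_size):
    """Extract aligned image/label patches of exactly ``patch_size`` centred at
    ``center``; voxels outside the grid are padded (image: -1, labels: 0)."""
    ps = tuple(int(s) for s in patch_size)
    img = np.full(ps, IMAGE_PAD_VALUE, dtype=image.data.dtype)
    lbl = np.zeros(ps, dtype=mask.data.dtype)
    src_sl, dst_sl = [], []
    for a in range(3):
        lo = int(center[a]) - ps[a] // 2
        s0, s1 = max(lo, 0), min(lo + ps[a], image.shape[a])
        if s1 <= s0:
            return img, lbl  # patch entirely off-grid: all padding
        src_sl.append(slice(s0, s1))
        dst_sl.append(slice(s0 - lo, s1 - lo))
    img[tuple(dst_sl)] = image.data[tuple(src_sl)]
    lbl[tuple(dst_sl)] = mask.data[tuple(src_sl)]
    return img, lbl


# ---------------------------------------------------------------------------
# Augmentation


def rotation_matrix(angle_deg: float, axes=(0, 1)) -> np.ndarray:
    """3x3 rotation matrix in the plane of ``axes``."""
    th = math.radians(angle_deg)
    m = np.eye(3)
    a, b = axes
    m[a, a] = math.cos(th)
    m[a, b] = -math.sin(th)
    m[b, a] = math.sin(th)
    m[b, b] = math.cos(th)
    return m


def apply_affine(image_patch, label_patch, matrix, shift_vox=(0, 0, 0)):
    """Apply one spatial transform jointly to both patches (about the centre).

    ``matrix`` maps output coordinates to input coordinates; images are
    interpolated linearly with edge padding -1, labels with nearest neighbour
    and padding 0, so the pair stays aligned.
    """
    center = (np.asarray(image_patch.shape) - 1) / 2.0
    offset = center - matrix @ center + np.asarray(shift_vox, dtype=float)
    img = ndimage.affine_transform(image_patch, matrix, offset=offset, order=1,
                                   mode="constant", cval=IMAGE_PAD_VALUE)
    lbl = ndimage.affine_transform(label_patch, matrix, offset=offset, order=0,
                                   mode="constant", cval=0)
    return img.astype(np.float32), lbl.astype(np.int32)


def apply_rotation(image_patch, label_patch, angle_deg: float, axes=(0, 1)):
    return apply_affine(image_patch, label_patch, rotation_matrix(angle_deg, axes))


def apply_flip(image_patch, label_patch, axes):
    sl = tuple(slice(None, None, -1) if a in axes else slice(None) for a in range(3))
    return np.ascontiguousarray(image_patch[sl]), np.ascontiguousarray(label_patch[sl])


def augment(image_patch, label_patch, cfg: AugmentConfig,
            rng: np.random.Generator | None = None, seed: int | None = None):
    """Randomized augmentation with one identical spatial transform for both
    patches; intensity noise is applied to the image only.  An empty transform
    list returns the inputs unchanged.  Reproducible from ``rng`` or ``seed``."""
    if not cfg.transforms:
        return image_patch, label_patch
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    img, lbl = image_patch, label_patch

    matrix = np.eye(3)
    shift = np.zeros(3)
    spatial = False
    if "rotate" in cfg.transforms:
        axes = tuple(sorted(rng.choice(3, size=2, replace=False)))
        angle = float(rng.uniform(-cfg.rotate_deg, cfg.rotate_deg))
        matrix = matrix @ rotation_matrix(angle, axes)
        spatial = True
    if "scale" in cfg.transforms:
        factor = float(rng.uniform(*cfg.scale_range))
        matrix = matrix / factor  # output->input map: zoom by `factor`
        spatial = True
    if "shift" in cfg.transforms:
        shift = rng.integers(-cfg.shift_vox, cfg.shift_vox + 1, size=3).astype(float)
        spatial = True
    if spatial:
        img, lbl = apply_affine(img, lbl, matrix, shift)
    if "flip" in cfg.transforms:
        axes = tuple(a for a in range(3) if rng.random() < 0.5)
        if axes:
            img, lbl = apply_flip(img, lbl, axes)
    if "noise" in cfg.transforms and cfg.noise_sd > 0:
        img = (img + rng.normal(0.0, cfg.noise_sd, size=img.shape)).astype(np.float32)
    return img, lbl


# ---------------------------------------------------------------------------
# Splits and the training loop


def split_train_val(cases: list, val_fraction: float = 0.10, seed: int = 0):
    """Random disjoint, exhaustive split with ``|val| = max(1, round(f*N))``."""
    if len(cases) < 2:
        raise ValueError("need at least 2 cases to split")
    if not (0 < val_fraction < 1):
        raise ValueError("val_fraction must be in (0, 1)")
    order = np.random.default_rng(seed).permutation(len(cases))
    n_val = max(1, int(np.floor(val_fraction * len(cases) + 0.5)))
    n_val = min(n_val, len(cases) - 1)
    val_idx = set(order[:n_val].tolist())
    train = [c for i, c in enumerate(cases) if i not in val_idx]
    val = [c for i, c in enumerate(cases) if i in val_idx]
    return train, val


def _assemble_batch(case, sampler_cfg, aug_cfg, rng, in_channels: int):
    image, mask = case
    centers = sample_patch_centers(image, mask, sampler_cfg, sampler_cfg.batch_size, rng)
    xs, ys = [], []
    for c in centers:
        img, lbl = extract_patch(image, mask, c, sampler_cfg.patch_size)
        if aug_cfg is not None:
            img, lbl = augment(img, lbl, aug_cfg, rng)
        xs.append(np.broadcast_to(img, (in_channels,) + img.shape))
        ys.append(lbl)
    return np.stack(xs).astype(np.float64), np.stack(ys)


def train_model(
    train_cases: list,
    val_cases: list,
    net_spec: NetworkSpec,
    loss_cfg: LossConfig,
    train_cfg: TrainConfig,
    sampler_cfg: SamplerConfig,
    out_dir,
) -> tuple[Path, pd.DataFrame]:
    """Train a model on preprocessed (normalized image, label mask) cases.

    Returns the checkpoint directory (best-validation parameters plus all
    configs) and the per-epoch log (epoch, train_loss, val_loss, lr).  With
    all seeds fixed the run is deterministic.  Non-finite losses abort.
    """
    if not train_cases:
        raise ValueError("need at least one training case")
    net_spec.validate_patch_size(sampler_cfg.patch_size)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    model = build_model(net_spec, seed=train_cfg.seed)
    opt = Adam(model.parameters(), lr=train_cfg.lr_initial, betas=tuple(train_cfg.betas),
               weight_decay=train_cfg.weight_decay)

    rng = np.random.default_rng(train_cfg.seed + 1)
    # fixed validation patch set, sampled once: a stable convergence signal
    val_rng = np.random.default_rng(train_cfg.seed + 2)
    val_sampler = sampler_cfg.model_copy(update={"scheme": "mask"})
    val_batches = [
        _assemble_batch(case, val_sampler, None, val_rng, net_spec.in_channels)
        for case in (val_cases if val_cases else train_cases[:1])
    ]

    stopper = EarlyStopping(train_cfg.patience_epochs)
    best_params = [p.data.copy() for p in model.parameters()]
    rows = []
    for epoch in range(1, train_cfg.epochs + 1):
        opt.lr = train_cfg.lr_initial * train_cfg.lr_factor ** ((epoch - 1) // train_cfg.lr_interval)
        batch_losses = []
        for case in train_cases:
            for _ in range(train_cfg.batches_per_case):
                x, y = _assemble_batch(case, sampler_cfg, train_cfg.augmentation,
                                       rng, net_spec.in_channels)
                probs = model(Tensor(x)).softmax(axis=1)
                loss = segmentation_loss(probs, y, loss_cfg)
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"training diverged: non-finite loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                batch_losses.append(loss.item())
        with no_grad():
            val_losses = []
            for x, y in val_batches:
                probs = model(Tensor(x)).softmax(axis=1)
                val_losses.append(segmentation_loss(probs, y, loss_cfg).item())
        train_loss = float(np.mean(batch_losses))
        val_loss = float(np.mean(val_losses))
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_loss": val_loss, "lr": opt.lr})
        improved_epoch = stopper.best_epoch
        stop = stopper.update(val_loss)
        if stopper.best_epoch != improved_epoch or epoch == 1:
            best_params = [p.data.copy() for p in model.parameters()]
        if stop:
            break

    for p, best in zip(model.parameters(), best_params):
        p.data[...] = best
    log = pd.DataFrame(rows)
    log.to_csv(out_dir / "training_log.csv", index=False)
    ckpt = save_checkpoint(
        model, out_dir,
        extra={
            "loss_config": loss_cfg.model_dump(),
            "train_config": train_cfg.model_dump(),
            "sampler_config": sampler_cfg.model_dump(),
            "best_epoch": stopper.best_epoch,
            "best_val_loss": stopper.best,
        },
    )
    return ckpt, log
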