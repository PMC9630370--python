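"""Training objectives: soft Dice in 3D and per-slice 2D, adaptive slice
weights, the combined multi-dimensional adaptive Dice loss, band-masked
boundary Dice, and focal loss.

The multi-dimensional adaptive loss is

    loss = lambda1 * loss3D + lambda2 * sum_i w_i * loss2D_i,

where ``loss3D``/``loss2D_i`` are smoothed soft Dice losses of the volume and
of slice ``i`` along the configured axis, and ``w_i = 1 - d_i**2`` with
``d_i`` the slice's Dice coefficient — slices that are already segmented well
contribute nothing, failed slices contribute with full weight, which pushes
optimization toward the superior-inferior boundary slices of a target volume.
Defaults: lambda1 = 0.7, lambda2 = 0.3.

All losses accept either autodiff Tensors (returning a scalar Tensor on the
tape) or plain numpy arrays (returning a float).  The adaptive weights are
kept on the tape, so each loss is exactly the function whose gradient the
engine reports; the optimum (prediction equal to target) is unchanged by
this choice and the weights stay in [0, 1].
"""

from __future__ import annotations

import warnings

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import ndimage

from .autodiff import Tensor

__all__ = [
    "LossConfig",
    "dice_loss_3d",
    "dice_loss_2d_slice",
    "adaptive_slice_weight",
    "adaptive_loss",
    "boundary_dice_loss",
    "focal_loss",
    "segmentation_loss",
]

_COMPONENTS = {"dice3d", "boundary_dice", "adaptive2d", "focal"}


class LossConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    lambda1: float = Field(0.7, ge=0)
    lambda2: float = Field(0.3, ge=0)
    smooth_eps: float = Field(1e-5, gt=0)
    boundary_width_vox: int = Field(2, ge=1)
    slice_axis: int = Field(2, ge=0, le=2)  # superior-inferior by convention
    components: list[str] = ["dice3d"]
    average_slices: bool = False
    focal_gamma: float = Field(2.0, ge=0)
    focal_alpha: float = Field(1.0, gt=0)

    def model_post_init(self, _ctx):
        unknown = set(self.components) - _COMPONENTS
        if unknown:
            raise ValueError(f"unknown loss components {sorted(unknown)}; valid: {sorted(_COMPONENTS)}")


def _prepare(pred, target, check_range: bool = True):
    """Coerce inputs; returns (pred Tensor, target constant Tensor, want_float)."""
    want_float = not isinstance(pred, Tensor)
    p = Tensor(np.asarray(pred, dtype=float)) if want_float else pred
    t_data = np.asarray(target.data if isinstance(target, Tensor) else target, dtype=float)
    if p.shape != t_data.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t_data.shape}")
    if check_range and (p.data.min() < -1e-9 or p.data.max() > 1 + 1e-9):
        raise ValueError("pred must be a probability grid in [0, 1]")
    return p, Tensor(t_data), want_float


def _ret(value: Tensor, want_float: bool):
    return value.item() if want_float else value


def _soft_dice(p: Tensor, t: Tensor, eps: float) -> Tensor:
    """Smoothed Dice coefficient (2*sum(p*t)+eps)/(sum(p)+sum(t)+eps)."""
    return (2.0 * (p * t).sum() + eps) / (p.sum() + t.sum() + eps)


def dice_loss_3d(pred, target, smooth_eps: float = 1e-5):
    """Soft 3D Dice loss, 1 - smoothed Dice coefficient; differentiable in pred."""
    p, t, wf = _prepare(pred, target)
    return _ret(1.0 - _soft_dice(p, t, smooth_eps), wf)


def dice_loss_2d_slice(pred_slice, target_slice, smooth_eps: float = 1e-5):
    """Soft Dice loss of a single 2D slice.  An empty pred/empty target slice
    has loss 0 under the smoothed form (vacuous slice)."""
    p, t, wf = _prepare(pred_slice, target_slice)
    return _ret(1.0 - _soft_dice(p, t, smooth_eps), wf)


def adaptive_slice_weight(pred_slice, target_slice, smooth_eps: float = 1e-5):
    """Adaptive slice weight ``1 - d**2`` with ``d`` the slice's smoothed Dice:
    0 for a perfect slice, 1 for a fully failed one."""
    p, t, wf = _prepare(pred_slice, target_slice)
    d = _soft_dice(p, t, smooth_eps)
    return _ret(1.0 - d * d, wf)


def adaptive_loss(pred, target, cfg: LossConfig = LossConfig()):
    """Multi-dimensional adaptive Dice loss over a 3D grid.

    ``lambda1 * loss3D + lambda2 * sum_i (1 - d_i^2) * loss2D_i`` with the sum
    over every slice along ``cfg.slice_axis`` (optionally averaged when
    ``cfg.average_slices``).  Equals ``lambda1 * loss3D`` when every slice is
    perfect; each slice term carries gradient.
    """
    p, t, wf = _prepare(pred, target)
    loss = cfg.lambda1 * (1.0 - _soft_dice(p, t, cfg.smooth_eps))
    axis = cfg.slice_axis
    n = p.shape[axis]
    idx = [slice(None)] * p.data.ndim
    total = Tensor(0.0)
    for i in range(n):
        idx[axis] = i
        pi, ti = p[tuple(idx)], t[tuple(idx)]
        d = _soft_dice(pi, ti, cfg.smooth_eps)
        total = total + (1.0 - d * d) * (1.0 - d)
    if cfg.average_slices:
        total = total * (1.0 / n)
    return _ret(loss + cfg.lambda2 * total, wf)


def boundary_dice_loss(pred, target, cfg: LossConfig = LossConfig()):
    """Dice loss restricted to the morphological boundary band of the target.

    The band is ``dilate(target, w) & ~erode(target, w)`` with
    ``w = cfg.boundary_width_vox``; both prediction and target are masked to
    the band before the soft Dice.  A target with no boundary (all background
    or all foreground) yields 0 with a warning.
    """
    p, t, wf = _prepare(pred, target)
    t_bin = t.data > 0.5
    n_fg = int(t_bin.sum())
    if n_fg == 0 or n_fg == t_bin.size:
        warnings.warn("target has no boundary (all background or all foreground); "
                      "boundary Dice loss defined as 0", stacklevel=2)
        return _ret(Tensor(0.0), wf)
    w = cfg.boundary_width_vox
    band = ndimage.binary_dilation(t_bin, iterations=w) & ~ndimage.binary_erosion(t_bin, iterations=w)
    band_t = Tensor(band.astype(float))
    return _ret(1.0 - _soft_dice(p * band_t, t * band_t, cfg.smooth_eps), wf)


def focal_loss(pred, target, gamma: float = 2.0, alpha: float = 1.0):
    """Binary focal loss: mean of ``-alpha * (1 - p_t)^gamma * log(p_t)``.

    ``p_t`` is the predicted probability of the true class; predictions at
    exactly 0/1 are clamped to keep the logarithm finite.  At ``gamma = 0``
    this reduces to ``alpha`` times binary cross-entropy.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p, t, wf = _prepare(pred, target)
    eps = 1e-7
    p = p.clip(eps, 1.0 - eps)
    p_t = p * t + (1.0 - p) * (1.0 - t)
    loss = (-alpha) * ((1.0 - p_t) ** gamma) * p_t.log()
    return _ret(loss.mean(), wf)


def segmentation_loss(probs: Tensor, labels: np.ndarray, cfg: LossConfig):
    """Total training objective for a softmax probability batch.

    ``probs`` is (N, K, D, H, W); ``labels`` is an integer (N, D, H, W) array.
    For each sample and each foreground class the configured components are
    summed (``adaptive2d`` subsumes the lambda1-weighted 3D Dice term), then
    averaged over samples and classes.
    """
    n, k = probs.shape[0], probs.shape[1]
    comps = set(cfg.components)
    total = Tensor(0.0)
    count = 0
    for s in range(n):
        for klass in range(1, k):
            p = probs[s, klass]
            t = (labels[s] == klass).astype(float)
            if "adaptive2d" in comps:
                total = total + adaptive_loss(p, Tensor(t), cfg)
            elif "dice3d" in comps:
                total = total + dice_loss_3d(p, t, cfg.smooth_eps)
            if "boundary_dice" in comps:
                total = total + boundary_dice_loss(p, Tensor(t), cfg)
            if "focal" in comps:
                total = total + focal_loss(p, Tensor(t), cfg.focal_gamma, cfg.focal_alpha)
            count += 1
    return total * (1.0 / max(count, 1))
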