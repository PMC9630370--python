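"""Two-stage coarse-to-fine inference with optional attention channels.

The coarse stage resamples the image to a large voxel spacing (default
5x5x5 mm, nearest neighbour), segments it, and converts the detected
structure into a bounding box on the original grid.  The fine stage crops to
that box, resamples to a small spacing (default 1x1x1 mm; trilinear for
isotropic input, nearest for anisotropic), optionally concatenates attention
channels (the union of organ-at-risk masks, and a superior-inferior extent
indicator derived from the coarse target segmentation), segments with
sliding-window patch inference, and pastes the result back onto the original
grid.  By construction the fine stage can never predict outside the coarse
box, which structurally rules out distant false positives; connected-
component post-processing removes the remainder.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy import ndimage

from .volume import (
    BoundingBox,
    LabelMask,
    NormalizationSpec,
    Volume,
    bounding_box_of,
    crop,
    normalize_intensity,
    paste,
    resample,
    resample_to_shape,
)

__all__ = [
    "CascadeConfig",
    "AttentionMaps",
    "sliding_window_predict",
    "coarse_localize",
    "fine_segment",
    "make_oar_attention",
    "make_boundary_attention",
    "postprocess",
    "run_cascade",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class PostprocessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    keep_largest_cc: bool = True
    min_cc_voxels: int = Field(27, ge=0)


class AttentionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    use_oar_map: bool = False
    use_boundary_map: bool = False

    @property
    def n_channels(self) -> int:
        return int(self.use_oar_map) + int(self.use_boundary_map)


class CascadeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    coarse_spacing: tuple[float, float, float] = (5.0, 5.0, 5.0)
    fine_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bbox_margin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    coarse_patch_size: tuple[int, int, int] = (96, 96, 96)
    fine_patch_size: tuple[int, int, int] = (96, 96, 96)
    window_overlap: float = Field(0.25, ge=0, lt=1)
    slice_axis: int = Field(2, ge=0, le=2)
    strict_detection: bool = False
    normalization: NormalizationSpec = NormalizationSpec()
    postprocess: PostprocessConfig = PostprocessConfig()
    attention: AttentionConfig = AttentionConfig()

    def model_post_init(self, _ctx):
        if any(c < f for c, f in zip(self.coarse_spacing, self.fine_spacing)):
            raise ValueError("coarse_spacing must be >= fine_spacing componentwise")


@dataclass
class AttentionMaps:
    """Auxiliary input channels on the fine crop grid."""

    oar_map: Volume | None = None
    boundary_map: Volume | None = None

    def channels(self) -> list[np.ndarray]:
        maps = [m for m in (self.oar_map, self.boundary_map) if m is not None]
        return [m.data.astype(np.float64) for m in maps]


# ---------------------------------------------------------------------------
# Sliding-window inference


def _window_starts(size: int, patch: int, overlap: float) -> list[int]:
    if size <= patch:
        return [0]
    step = max(1, int(round(patch * (1.0 - overlap))))
    starts = list(range(0, size - patch + 1, step))
    if starts[-1] != size - patch:
        starts.append(size - patch)  # flush final window: every voxel covered
    return starts


def sliding_window_predict(channels: np.ndarray, model, patch_size,
                           window_overlap: float = 0.25) -> np.ndarray:
    """Tile a (C, D, H, W) normalized input and average per-class probabilities.

    Windows beyond the image edge are handled by padding the whole input up to
    the patch size (image channels padded with -1) and cropping the result
    back.  Per-voxel probabilities from overlapping windows are combined by
    uniform averaging, so they still sum to one over classes.
    """
    channels = np.asarray(channels, dtype=np.float64)
    if channels.ndim != 4:
        raise ValueError("expected (C, D, H, W) input")
    ps = tuple(int(p) for p in patch_size)
    orig_shape = channels.shape[1:]
    pad = [(0, max(0, p - s)) for p, s in zip(ps, orig_shape)]
    if any(p[1] for p in pad):
        channels = np.pad(channels, [(0, 0)] + pad, constant_values=-1.0)
    shape = channels.shape[1:]

    n_classes = model.spec.out_classes
    probs = np.zeros((n_classes,) + shape)
    counts = np.zeros(shape)
    starts = [_window_starts(shape[a], ps[a], window_overlap) for a in range(3)]
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                sl = (slice(i, i + ps[0]), slice(j, j + ps[1]), slice(k, k + ps[2]))
                window = channels[(slice(None),) + sl]
                probs[(slice(None),) + sl] += model.predict_proba(window)
                counts[sl] += 1.0
    assert counts.min() >= 1.0
    probs /= counts
    crop_sl = tuple(slice(0, s) for s in orig_shape)
    return probs[(slice(None),) + crop_sl]


# ---------------------------------------------------------------------------
# Coarse stage


def coarse_localize(image: Volume, coarse_model, cfg: CascadeConfig,
                    label: int = 1) -> BoundingBox:
    """Localize structure ``label`` on the coarse grid and map its bounding box
    back to original-image voxel coordinates, expanded by ``bbox_margin_mm``.

    If the coarse prediction misses the label entirely, either raises
    (``strict_detection``) or falls back to the whole-image box with a warning.
    """
    coarse_img = resample(image, cfg.coarse_spacing, method="nearest")
    norm = normalize_intensity(coarse_img, cfg.normalization)
    probs = sliding_window_predict(norm.data[None], coarse_model,
                                   cfg.coarse_patch_size, cfg.window_overlap)
    pred = LabelMask(np.argmax(probs, axis=0).astype(np.int32),
                     coarse_img.spacing, coarse_img.origin)
    try:
        box_c = bounding_box_of(pred, label)
    except ValueError:
        if cfg.strict_detection:
            raise ValueError(f"coarse detection failure: label {label} not found")
        warnings.warn(f"coarse detection failure for label {label}; "
                      "falling back to the whole-image box", stacklevel=2)
        return BoundingBox((0, 0, 0), image.shape)

    ratio = [c / o for c, o in zip(cfg.coarse_spacing, image.spacing)]
    lo = [int(np.floor(box_c.lo[a] * ratio[a])) for a in range(3)]
    hi = [int(np.ceil(box_c.hi[a] * ratio[a])) for a in range(3)]
    margin = [int(np.ceil(m / image.spacing[a])) for a, m in enumerate(cfg.bbox_margin_mm)]
    return BoundingBox(lo, hi).expand(margin).clamp(image.shape)


# ---------------------------------------------------------------------------
# Attention maps


def make_oar_attention(oar_masks: list[LabelMask], box: BoundingBox,
                       fine_crop_shape, reference: Volume) -> Volume:
    """Binary union of organ-at-risk masks, cropped to the box and resampled
    (nearest) to the fine crop grid."""
    union = np.zeros(reference.shape, dtype=np.int32)
    for m in oar_masks:
        if not m.same_geometry(reference):
            raise ValueError("all OAR masks must share the reference image geometry")
        union |= (m.data > 0).astype(np.int32)
    cropped = union[box.slices()]
    data = resample_to_shape(cropped, fine_crop_shape, method="nearest")
    return Volume(data.astype(np.float32))


def make_boundary_attention(coarse_target: LabelMask, box: BoundingBox,
                            fine_crop_shape, reference: Volume,
                            slice_axis: int = 2) -> Volume:
    """Superior-inferior extent indicator of the coarse target segmentation.

    On the fine crop grid: value 1 for slices (along ``slice_axis``) between
    the lowest and highest slice occupied by the coarse target inside the
    box, 0 outside.  Encodes the upper/lower boundary prior for target-volume
    delineation; constant within each slice by construction.
    """
    if not (coarse_target.data > 0).any():
        raise ValueError("empty coarse target mask")
    # coarse target on its own grid -> original grid indices along the axis
    occ = np.argwhere(coarse_target.data > 0)
    ratio = coarse_target.spacing[slice_axis] / reference.spacing[slice_axis]
    lo_orig = occ[:, slice_axis].min() * ratio
    hi_orig = (occ[:, slice_axis].max() + 1) * ratio
    # map to fine-crop slice indices
    crop_extent = box.hi[slice_axis] - box.lo[slice_axis]
    scale = fine_crop_shape[slice_axis] / crop_extent
    lo_f = int(np.floor((lo_orig - box.lo[slice_axis]) * scale))
    hi_f = int(np.ceil((hi_orig - box.lo[slice_axis]) * scale))
    lo_f = max(lo_f, 0)
    hi_f = min(hi_f, fine_crop_shape[slice_axis])
    data = np.zeros(fine_crop_shape, dtype=np.float32)
    sl = [slice(None)] * 3
    sl[slice_axis] = slice(lo_f, hi_f)
    data[tuple(sl)] = 1.0
    return Volume(data)


# ---------------------------------------------------------------------------
# Fine stage


def _is_isotropic(spacing) -> bool:
    return max(spacing) / min(spacing) < 1.01


def fine_segment(image: Volume, box: BoundingBox, fine_model, cfg: CascadeConfig,
                 attention: AttentionMaps | None = None) -> LabelMask:
    """Segment inside ``box`` at fine spacing and paste onto the original grid.

    The fine model's input channel count must equal 1 plus the number of
    attention channels supplied.  Voxels outside the box are always 0.
    """
    n_att = len(attention.channels()) if attention is not None else 0
    if fine_model.spec.in_channels != 1 + n_att:
        raise ValueError(
            f"fine model expects {fine_model.spec.in_channels} input channels "
            f"but {1 + n_att} were supplied (image + {n_att} attention)"
        )
    box = box.clamp(image.shape)
    cropped = crop(image, box)
    method = "linear" if _is_isotropic(image.spacing) else "nearest"
    fine_img = resample(cropped, cfg.fine_spacing, method=method)
    norm = normalize_intensity(fine_img, cfg.normalization)

    channels = [norm.data.astype(np.float64)]
    if attention is not None:
        for ch in attention.channels():
            if ch.shape != norm.shape:
                raise ValueError(f"attention map shape {ch.shape} != fine crop {norm.shape}")
            channels.append(ch)
    probs = sliding_window_predict(np.stack(channels), fine_model,
                                   cfg.fine_patch_size, cfg.window_overlap)
    fine_pred = np.argmax(probs, axis=0).astype(np.int32)
    back = resample_to_shape(fine_pred, box.shape, method="nearest")
    canvas = LabelMask(np.zeros(image.shape, dtype=np.int32), image.spacing, image.origin)
    return paste(canvas, back.astype(np.int32), box)


# ---------------------------------------------------------------------------
# Post-processing


def postprocess(mask: LabelMask, cfg: PostprocessConfig = PostprocessConfig()) -> LabelMask:
    """Connected-component cleanup per label (26-connectivity); never adds voxels.

    ``keep_largest_cc`` retains only the largest component of each label;
    otherwise components smaller than ``min_cc_voxels`` are removed.
    """
    out = np.zeros_like(mask.data)
    for label in mask.labels():
        binary = mask.data == label
        comps, n = ndimage.label(binary, structure=_CONN26)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(binary, comps, index=np.arange(1, n + 1))
        if cfg.keep_largest_cc:
            keep = comps == (int(np.argmax(sizes)) + 1)
        else:
            good = np.flatnonzero(sizes >= cfg.min_cc_voxels) + 1
            keep = np.isin(comps, good)
        out[keep] = label
    return LabelMask(out, mask.spacing, mask.origin)


# ---------------------------------------------------------------------------
# Full cascade


def run_cascade(image: Volume, coarse_model, fine_model, cfg: CascadeConfig,
                label: int = 1, oar_masks: list[LabelMask] | None = None,
                coarse_target: LabelMask | None = None):
    """Coarse localization -> attention construction -> fine segmentation ->
    post-processing.  Returns ``(mask, report)``; the report records the box,
    stage timings, and per-stage voxel counts."""
    att_cfg = cfg.attention
    n_att = att_cfg.n_channels
    if fine_model.spec.in_channels != 1 + n_att:
        raise ValueError(
            f"configuration error: attention supplies {n_att} extra channels but the "
            f"fine model was built for {fine_model.spec.in_channels} input channels"
        )
    report: dict = {}
    t0 = time.perf_counter()
    box = coarse_localize(image, coarse_model, cfg, label=label)
    report["box"] = {"lo": list(box.lo), "hi": list(box.hi)}
    report["coarse_seconds"] = time.perf_counter() - t0

    attention = None
    if n_att:
        cropped_shape = _fine_crop_shape(image, box, cfg)
        oar_map = boundary_map = None
        if att_cfg.use_oar_map:
            oar_map = make_oar_attention(oar_masks or [], box, cropped_shape, image)
        if att_cfg.use_boundary_map:
            if coarse_target is None:
                raise ValueError("boundary attention requires a coarse target mask")
            boundary_map = make_boundary_attention(coarse_target, box, cropped_shape,
                                                   image, cfg.slice_axis)
        attention = AttentionMaps(oar_map=oar_map, boundary_map=boundary_map)

    t1 = time.perf_counter()
    mask = fine_segment(image, box, fine_model, cfg, attention)
    report["fine_seconds"] = time.perf_counter() - t1
    report["voxels_before_postprocess"] = int((mask.data > 0).sum())

    t2 = time.perf_counter()
    mask = postprocess(mask, cfg.postprocess)
    report["postprocess_seconds"] = time.perf_counter() - t2
    report["voxels_after_postprocess"] = int((mask.data > 0).sum())
    report["total_seconds"] = time.perf_counter() - t0
    return mask, report


def _fine_crop_shape(image: Volume, box: BoundingBox, cfg: CascadeConfig):
    from .volume import _output_shape  # shared rounding rule

    return _output_shape(box.shape, image.spacing, cfg.fine_spacing)
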