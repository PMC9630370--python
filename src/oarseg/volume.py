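"""Volumetric grid types, NIfTI I/O, resampling, and intensity normalization.

All geometry in this package is axis-aligned voxel geometry: the physical
position of voxel ``(i, j, k)`` is ``origin + (i*sx, j*sy, k*sz)`` with
spacing ``(sx, sy, sz)`` in millimetres.  Direction matrices (oblique
acquisitions) are out of scope and rejected at read time.

Resampling follows the cascade's two conventions: nearest-neighbour index
mapping for label masks and coarse-stage images, trilinear interpolation for
fine-stage images.  The output shape under a spacing change is
``round(shape * spacing / target_spacing)`` with a floor of one voxel per
axis; "round" here is ``floor(x + 0.5)`` so that the rule is reproducible
across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "LabelMask",
    "BoundingBox",
    "NormalizationSpec",
    "read_volume",
    "write_volume",
    "resample",
    "normalize_intensity",
    "bounding_box_of",
    "crop",
    "paste",
]


def _check_geometry(data: np.ndarray, spacing, origin) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D data")
    if len(spacing) != 3 or len(origin) != 3:
        raise ValueError("spacing and origin must be length-3")
    sp = np.asarray(spacing, dtype=float)
    if not np.all(np.isfinite(sp)) or np.any(sp <= 0):
        raise ValueError(f"spacing must be positive and finite, got {tuple(spacing)}")


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing (mm) and origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        _check_geometry(self.data, self.spacing, self.origin)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())

    def same_geometry(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class LabelMask(Volume):
    """A 3D integer grid on the same geometry as :class:`Volume`.

    Value 0 is background; value ``k >= 1`` is structure ``k``.
    """

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(self.data == np.round(self.data)):
                raise ValueError("label mask requires integer values")
            self.data = self.data.astype(np.int32)
        if self.data.size and self.data.min() < 0:
            raise ValueError("label values must be non-negative")
        super().__post_init__()

    def labels(self) -> list[int]:
        """Sorted structure labels present (excluding background)."""
        vals = np.unique(self.data)
        return [int(v) for v in vals if v > 0]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned half-open voxel-index box ``[lo, hi)``."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "lo", tuple(int(v) for v in self.lo))
        object.__setattr__(self, "hi", tuple(int(v) for v in self.hi))
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate box lo={self.lo} hi={self.hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    def volume(self) -> int:
        return int(np.prod(self.shape))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def clamp(self, shape) -> "BoundingBox":
        lo = tuple(min(max(l, 0), s) for l, s in zip(self.lo, shape))
        hi = tuple(min(max(h, 0), s) for h, s in zip(self.hi, shape))
        if any(h <= l for l, h in zip(lo, hi)):
            raise ValueError(f"box {self.lo}..{self.hi} does not intersect grid {tuple(shape)}")
        return BoundingBox(lo, hi)

    def expand(self, margin_vox) -> "BoundingBox":
        m = tuple(int(v) for v in margin_vox)
        if any(v < 0 for v in m):
            raise ValueError("margin must be non-negative")
        return BoundingBox(
            tuple(l - v for l, v in zip(self.lo, m)),
            tuple(h + v for h, v in zip(self.hi, m)),
        )

    def contains(self, other: "BoundingBox") -> bool:
        return all(sl <= ol and oh <= sh for sl, ol, oh, sh in zip(self.lo, other.lo, other.hi, self.hi))


@dataclass(frozen=True)
class NormalizationSpec:
    """Intensity normalization to [-1, 1].

    ``ct_window`` mode maps ``(x - window_level) / (window_width / 2)`` and
    clips to [-1, 1]; this is the fixed z-score used for quantitative CT.
    ``mri_percentile`` mode clips to the [lower_pct, upper_pct] intensity
    band, standardizes by the band's mean and SD, then clips to [-1, 1].
    """

    mode: str = "ct_window"
    window_level: float = 40.0
    window_width: float = 400.0
    lower_pct: float = 0.5
    upper_pct: float = 99.5

    def __post_init__(self):
        if self.mode not in ("ct_window", "mri_percentile"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        if self.window_width <= 0:
            raise ValueError("window_width must be > 0")
        if not (0 <= self.lower_pct < self.upper_pct <= 100):
            raise ValueError("require 0 <= lower_pct < upper_pct <= 100")


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path) -> Volume:
    """Read a 3D NIfTI file as a :class:`Volume` (or :class:`LabelMask` if integer-typed)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume in {path}, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any((not np.isfinite(z)) or z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing in {path}: {zooms}")
    affine = img.affine
    rot = affine[:3, :3]
    # reject oblique geometry; accept axis-aligned affines of either sign
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > 1e-3 * max(zooms):
        raise ValueError(f"oblique (non-axis-aligned) geometry in {path} is not supported")
    origin = tuple(float(v) for v in affine[:3, 3])
    if np.issubdtype(data.dtype, np.integer):
        return LabelMask(data.astype(np.int32), tuple(float(z) for z in zooms), origin)
    return Volume(data.astype(np.float32), tuple(float(z) for z in zooms), origin)


def write_volume(v: Volume, path):
    """Write a volume or label mask to NIfTI; labels are stored as unsigned integers."""
    affine = np.diag(list(v.spacing) + [1.0]).astype(float)
    affine[:3, 3] = v.origin
    if isinstance(v, LabelMask):
        data = v.data.astype(np.uint16)
    else:
        data = v.data.astype(np.float32)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Resampling


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def _output_shape(shape, spacing, target_spacing):
    out = _round_half_up(np.asarray(shape) * np.asarray(spacing) / np.asarray(target_spacing))
    return tuple(int(max(1, n)) for n in out)


def resample(v: Volume, target_spacing, method: str = "nearest") -> Volume:
    """Resample to ``target_spacing`` (mm), preserving the origin.

    ``method`` is ``"nearest"`` or ``"linear"``.  Label masks may only be
    resampled with nearest-neighbour interpolation: linear interpolation of
    integer labels would synthesize classes that do not exist.
    """
    ts = tuple(float(s) for s in target_spacing)
    if any((not math.isfinite(s)) or s <= 0 for s in ts):
        raise ValueError(f"target spacing must be positive, got {ts}")
    if method not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation method {method!r}")
    is_mask = isinstance(v, LabelMask)
    if is_mask and method != "nearest":
        raise ValueError("label masks must be resampled with nearest-neighbour interpolation")

    if all(abs(t - s) < 1e-12 for t, s in zip(ts, v.spacing)):
        return replace(v, data=v.data.copy(), spacing=ts)  # exact identity

    out_shape = _output_shape(v.shape, v.spacing, ts)
    # fractional source index for each output index, per axis
    axes_idx = [
        np.arange(n) * (ts[a] / v.spacing[a]) for a, n in enumerate(out_shape)
    ]
    if method == "nearest":
        idx = [np.clip(_round_half_up(ax), 0, v.shape[a] - 1) for a, ax in enumerate(axes_idx)]
        out = v.data[np.ix_(*idx)]
    else:
        coords = np.meshgrid(*axes_idx, indexing="ij")
        out = ndimage.map_coordinates(v.data, coords, order=1, mode="nearest")
    cls = LabelMask if is_mask else Volume
    return cls(out, ts, v.origin)


def resample_to_shape(data: np.ndarray, out_shape, method: str = "nearest") -> np.ndarray:
    """Resample a raw 3D array to an exact output shape (index-ratio mapping).

    Used when mapping a fine-grid segmentation back onto the raw grid, where
    the target shape (the bounding-box shape) is prescribed and must be hit
    exactly regardless of spacing-ratio rounding.
    """
    in_shape = data.shape
    axes_idx = [
        np.arange(n) * (in_shape[a] / n) for a, n in enumerate(out_shape)
    ]
    if method == "nearest":
        idx = [np.clip(_round_half_up(ax), 0, in_shape[a] - 1) for a, ax in enumerate(axes_idx)]
        return data[np.ix_(*idx)]
    coords = np.meshgrid(*axes_idx, indexing="ij")
    return ndimage.map_coordinates(data.astype(np.float32), coords, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# Intensity normalization


def normalize_intensity(v: Volume, spec: NormalizationSpec = NormalizationSpec()) -> Volume:
    """Normalize intensities to [-1, 1] per the configured mode.

    CT: ``clip((x - level) / (width/2), -1, 1)``.  MRI: percentile z-score —
    clip to the [lower_pct, upper_pct] band, standardize by band mean/SD,
    clip to [-1, 1].  Both maps are monotone non-decreasing in the input.
    """
    x = v.data.astype(np.float32)
    if spec.mode == "ct_window":
        out = (x - spec.window_level) / (spec.window_width / 2.0)
    else:
        lo, hi = np.percentile(x, [spec.lower_pct, spec.upper_pct])
        band = np.clip(x, lo, hi)
        sd = float(band.std())
        if sd <= 0:
            raise ValueError("degenerate MRI intensity band (zero spread)")
        out = (band - float(band.mean())) / sd
    out = np.clip(out, -1.0, 1.0)
    return Volume(out.astype(np.float32), v.spacing, v.origin)


# ---------------------------------------------------------------------------
# Boxes, crop, paste


def bounding_box_of(m: LabelMask, label: int, margin_mm=(0.0, 0.0, 0.0)) -> BoundingBox:
    """Tightest box containing ``mask == label``, expanded by ``margin_mm`` and clamped.

    The margin is converted to voxels as ``ceil(margin_mm / spacing)`` per side.
    Raises ``ValueError`` if the label is absent (coarse-stage detection failure).
    """
    where = m.data == int(label)
    if not where.any():
        raise ValueError(f"empty structure: label {label} not present in mask")
    lo, hi = [], []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        prof = where.any(axis=other)
        nz = np.flatnonzero(prof)
        lo.append(int(nz[0]))
        hi.append(int(nz[-1]) + 1)
    margin_vox = [int(math.ceil(float(mm) / m.spacing[a])) for a, mm in enumerate(margin_mm)]
    return BoundingBox(lo, hi).expand(margin_vox).clamp(m.shape)


def crop(v: Volume, box: BoundingBox) -> Volume:
    """Crop to ``box`` (must lie within the grid); origin shifts by ``lo * spacing``."""
    box = box.clamp(v.shape)
    out = v.data[box.slices()].copy()
    origin = tuple(o + l * s for o, l, s in zip(v.origin, box.lo, v.spacing))
    cls = LabelMask if isinstance(v, LabelMask) else Volume
    return cls(out, v.spacing, origin)


def paste(canvas: Volume, patch_data: np.ndarray, box: BoundingBox) -> Volume:
    """Write ``patch_data`` (shaped like ``box``) into a copy of ``canvas`` at ``box``."""
    if tuple(patch_data.shape) != box.shape:
        raise ValueError(f"patch shape {patch_data.shape} != box shape {box.shape}")
    out = canvas.copy()
    out.data[box.slices()] = patch_data
    return out
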