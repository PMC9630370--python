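"""Synthetic CT-like phantoms with known ellipsoid geometry.

A phantom is a body ellipsoid (soft-tissue intensity) embedded in an air-like
background, containing one or more "organ" ellipsoids with distinct mean
intensities, plus additive Gaussian noise.  Closed-form ellipsoid membership
gives every downstream test an analytic oracle (volumes, centroids, bounding
boxes), which is the reason ellipsoids are used instead of meshes.

Intensities loosely mimic non-contrast CT: background -1000 (air), body ~40
(soft tissue), organs 100-300, so the default CT window preset
(level 40, width 400) is exercised as-is.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .volume import LabelMask, Volume, write_volume

__all__ = ["Ellipsoid", "PhantomSpec", "generate_phantom", "generate_dataset", "default_spec"]


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in physical coordinates (mm)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    intensity: float

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")

    def contains_ellipsoid(self, inner: "Ellipsoid") -> bool:
        """Conservative analytic containment test.

        Any point of the inner ellipsoid is ``c_in + a_in ∘ u`` with |u| = 1;
        in the outer ellipsoid's normalized frame its norm is bounded by
        ``|(c_in - c_out)/a_out| + max_i(a_in_i / a_out_i)``.  Bound <= 1 is
        sufficient for containment.
        """
        d = np.asarray(inner.center) - np.asarray(self.center)
        a_out = np.asarray(self.semi_axes)
        a_in = np.asarray(inner.semi_axes)
        return float(np.linalg.norm(d / a_out) + np.max(a_in / a_out)) <= 1.0

    def membership(self, coords) -> np.ndarray:
        """Boolean grid of voxels inside the ellipsoid; ``coords`` = (X, Y, Z) mm grids."""
        q = np.zeros(coords[0].shape, dtype=np.float64)
        for x, c, a in zip(coords, self.center, self.semi_axes):
            q += ((x - c) / a) ** 2
        return q <= 1.0

    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic case.

    Organ labels must be contiguous 1..K; organs must lie inside the body
    ellipsoid (checked analytically).  On overlap, later organs win.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    body: Ellipsoid = Ellipsoid((32.0, 32.0, 32.0), (26.0, 26.0, 26.0), 40.0)
    organs: tuple[tuple[int, Ellipsoid], ...] = (
        (1, Ellipsoid((36.0, 30.0, 32.0), (10.0, 12.0, 9.0), 200.0)),
    )
    background_intensity: float = -1000.0
    noise_sd: float = 15.0
    seed: int = 0

    def __post_init__(self):
        labels = [lab for lab, _ in self.organs]
        if labels != list(range(1, len(labels) + 1)):
            raise ValueError(f"organ labels must be contiguous 1..K, got {labels}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for lab, organ in self.organs:
            if not self.body.contains_ellipsoid(organ):
                raise ValueError(f"organ {lab} is not contained in the body ellipsoid")

    @property
    def n_labels(self) -> int:
        return len(self.organs)

    def to_dict(self) -> dict:
        return asdict(self)


def _coords(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMask]:
    """Render a spec into an (image, label) pair.  Identical specs give
    bit-identical outputs: all noise comes from a generator seeded with
    ``spec.seed`` and no global state is touched."""
    coords = _coords(spec.shape, spec.spacing)
    image = np.full(spec.shape, spec.background_intensity, dtype=np.float64)
    labels = np.zeros(spec.shape, dtype=np.int32)

    body = spec.body.membership(coords)
    image[body] = spec.body.intensity
    for lab, organ in spec.organs:  # later organs override earlier on overlap
        inside = organ.membership(coords)
        image[inside] = organ.intensity
        labels[inside] = lab

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    vol = Volume(image.astype(np.float32), spec.spacing)
    mask = LabelMask(labels, spec.spacing)
    return vol, mask


def default_spec(**overrides) -> PhantomSpec:
    """The stock single-organ phantom used throughout the tests and benchmark."""
    return PhantomSpec(**overrides)


def _jitter_spec(base: PhantomSpec, rng: np.random.Generator,
                 semi_axis_frac: float, center_mm: float, seed: int) -> PhantomSpec:
    organs = []
    for lab, organ in base.organs:
        axes = tuple(
            a * (1.0 + rng.uniform(-semi_axis_frac, semi_axis_frac))
            for a in organ.semi_axes
        )
        center = tuple(
            c + rng.uniform(-center_mm, center_mm) for c in organ.center
        )
        organs.append((lab, Ellipsoid(center, axes, organ.intensity)))
    return PhantomSpec(
        shape=base.shape, spacing=base.spacing, body=base.body,
        organs=tuple(organs), background_intensity=base.background_intensity,
        noise_sd=base.noise_sd, seed=seed,
    )


def generate_dataset(
    n_cases: int,
    out_dir,
    base_spec: PhantomSpec | None = None,
    semi_axis_jitter: float = 0.2,
    center_jitter_mm: float = 4.0,
    seed: int = 0,
    max_retries: int = 50,
) -> list[Path]:
    """Write ``n_cases`` jittered image/label NIfTI pairs plus a manifest.

    Per-case organ geometry is perturbed by up to ``semi_axis_jitter``
    (fractional) and ``center_jitter_mm`` (mm); draws violating body
    containment are rejected and retried up to ``max_retries`` times.
    Fully reproducible from ``seed``.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    base = base_spec if base_spec is not None else default_spec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    case_dirs = []
    manifest = {"seed": seed, "n_cases": n_cases, "cases": [],
                "labels": list(range(1, base.n_labels + 1)),
                "base_spec": base.to_dict()}
    for i in range(n_cases):
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = None
        if semi_axis_jitter == 0 and center_jitter_mm == 0:
            spec = PhantomSpec(
                shape=base.shape, spacing=base.spacing, body=base.body,
                organs=base.organs, background_intensity=base.background_intensity,
                noise_sd=base.noise_sd, seed=base.seed,
            )
        else:
            for _ in range(max_retries):
                try:
                    spec = _jitter_spec(base, rng, semi_axis_jitter, center_jitter_mm, case_seed)
                    break
                except ValueError:
                    continue
            if spec is None:
                raise RuntimeError(
                    f"could not draw a contained organ geometry in {max_retries} tries; "
                    "reduce the jitter ranges"
                )
        image, mask = generate_phantom(spec)
        case_dir = out_dir / f"case_{i:04d}"
        case_dir.mkdir(exist_ok=True)
        write_volume(image, case_dir / "image.nii.gz")
        write_volume(mask, case_dir / "label.nii.gz")
        manifest["cases"].append({"id": f"case_{i:04d}", "seed": spec.seed,
                                  "spec": spec.to_dict()})
        case_dirs.append(case_dir)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return case_dirs
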