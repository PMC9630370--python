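# Methods

This note documents the models and procedures implemented in `oarseg`, the
defaults and the reasoning behind them, what the synthetic phantoms do and do
not establish, and the numerical conventions a maintainer needs to know.

## Geometry and preprocessing

A `Volume` is a 3D scalar grid with voxel spacing (mm) and an origin; the
physical position of voxel `(i,j,k)` is `origin + (i·sx, j·sy, k·sz)`.
Geometry is strictly axis-aligned: direction matrices are out of scope and
oblique NIfTI affines are rejected at read time. Voxel indexing is 0-based
and bounding boxes are half-open `[lo, hi)`, so crop/paste compose without
off-by-one corrections.

**Resampling.** Output shape under a spacing change is
`round(shape·spacing/target)` with a floor of one voxel per axis; "round" is
`floor(x+0.5)` everywhere (including the nearest-neighbour source-index map)
to avoid platform- and library-dependent half-even behaviour. Label masks
are only ever resampled with nearest neighbour: linear interpolation of
integer labels would synthesize classes that do not exist. (A probabilistic
one-hot-then-argmax path would be a legitimate alternative but is an
uncontrolled extension; it is deliberately not implemented.) Images use
nearest neighbour at the coarse stage and for anisotropic inputs at the fine
stage, trilinear otherwise.

**Intensity normalization.** CT intensities are quantitative, so the map is
affine: `clip((x − level)/(width/2), −1, 1)`. The generic default window
(level 40, width 400) covers soft tissue on non-contrast CT; per-structure
presets belong in the run config. For MRI, where intensities are relative,
the percentile z-score is used: clip to the `[0.5, 99.5]` percentile band,
standardize by the band's mean and SD, clip to `[−1, 1]`. Both maps are
monotone, and everything downstream (padding value −1, foreground threshold
for global sampling) assumes the `[−1, 1]` range.

## The numerical engine

No tensor-autodiff framework is a dependency of this package; the networks
run on `oarseg.autodiff`, a small reverse-mode engine over numpy with exactly
the primitives needed: broadcasting arithmetic, reductions, ReLU/exp/log/
clip, channel concatenation and slicing, and three convolution forms —
same-padded stride-1 conv (kernels 1 and 3), kernel-2/stride-2 down-conv,
and its transposed counterpart. Restricting convolutions to these cases
makes every forward/backward pass a reshape plus one einsum/tensordot, which
is fast enough on one CPU at the patch sizes used here. Every primitive and
every loss is pinned by central finite-difference tests (relative error
< 1e-4 on 4³ grids; primitives < 1e-6).

## VB-Net

The backbone is an encoder–decoder at `levels` resolutions below the input:

* input block: 3³ convolution → instance norm → ReLU at `base_channels`;
* per encoder level: kernel-2/stride-2 convolution (norm + ReLU) doubling
  the channel count (capped at 16× base), then a configurable number of
  bottleneck residual blocks (1³ reduce to half channels → 3³ → 1³ restore,
  residual addition);
* symmetric decoder with kernel-2/stride-2 transposed convolutions and
  additive skip connections at every level, mirrored bottleneck counts;
* output block: 1³ convolution to per-class scores; probabilities are an
  explicit softmax at the API boundary and losses consume probabilities.

Channel widths, kernel sizes, and normalization are package choices: channel
doubling follows the V-Net lineage; instance norm suits batch sizes as small
as 2; He-normal initialization is seeded so that two builds from one spec
are bit-identical. Patch sides must be divisible by `2^levels`
(`2^(levels+1)` with the adaptive module) so all down/up samplings are
exact — the production patch default is 96³; for large-organ work the
nearest valid large patch is 192³.

The **adaptive input module** wraps the backbone with one learned stride-2
convolution (in_channels → in_channels) before it and one learned stride-2
transposed convolution (classes → classes) after it. The external shape
contract is unchanged, the backbone sees half resolution (double receptive
field in input voxels), and the parameter count exceeds the plain backbone
by exactly those two layers — a property the tests pin.

## Losses

With smoothed soft Dice `d(p,t) = (2Σpt + ε)/(Σp + Σt + ε)`, `ε = 1e-5`
added to numerator and denominator:

* `dice_loss_3d = 1 − d` over the volume;
* `dice_loss_2d_slice = 1 − d` over one slice; an empty pred/target slice
  has `d = 1`, so vacuous slices contribute nothing;
* `adaptive_slice_weight = 1 − d²`: 0 for perfect slices, 1 for failed ones;
* `adaptive_loss = λ₁·loss₃D + λ₂·Σᵢ (1−dᵢ²)·loss₂Dⁱ` with λ₁ = 0.7,
  λ₂ = 0.3, summed (not averaged) over slices along the superior–inferior
  axis; an `average_slices` switch exists but is off by default;
* `boundary_dice_loss`: Dice restricted to the band
  `dilate(t, w) ∧ ¬erode(t, w)` (default width 2 voxels). "Boundary Dice"
  has no single canonical formula; the band-masked construction is this
  package's declared interpretation. A target with no boundary yields 0
  with a warning;
* `focal_loss = mean(−α(1−p_t)^γ log p_t)` with clamping at 1e-7.

The adaptive weights are kept on the differentiation tape (gradient flows
through `1 − d²`) rather than treated as frozen per-step constants. The
frozen variant makes each step a convex combination of slice losses, but
then the reported gradient is that of a surrogate, and finite-difference
verification of the actual function becomes ill-posed. With weights on the
tape the implemented loss is exactly the function whose gradient the engine
returns; the optimum (prediction = target) and the bound
`adaptive_loss ≥ λ₁·dice_loss_3d` (weights stay in `[0,1]`) are unchanged.

## Training

Patches are cropped around random centre points: *global* sampling draws
centres uniformly over voxels with normalized intensity above a threshold
(default −0.95, i.e. anywhere inside the body) and is the coarse-stage
default; *mask* sampling draws centres inside the labelled region and is the
fine-stage default; `both` mixes 50/50. Out-of-grid patch voxels are padded
with −1 (image) and 0 (labels). Augmentation applies one joint spatial
transform to image and labels (rotations ±10°, scale 0.9–1.1, axis flips,
shifts ±5 voxels; nearest neighbour for labels) plus image-only Gaussian
noise (sd 0.02); ranges are package defaults since only the transform
families are standard.

Optimization is Adam, betas (0.9, 0.999), with "decay 1e-4" read as
*decoupled weight decay* (the conventional reading next to a separate LR
schedule; "momentum 0.9" is folded into β₁). The step LR schedule starts at
1e-4 with default factor 0.1 every 250 epochs. An epoch is a fixed number of
sampled batches per case (default 4) — patch sampling has no natural epoch.
10% of cases (at least one) form the validation split; training stops when
the validation loss has not improved (strict decrease beyond 1e-6) for 5
consecutive epochs, and the checkpoint keeps the best-validation parameters
together with every config object. Watching *validation* rather than
training loss is a deliberate choice where either reading is defensible.

## Cascade inference

`coarse_localize` resamples to the coarse spacing (nearest), normalizes,
predicts with sliding windows, takes the argmax label's bounding box, maps
the corners back to original voxel coordinates by the spacing ratio
(floor/ceil outward), expands by the margin, and clamps. A coarse miss falls
back to the whole-image box with a logged warning (strict mode raises
instead): clinical-style robustness beats aborting. `fine_segment` crops,
resamples to the fine spacing, normalizes, optionally stacks attention
channels, predicts, argmaxes, maps the labels back to the raw grid by an
exact shape-ratio nearest map, and pastes into a zero canvas — so voxels
outside the box are structurally zero. Overlapping window probabilities are
combined by uniform averaging (no Gaussian weighting): the simplest contract
that keeps per-voxel probabilities normalized.

Attention channels: the OAR map is the binary union of supplied OAR masks on
the fine crop grid (a probabilistic or subset variant would also be faithful;
binary union is the minimal reading and subsets are selectable by passing
fewer masks). The boundary map encodes the superior–inferior extent of the
coarse target segmentation as a slice indicator — 1 between the lowest and
highest occupied slices, 0 outside — i.e. the prior that target volumes fail
at their upper/lower boundaries.

Post-processing is per-label 26-connected component analysis: keep the
largest component (organ tasks) or remove components below `min_cc_voxels`
(default 27 ≈ 3³ at 1 mm; tumour tasks). It never adds voxels and is
idempotent.

## Phantoms and the desk-scale benchmark

The phantom generator renders a body ellipsoid (soft-tissue intensity ~40)
in an air-like background (−1000) with organ ellipsoids (100–300) and
additive Gaussian noise (default sd 15), all in physical coordinates, from a
seeded generator with no global state. Ellipsoids are used *because* they
admit closed-form membership: voxel counts, centroids, and bounding boxes
all have analytic oracles. Overlapping organs resolve by list order (later
wins). Datasets jitter organ semi-axes (±20%) and centres (±4 mm) with
rejection of draws that leave the body, so case difficulty varies while
containment is guaranteed.

The benchmark (`oarseg.benchmark`) trains 2-level, 4-channel VB-Nets on 15
of 20 phantoms (64³ at 1 mm) — the coarse stage at 4 mm with 16³ patches
(a 5 mm grid would give 13³, not divisible by the tiny network's
down-sampling chain), the fine stage at 1 mm with 24³ mask-sampled
patches — and evaluates the cascade on the 5 held-out cases. Short runs use
lr 3e-3; the production schedule (1e-4, 1000 epochs) is kept as the config
default. These problem sizes are the package's chosen desk-scale study
conditions; they hold the end-to-end run to a few minutes on one CPU.

**What passing proves and what it does not.** Phantoms have near-constant
class intensities, closed convex shapes, and stationary Gaussian noise, so a
held-out Dice of ~0.97 shows the pipeline is *correctly wired* (geometry,
sampling, loss, optimization, cascade bookkeeping), not that it reaches
clinical accuracy: real CT has texture, low-contrast boundaries, anatomy
far from ellipsoidal, and annotation ambiguity. The single-stage comparison
(same fine model slid over the whole image, same patch budget) isolates the
localization benefit; its collapse to Dice ~0.14 here partly reflects that a
mask-sampled model never sees background context — which is itself the
argument for the cascade design, not an artefact.

## Numerical conventions and degenerate inputs

* Dice of two empty masks is defined as 1 (evaluation); the smoothed losses
  give empty slices loss 0 and weight 0.
* Nearest resampling at the identity spacing short-circuits to a copy, so
  the identity is bitwise.
* `largest-component` ties follow the first-encountered component
  (scipy label order); tests only pin the exact voxel set when the largest
  component is unique.
* Sampling, augmentation, initialization, and training consume only local
  `numpy` generators seeded from the configs, so fixed-seed runs are
  bit-identical in single-threaded execution.

## Known limitations

* No DICOM / DICOM-RT I/O, no direction-cosine geometry, no 4D data.
* The attention-steered fine model is exercised with oracle models and
  shape-level tests; the desk-scale benchmark trains the plain
  single-channel cascade.
* The engine is CPU-only and unbatched beyond the mini-batch dimension;
  production-scale 96³/192³ training is out of reach by design.
* Surface-distance metrics (Hausdorff) and statistical method comparison
  are out of scope.
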