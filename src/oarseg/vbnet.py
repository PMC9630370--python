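"""VB-Net: a V-Net-style 3D encoder-decoder with bottleneck residual blocks.

The network is built from a declarative :class:`NetworkSpec` so that a
checkpoint can always be reconstructed without guessing the architecture.
Structure:

* input block: same-padded 3x3x3 convolution + instance norm + ReLU;
* ``levels`` encoder stages, each a kernel-2/stride-2 down-convolution
  followed by a configurable number of bottleneck residual blocks
  (1x1x1 reduce -> 3x3x3 -> 1x1x1 restore, residual addition);
* symmetric decoder stages with kernel-2/stride-2 transposed convolutions
  and additive skip connections at every resolution level;
* output block: 1x1x1 convolution to per-class scores.

Channel widths start at ``base_channels`` and double per level, capped at
16x base.  The adaptive-input variant wraps the backbone with one learned
stride-2 convolution before it and one learned stride-2 transposed
convolution after it, doubling the backbone's receptive field in input
voxels while keeping the external shape contract unchanged — the mechanism
used for very large structures such as whole-body skin.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .autodiff import Parameter, Tensor, conv3d_same, down_conv, no_grad, up_conv

__all__ = [
    "NetworkSpec",
    "VBNet",
    "AdaptiveVBNet",
    "build_vbnet",
    "build_adaptive_vbnet",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

_CHANNEL_CAP = 16


class NetworkSpec(BaseModel):
    """Declarative description of a (adaptive) VB-Net."""

    model_config = ConfigDict(extra="forbid")

    in_channels: int = Field(1, ge=1)
    out_classes: int = Field(2, ge=2)
    levels: int = Field(2, ge=2)
    base_channels: int = Field(8, ge=1)
    bottlenecks_per_block: list[int] | None = None
    adaptive_input: bool = False

    @model_validator(mode="after")
    def _fill_bottlenecks(self):
        n_blocks = 2 * self.levels
        if self.bottlenecks_per_block is None:
            self.bottlenecks_per_block = [1] * n_blocks
        if len(self.bottlenecks_per_block) != n_blocks:
            raise ValueError(
                f"bottlenecks_per_block must have one entry per down/up block "
                f"({n_blocks} for {self.levels} levels), got {len(self.bottlenecks_per_block)}"
            )
        if any(b < 0 for b in self.bottlenecks_per_block):
            raise ValueError("bottleneck counts must be >= 0")
        return self

    @property
    def divisor(self) -> int:
        return 2 ** (self.levels + 1) if self.adaptive_input else 2**self.levels

    def validate_patch_size(self, patch_size) -> None:
        for s in patch_size:
            if s % self.divisor != 0:
                raise ValueError(
                    f"patch side {s} not divisible by {self.divisor} "
                    f"(levels={self.levels}, adaptive_input={self.adaptive_input})"
                )

    def channels_at(self, level: int) -> int:
        return self.base_channels * min(2**level, _CHANNEL_CAP)


# ---------------------------------------------------------------------------
# Layers


def _he_conv(rng, c_out, c_in, k):
    fan_in = c_in * k**3
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k, k))
    return Parameter(w), Parameter(np.zeros(c_out))


class _Conv:
    def __init__(self, rng, c_in, c_out, k):
        self.w, self.b = _he_conv(rng, c_out, c_in, k)

    def __call__(self, x):
        return conv3d_same(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class _InstanceNorm:
    """Per-sample, per-channel normalization over the spatial axes, with affine."""

    eps = 1e-5

    def __init__(self, channels):
        self.gamma = Parameter(np.ones((1, channels, 1, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1, 1)))

    def __call__(self, x):
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        return xn * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class _ConvINReLU:
    def __init__(self, rng, c_in, c_out, k):
        self.conv = _Conv(rng, c_in, c_out, k)
        self.norm = _InstanceNorm(c_out)

    def __call__(self, x):
        return self.norm(self.conv(x)).relu()

    def parameters(self):
        return self.conv.parameters() + self.norm.parameters()


class _DownConv:
    """Kernel-2 stride-2 strided convolution + norm + ReLU."""

    def __init__(self, rng, c_in, c_out):
        fan_in = c_in * 8
        self.w = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 2, 2, 2)))
        self.b = Parameter(np.zeros(c_out))
        self.norm = _InstanceNorm(c_out)

    def __call__(self, x):
        return self.norm(down_conv(x, self.w, self.b)).relu()

    def parameters(self):
        return [self.w, self.b] + self.norm.parameters()


class _UpConv:
    """Kernel-2 stride-2 transposed convolution + norm + ReLU."""

    def __init__(self, rng, c_in, c_out):
        fan_in = c_in  # each output voxel receives exactly one kernel tap
        self.w = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, c_out, 2, 2, 2)))
        self.b = Parameter(np.zeros(c_out))
        self.norm = _InstanceNorm(c_out)

    def __call__(self, x):
        return self.norm(up_conv(x, self.w, self.b)).relu()

    def parameters(self):
        return [self.w, self.b] + self.norm.parameters()


class _Bottleneck:
    """Residual block: 1x1x1 reduce -> 3x3x3 -> 1x1x1 restore, then add input."""

    def __init__(self, rng, channels):
        mid = max(channels // 2, 1)
        self.reduce = _ConvINReLU(rng, channels, mid, 1)
        self.spatial = _ConvINReLU(rng, mid, mid, 3)
        self.restore = _Conv(rng, mid, channels, 1)
        self.norm = _InstanceNorm(channels)

    def __call__(self, x):
        y = self.norm(self.restore(self.spatial(self.reduce(x))))
        return (y + x).relu()

    def parameters(self):
        return (self.reduce.parameters() + self.spatial.parameters()
                + self.restore.parameters() + self.norm.parameters())


# ---------------------------------------------------------------------------
# Models


class VBNet:
    """Plain VB-Net backbone.  Input (N, C_in, D, H, W) -> scores (N, K, D, H, W)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        if spec.adaptive_input:
            raise ValueError("use AdaptiveVBNet / build_adaptive_vbnet for adaptive specs")
        self.spec = spec
        rng = np.random.default_rng(seed)
        L = spec.levels
        ch = [spec.channels_at(i) for i in range(L + 1)]

        self.stem = _ConvINReLU(rng, spec.in_channels, ch[0], 3)
        self.downs, self.down_blocks = [], []
        for lev in range(L):
            self.downs.append(_DownConv(rng, ch[lev], ch[lev + 1]))
            n_blk = spec.bottlenecks_per_block[lev]
            self.down_blocks.append([_Bottleneck(rng, ch[lev + 1]) for _ in range(n_blk)])
        self.ups, self.up_blocks = [], []
        for i, lev in enumerate(range(L, 0, -1)):
            self.ups.append(_UpConv(rng, ch[lev], ch[lev - 1]))
            n_blk = spec.bottlenecks_per_block[L + i]
            self.up_blocks.append([_Bottleneck(rng, ch[lev - 1]) for _ in range(n_blk)])
        self.head = _Conv(rng, ch[0], spec.out_classes, 1)
        self.feature_shapes: dict[str, tuple] = {}

    def parameters(self):
        params = self.stem.parameters()
        for down, blocks in zip(self.downs, self.down_blocks):
            params += down.parameters()
            for blk in blocks:
                params += blk.parameters()
        for upc, blocks in zip(self.ups, self.up_blocks):
            params += upc.parameters()
            for blk in blocks:
                params += blk.parameters()
        return params + self.head.parameters()

    def __call__(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        self.spec.validate_patch_size(x.shape[2:])
        self.feature_shapes = {"input": x.shape[2:]}
        f = self.stem(x)
        skips = [f]
        for lev, (down, blocks) in enumerate(zip(self.downs, self.down_blocks)):
            f = down(f)
            for blk in blocks:
                f = blk(f)
            self.feature_shapes[f"encoder_level_{lev + 1}"] = f.shape[2:]
            skips.append(f)
        for upc, blocks, skip in zip(self.ups, self.up_blocks, reversed(skips[:-1])):
            f = upc(f) + skip
            for blk in blocks:
                f = blk(f)
        return self.head(f)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-class probabilities for one (C, D, H, W) input, no gradient tape."""
        with no_grad():
            scores = self(x[None])
            probs = scores.softmax(axis=1)
        return probs.data[0]


class AdaptiveVBNet:
    """VB-Net with the adaptive input module.

    A learned stride-2 convolution halves each spatial dimension before the
    backbone; a learned stride-2 transposed convolution restores the class
    score map to full resolution after it.  The two resampling layers are the
    only parameters added relative to the plain backbone.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        if not spec.adaptive_input:
            raise ValueError("spec.adaptive_input must be true")
        backbone_spec = spec.model_copy(update={"adaptive_input": False})
        self.spec = spec
        self.backbone = VBNet(backbone_spec, seed=seed)
        rng = np.random.default_rng(seed + 1)
        cin, k = spec.in_channels, spec.out_classes
        self.pre_w = Parameter(rng.normal(0.0, np.sqrt(2.0 / (cin * 8)), size=(cin, cin, 2, 2, 2)))
        self.pre_b = Parameter(np.zeros(cin))
        self.post_w = Parameter(rng.normal(0.0, np.sqrt(2.0 / k), size=(k, k, 2, 2, 2)))
        self.post_b = Parameter(np.zeros(k))

    def parameters(self):
        return [self.pre_w, self.pre_b, self.post_w, self.post_b] + self.backbone.parameters()

    @property
    def feature_shapes(self):
        return self.backbone.feature_shapes

    def __call__(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        self.spec.validate_patch_size(x.shape[2:])
        f = down_conv(x, self.pre_w, self.pre_b)
        scores = self.backbone(f)
        return up_conv(scores, self.post_w, self.post_b)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        with no_grad():
            probs = self(x[None]).softmax(axis=1)
        return probs.data[0]


def build_vbnet(spec: NetworkSpec, seed: int = 0) -> VBNet:
    """Build a plain VB-Net with deterministic (seeded) initialization."""
    return VBNet(spec, seed=seed)


def build_adaptive_vbnet(spec: NetworkSpec, seed: int = 0) -> AdaptiveVBNet:
    """Build an adaptive-input VB-Net with deterministic initialization."""
    return AdaptiveVBNet(spec, seed=seed)


def build_model(spec: NetworkSpec, seed: int = 0):
    return build_adaptive_vbnet(spec, seed) if spec.adaptive_input else build_vbnet(spec, seed)


def count_parameters(model) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# Checkpoints: parameter archive + the generating NetworkSpec, so inference
# never has to guess the architecture.


def save_checkpoint(model, ckpt_dir, extra: dict | None = None) -> Path:
    ckpt_dir = Path(ckpt_dir)
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    meta = {"network_spec": model.spec.model_dump()}
    if extra:
        meta.update(extra)
    (ckpt_dir / "spec.json").write_text(json.dumps(meta, indent=1))
    arrays = {f"p{i:04d}": p.data for i, p in enumerate(model.parameters())}
    np.savez(ckpt_dir / "params.npz", **arrays)
    return ckpt_dir


def load_checkpoint(ckpt_dir):
    """Rebuild the model from ``spec.json`` and load its parameters.

    Returns ``(model, meta)`` where ``meta`` is the full checkpoint metadata.
    """
    ckpt_dir = Path(ckpt_dir)
    meta = json.loads((ckpt_dir / "spec.json").read_text())
    spec = NetworkSpec(**meta["network_spec"])
    model = build_model(spec)
    with np.load(ckpt_dir / "params.npz") as arc:
        params = model.parameters()
        if len(arc.files) != len(params):
            raise ValueError("checkpoint parameter count does not match the spec")
        for i, p in enumerate(params):
            p.data[...] = arc[f"p{i:04d}"]
    return model, meta
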