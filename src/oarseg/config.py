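"""Run configuration: one file drives both cascade stages.

The schema mirrors the recommended multi-resolution recipe field for field —
coarse stage at 5x5x5 mm with global patch sampling, fine stage at 1x1x1 mm
with mask sampling, 96^3 patches, batch size at least 2, Adam with a step
learning-rate schedule from 1e-4, 1000 epochs with patience-5 convergence on
a 10% validation split.  An empty config file therefore reproduces the stock
recipe; unknown keys and invalid values are rejected with the offending key
named.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .cascade import CascadeConfig
from .losses import LossConfig
from .training import SamplerConfig, TrainConfig
from .vbnet import NetworkSpec

__all__ = ["StageConfig", "RunConfig", "load_config", "dump_config"]


class StageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    target_spacing: tuple[float, float, float] = (5.0, 5.0, 5.0)
    interpolation: str = "nearest"
    network: NetworkSpec = NetworkSpec()
    sampler: SamplerConfig = SamplerConfig()
    loss: LossConfig = LossConfig()
    train: TrainConfig = TrainConfig()

    def model_post_init(self, _ctx):
        if self.interpolation not in ("nearest", "linear"):
            raise ValueError(f"interpolation must be 'nearest' or 'linear', got {self.interpolation!r}")


class CoarseStageConfig(StageConfig):
    """Coarse-stage defaults: 5 mm grid, nearest interpolation, global sampling."""

    target_spacing: tuple[float, float, float] = (5.0, 5.0, 5.0)
    interpolation: str = "nearest"
    sampler: SamplerConfig = SamplerConfig(scheme="global")


class FineStageConfig(StageConfig):
    """Fine-stage defaults: 1 mm grid, linear interpolation, mask sampling."""

    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    interpolation: str = "linear"
    sampler: SamplerConfig = SamplerConfig(scheme="mask")


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    coarse: CoarseStageConfig = CoarseStageConfig()
    fine: FineStageConfig = FineStageConfig()
    cascade: CascadeConfig = CascadeConfig()
    seed: int = 0
    output_dir: str = "runs"


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path) -> RunConfig:
    """Load YAML or JSON; missing fields take the recommended defaults.

    Raises ``ValueError`` naming the offending key on unknown keys or
    constraint violations.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text) if text.strip() else {}
    else:
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    # partial sections inherit the stage defaults field by field
    merged = _deep_merge(RunConfig().model_dump(mode="json"), raw)
    try:
        return RunConfig(**merged)
    except ValidationError as err:
        details = "; ".join(
            f"{'.'.join(str(l) for l in e['loc'])}: {e['msg']}" for e in err.errors()
        )
        raise ValueError(f"invalid config {path}: {details}") from err


def dump_config(cfg: RunConfig, path) -> Path:
    """Write the full effective config (all defaults filled) as YAML."""
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False))
    return path
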