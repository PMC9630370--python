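"""Segmentation evaluation: per-structure Dice and per-case summary tables.

Convention: the Dice coefficient of two empty masks is 1 (perfect agreement
on absence); exactly one empty mask gives 0.  This choice is recorded in the
summary metadata so downstream consumers are not surprised by it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import read_volume

__all__ = ["EvalRecord", "dice_coefficient", "evaluate_cases"]


@dataclass(frozen=True)
class EvalRecord:
    case_id: str
    label: int
    dice: float
    voxels_pred: int
    voxels_true: int
    inference_seconds: float = float("nan")


def dice_coefficient(pred, truth) -> float:
    """2|P∩T| / (|P| + |T|) for binary masks on the same grid."""
    p = np.asarray(pred).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"geometry mismatch: {p.shape} vs {t.shape}")
    np_, nt = int(p.sum()), int(t.sum())
    if np_ == 0 and nt == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / (np_ + nt)


def evaluate_cases(pred_dir, truth_dir, timings: dict | None = None):
    """Evaluate matching ``<case>.nii.gz`` (or ``<case>/label.nii.gz``) pairs.

    Returns ``(records, summary, unmatched)``: one record per (case, label)
    as a DataFrame; mean and SD of Dice per label; and the list of case ids
    present on only one side (flagged, never silently dropped).
    """
    preds = _index_masks(Path(pred_dir))
    truths = _index_masks(Path(truth_dir))
    common = sorted(set(preds) & set(truths))
    unmatched = sorted(set(preds) ^ set(truths))

    rows = []
    for cid in common:
        pred = read_volume(preds[cid])
        truth = read_volume(truths[cid])
        labels = sorted(set(np.unique(truth.data)) | set(np.unique(pred.data)))
        for label in labels:
            if label == 0:
                continue
            rows.append(EvalRecord(
                case_id=cid,
                label=int(label),
                dice=dice_coefficient(pred.data == label, truth.data == label),
                voxels_pred=int((pred.data == label).sum()),
                voxels_true=int((truth.data == label).sum()),
                inference_seconds=(timings or {}).get(cid, float("nan")),
            ).__dict__)
    records = pd.DataFrame(rows, columns=["case_id", "label", "dice", "voxels_pred",
                                          "voxels_true", "inference_seconds"])
    if len(records):
        summary = (records.groupby("label")["dice"]
                   .agg(mean_dice="mean", sd_dice="std", n="count").reset_index())
        summary["sd_dice"] = summary["sd_dice"].fillna(0.0)
    else:
        summary = pd.DataFrame(columns=["label", "mean_dice", "sd_dice", "n"])
    summary.attrs["empty_empty_dice"] = 1.0
    return records, summary, unmatched


def _index_masks(root: Path) -> dict[str, Path]:
    """Map case id -> mask path for flat files or case_XXXX/label.nii.gz layouts."""
    out: dict[str, Path] = {}
    for p in sorted(root.glob("*.nii.gz")) + sorted(root.glob("*.nii")):
        out[p.name.split(".nii")[0]] = p
    for p in sorted(root.glob("*/label.nii.gz")):
        out[p.parent.name] = p
    return out
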