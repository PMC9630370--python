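"""Desk-scale end-to-end experiments on synthetic phantoms.

These drivers exercise the full pipeline — phantom generation, two-stage
training, cascade inference, evaluation — at sizes a single CPU handles in
minutes: 64^3 phantoms at 1 mm, a coarse stage at 4 mm (the 5 mm production
default would leave a 13^3 grid, not divisible by the tiny network's
down-sampling chain), and 2-level VB-Nets with 4 base channels.  The
learning rate is raised to 3e-3 for these short runs; the production default
(1e-4, 1000 epochs) is impractical for a minutes-long budget and the schedule
is otherwise unchanged.

The cascade benchmark also runs the fine model as a whole-image single-stage
segmenter with the same patch size and overlap, the comparison that isolates
what coarse localization buys.
"""

from __future__ import annotations

import numpy as np

from .cascade import (
    CascadeConfig,
    PostprocessConfig,
    postprocess,
    run_cascade,
    sliding_window_predict,
)
from .losses import LossConfig, dice_loss_3d
from .metrics import dice_coefficient
from .phantom import PhantomSpec, _jitter_spec, default_spec, generate_phantom
from .training import SamplerConfig, TrainConfig, split_train_val, train_model
from .vbnet import NetworkSpec, build_vbnet
from .volume import LabelMask, NormalizationSpec, normalize_intensity, resample
from .autodiff import Adam, Tensor

__all__ = ["make_cases", "run_cascade_benchmark", "overfit_single_patch"]

_NORM = NormalizationSpec()  # CT window: level 40, width 400


def make_cases(n_cases: int, seed: int, base_spec: PhantomSpec | None = None,
               semi_axis_jitter: float = 0.2, center_jitter_mm: float = 4.0):
    """Generate ``n_cases`` jittered (image, mask) pairs in memory."""
    base = base_spec if base_spec is not None else default_spec()
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n_cases):
        case_seed = int(rng.integers(0, 2**31 - 1))
        for _ in range(50):
            try:
                spec = _jitter_spec(base, rng, semi_axis_jitter, center_jitter_mm, case_seed)
                break
            except ValueError:
                continue
        cases.append(generate_phantom(spec))
    return cases


def _preprocess(cases, spacing):
    """Resample (nearest, as in the coarse recipe) and window-normalize."""
    out = []
    for image, mask in cases:
        img = resample(image, spacing, method="nearest") if spacing else image
        msk = resample(mask, spacing, method="nearest") if spacing else mask
        out.append((normalize_intensity(img, _NORM), msk))
    return out


def _tiny_net(in_channels: int = 1) -> NetworkSpec:
    return NetworkSpec(in_channels=in_channels, out_classes=2, levels=2, base_channels=4)


def run_cascade_benchmark(seed: int = 0, workdir=None, n_cases: int = 20,
                          n_holdout: int = 5, coarse_epochs: int = 12,
                          fine_epochs: int = 10):
    """Train a tiny two-stage cascade on phantoms and evaluate on held-out cases.

    Returns a dict with per-case and mean Dice for the cascade and for
    whole-image single-stage inference with the same fine model and patch
    budget, plus the count of predicted foreground voxels outside the coarse
    bounding box (structurally zero).
    """
    import tempfile
    from pathlib import Path

    workdir = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="oarseg_bench_"))
    cases = make_cases(n_cases, seed=seed)
    train_cases, test_cases = cases[:-n_holdout], cases[-n_holdout:]

    loss_cfg = LossConfig(components=["dice3d"])
    train_kwargs = dict(lr_initial=3e-3, lr_factor=0.5, lr_interval=8,
                        batches_per_case=1, seed=seed)

    # coarse stage: 4 mm grid, global sampling over the body
    coarse_pre = _preprocess(train_cases, (4.0, 4.0, 4.0))
    tr, va = split_train_val(coarse_pre, val_fraction=0.10, seed=seed)
    coarse_sampler = SamplerConfig(scheme="global", patch_size=(16, 16, 16),
                                   batch_size=4, seed=seed)
    coarse_cfg = TrainConfig(epochs=coarse_epochs, **train_kwargs)
    coarse_dir = workdir / "coarse"
    _, coarse_log = train_model(tr, va, _tiny_net(), loss_cfg, coarse_cfg,
                                coarse_sampler, coarse_dir)
    from .vbnet import load_checkpoint

    coarse_model, _ = load_checkpoint(coarse_dir)

    # fine stage: native 1 mm grid, mask sampling inside the organ
    fine_pre = _preprocess(train_cases, None)
    tr_f, va_f = split_train_val(fine_pre, val_fraction=0.10, seed=seed)
    fine_sampler = SamplerConfig(scheme="mask", patch_size=(24, 24, 24),
                                 batch_size=2, seed=seed)
    fine_cfg = TrainConfig(epochs=fine_epochs, **train_kwargs)
    fine_dir = workdir / "fine"
    _, fine_log = train_model(tr_f, va_f, _tiny_net(), loss_cfg, fine_cfg,
                              fine_sampler, fine_dir)
    fine_model, _ = load_checkpoint(fine_dir)

    cascade_cfg = CascadeConfig(
        coarse_spacing=(4.0, 4.0, 4.0), fine_spacing=(1.0, 1.0, 1.0),
        bbox_margin_mm=(4.0, 4.0, 4.0), coarse_patch_size=(16, 16, 16),
        fine_patch_size=(24, 24, 24), window_overlap=0.25,
        postprocess=PostprocessConfig(keep_largest_cc=True),
    )

    cascade_dice, single_dice, outside_box_voxels, reports = [], [], [], []
    for image, mask in test_cases:
        pred, report = run_cascade(image, coarse_model, fine_model, cascade_cfg)
        cascade_dice.append(dice_coefficient(pred.data == 1, mask.data == 1))
        box = report["box"]
        outside = pred.data.copy()
        outside[tuple(slice(l, h) for l, h in zip(box["lo"], box["hi"]))] = 0
        outside_box_voxels.append(int((outside > 0).sum()))
        reports.append(report)

        # single-stage comparison: same model, same patch size and overlap,
        # sliding over the whole image instead of the localized crop
        norm = normalize_intensity(image, _NORM)
        probs = sliding_window_predict(norm.data[None], fine_model,
                                       cascade_cfg.fine_patch_size,
                                       cascade_cfg.window_overlap)
        single = LabelMask(np.argmax(probs, axis=0).astype(np.int32),
                           image.spacing, image.origin)
        single = postprocess(single, cascade_cfg.postprocess)
        single_dice.append(dice_coefficient(single.data == 1, mask.data == 1))

    return {
        "cascade_dice": cascade_dice,
        "cascade_mean_dice": float(np.mean(cascade_dice)),
        "single_stage_dice": single_dice,
        "single_stage_mean_dice": float(np.mean(single_dice)),
        "outside_box_voxels": outside_box_voxels,
        "coarse_log": coarse_log,
        "fine_log": fine_log,
        "reports": reports,
        "workdir": str(workdir),
    }


def overfit_single_patch(seed: int = 0, steps: int = 200, lr: float = 3e-3):
    """Optimization sanity check: drive a tiny VB-Net to near-perfect training
    Dice on one 32^3 phantom patch.  Returns the Dice trajectory."""
    image, mask = generate_phantom(default_spec(seed=seed))
    norm = normalize_intensity(image, _NORM)
    center = np.argwhere(mask.data == 1).mean(axis=0).astype(int)
    sl = tuple(slice(int(c) - 16, int(c) + 16) for c in center)
    x = norm.data[sl].astype(np.float64)[None, None]
    y = (mask.data[sl] == 1).astype(float)

    model = build_vbnet(_tiny_net(), seed=seed)
    opt = Adam(model.parameters(), lr=lr, weight_decay=0.0)
    history = []
    for step in range(1, steps + 1):
        probs = model(Tensor(x)).softmax(axis=1)
        loss = dice_loss_3d(probs[0, 1], y)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if step % 10 == 0 or step == steps:
            pred = np.argmax(model.predict_proba(x[0]), axis=0)
            history.append((step, dice_coefficient(pred == 1, y > 0.5)))
            if history[-1][1] >= 0.995:
                break
    return {"history": history, "final_dice": history[-1][1], "steps": history[-1][0]}
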