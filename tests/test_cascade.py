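"""Cascade inference: tiling, localization, attention maps, post-processing."""

from collections import deque

import numpy as np
import pytest

from oarseg.cascade import (
    AttentionMaps,
    CascadeConfig,
    PostprocessConfig,
    _window_starts,
    coarse_localize,
    fine_segment,
    make_boundary_attention,
    make_oar_attention,
    postprocess,
    run_cascade,
    sliding_window_predict,
)
from oarseg.metrics import dice_coefficient
from oarseg.vbnet import NetworkSpec
from oarseg.volume import BoundingBox, LabelMask, Volume, bounding_box_of


class IntensityOracleModel:
    """Stand-in model that thresholds the normalized image: the phantom organ
    (window-normalized 0.8) vs body (0.0) is separable at 0.4."""

    def __init__(self, threshold=0.4, in_channels=1):
        self.spec = NetworkSpec(in_channels=in_channels, out_classes=2,
                                levels=2, base_channels=1)
        self.threshold = threshold

    def predict_proba(self, x):
        fg = (x[0] > self.threshold).astype(float)
        return np.stack([1.0 - fg, fg])


class ConstantModel:
    def __init__(self, probs=(0.3, 0.7)):
        self.spec = NetworkSpec(in_channels=1, out_classes=len(probs),
                                levels=2, base_channels=1)
        self.probs = probs

    def predict_proba(self, x):
        out = np.empty((len(self.probs),) + x.shape[1:])
        for k, p in enumerate(self.probs):
            out[k] = p
        return out


def _cascade_cfg(**over):
    base = dict(
        coarse_spacing=(4.0, 4.0, 4.0),
        fine_spacing=(1.0, 1.0, 1.0),
        bbox_margin_mm=(4.0, 4.0, 4.0),
        coarse_patch_size=(16, 16, 16),
        fine_patch_size=(24, 24, 24),
        window_overlap=0.25,
    )
    base.update(over)
    return CascadeConfig(**base)


class TestSlidingWindow:
    def test_window_starts_cover_and_match_tiling_oracle(self):
        for size, patch, overlap in [(20, 8, 0.5), (100, 96, 0.5), (33, 16, 0.0), (8, 8, 0.25)]:
            starts = _window_starts(size, patch, overlap)
            # oracle: fixed-step grid plus a flush final window
            step = max(1, int(round(patch * (1 - overlap))))
            expect = list(range(0, size - patch + 1, step)) if size > patch else [0]
            if expect[-1] != max(size - patch, 0):
                expect.append(size - patch)
            assert starts == expect
            covered = np.zeros(size, dtype=int)
            for s in starts:
                covered[s : s + patch] += 1
            assert covered.min() >= 1

    def test_small_image_single_padded_window(self):
        model = ConstantModel()
        out = sliding_window_predict(np.zeros((1, 5, 6, 7)), model, (8, 8, 8))
        assert out.shape == (2, 5, 6, 7)
        np.testing.assert_allclose(out.sum(axis=0), 1.0)

    def test_overlap_invariance_for_constant_model(self, rng):
        x = rng.normal(size=(1, 20, 20, 20))
        model = ConstantModel()
        a = sliding_window_predict(x, model, (8, 8, 8), window_overlap=0.0)
        b = sliding_window_predict(x, model, (8, 8, 8), window_overlap=0.5)
        np.testing.assert_allclose(a, b)
        np.testing.assert_allclose(a[1], 0.7)

    def test_probabilities_sum_to_one_after_averaging(self, rng):
        x = rng.normal(size=(1, 12, 12, 12))
        out = sliding_window_predict(x, IntensityOracleModel(), (8, 8, 8), 0.5)
        np.testing.assert_allclose(out.sum(axis=0), 1.0)


class TestCoarseLocalize:
    def test_oracle_box_contains_tight_organ_box(self, noisy_phantom):
        image, mask = noisy_phantom
        cfg = _cascade_cfg()
        box = coarse_localize(image, IntensityOracleModel(), cfg)
        true_box = bounding_box_of(mask, 1)
        assert box.contains(true_box)
        # within one coarse voxel (4 mm) + margin (4 mm) of the tight box
        for a in range(3):
            assert true_box.lo[a] - box.lo[a] <= 8
            assert box.hi[a] - true_box.hi[a] <= 8

    def test_margin_monotonicity(self, noisy_phantom):
        image, _ = noisy_phantom
        small = coarse_localize(image, IntensityOracleModel(), _cascade_cfg(bbox_margin_mm=(0, 0, 0)))
        large = coarse_localize(image, IntensityOracleModel(), _cascade_cfg(bbox_margin_mm=(10, 10, 10)))
        assert large.contains(small)

    def test_detection_failure_falls_back_to_whole_image(self, noisy_phantom):
        image, _ = noisy_phantom
        blind = IntensityOracleModel(threshold=10.0)  # never fires
        with pytest.warns(UserWarning, match="detection failure"):
            box = coarse_localize(image, blind, _cascade_cfg())
        assert box.lo == (0, 0, 0) and box.hi == image.shape

    def test_strict_mode_raises_on_detection_failure(self, noisy_phantom):
        image, _ = noisy_phantom
        with pytest.raises(ValueError, match="detection failure"):
            coarse_localize(image, IntensityOracleModel(threshold=10.0),
                            _cascade_cfg(strict_detection=True))


class TestFineSegment:
    def test_oracle_model_recovers_truth_inside_box_and_zero_outside(self, noisy_phantom):
        image, mask = noisy_phantom
        box = bounding_box_of(mask, 1, margin_mm=(4, 4, 4))
        out = fine_segment(image, box, IntensityOracleModel(), _cascade_cfg())
        assert dice_coefficient(out.data == 1, mask.data == 1) > 0.95
        outside = out.data.copy()
        outside[box.slices()] = 0
        assert not outside.any()

    def test_resampling_round_trip_preserves_volume(self, noisy_phantom):
        image, mask = noisy_phantom
        box = bounding_box_of(mask, 1, margin_mm=(4, 4, 4))
        out = fine_segment(image, box, IntensityOracleModel(), _cascade_cfg())
        n_true = (mask.data == 1).sum()
        assert abs(int((out.data == 1).sum()) - n_true) / n_true < 0.05

    def test_channel_count_mismatch_rejected(self, noisy_phantom):
        image, mask = noisy_phantom
        box = bounding_box_of(mask, 1)
        att = AttentionMaps(oar_map=Volume(np.zeros(box.shape, dtype=np.float32)))
        with pytest.raises(ValueError, match="channels"):
            fine_segment(image, box, IntensityOracleModel(in_channels=1), _cascade_cfg(), att)


class TestAttentionMaps:
    def test_no_oars_gives_zero_map(self, noisy_phantom):
        image, _ = noisy_phantom
        box = BoundingBox((10, 10, 10), (30, 30, 30))
        m = make_oar_attention([], box, (20, 20, 20), image)
        assert not m.data.any()

    def test_filled_box_gives_all_one_map(self, noisy_phantom):
        image, _ = noisy_phantom
        box = BoundingBox((10, 10, 10), (30, 30, 30))
        full = LabelMask(np.ones(image.shape, dtype=np.int32), image.spacing, image.origin)
        m = make_oar_attention([full], box, (20, 20, 20), image)
        np.testing.assert_array_equal(m.data, 1.0)

    def test_disjoint_oars_union_counts_add(self, noisy_phantom):
        image, _ = noisy_phantom
        box = BoundingBox((0, 0, 0), (40, 40, 40))
        a = np.zeros(image.shape, dtype=np.int32)
        b = np.zeros(image.shape, dtype=np.int32)
        a[2:6, 2:6, 2:6] = 1
        b[20:26, 20:26, 20:26] = 1
        ma = make_oar_attention([LabelMask(a, image.spacing)], box, (40, 40, 40), image)
        mb = make_oar_attention([LabelMask(b, image.spacing)], box, (40, 40, 40), image)
        both = make_oar_attention(
            [LabelMask(a, image.spacing), LabelMask(b, image.spacing)], box, (40, 40, 40), image
        )
        assert both.data.sum() == ma.data.sum() + mb.data.sum()

    def test_boundary_map_marks_exact_slice_extent(self):
        ref = Volume(np.zeros((40, 40, 40), dtype=np.float32))
        coarse = np.zeros((40, 40, 40), dtype=np.int32)
        coarse[15:25, 15:25, 10:21] = 1  # occupies slices 10..20 along axis 2
        box = BoundingBox((0, 0, 0), (40, 40, 40))
        m = make_boundary_attention(LabelMask(coarse), box, (40, 40, 40), ref, slice_axis=2)
        on = np.flatnonzero(m.data.any(axis=(0, 1)))
        assert on.min() == 10 and on.max() == 20
        # constant within each axial slice
        for k in range(40):
            assert len(np.unique(m.data[:, :, k])) == 1

    def test_empty_coarse_target_rejected(self):
        ref = Volume(np.zeros((8, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError, match="empty"):
            make_boundary_attention(LabelMask(np.zeros((8, 8, 8), dtype=np.int32)),
                                    BoundingBox((0, 0, 0), (8, 8, 8)), (8, 8, 8), ref)


def _flood_fill_components(binary):
    """Independent BFS connected components with 26-neighborhood."""
    visited = np.zeros_like(binary, dtype=bool)
    comps = []
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    for start in map(tuple, np.argwhere(binary)):
        if visited[start]:
            continue
        comp = []
        queue = deque([start])
        visited[start] = True
        while queue:
            v = queue.popleft()
            comp.append(v)
            for off in offsets:
                n = tuple(v[a] + off[a] for a in range(3))
                if all(0 <= n[a] < binary.shape[a] for a in range(3)):
                    if binary[n] and not visited[n]:
                        visited[n] = True
                        queue.append(n)
        comps.append(comp)
    return comps


class TestPostprocess:
    def test_keep_largest_component(self):
        m = np.zeros((12, 12, 12), dtype=np.int32)
        m[1:6, 1:6, 1:5] = 1  # 100 voxels
        m[9:10, 9:10, 3:8] = 1  # 5 voxels
        out = postprocess(LabelMask(m), PostprocessConfig(keep_largest_cc=True))
        assert (out.data > 0).sum() == 100

    def test_single_component_unchanged_and_idempotent(self, rng):
        m = np.zeros((10, 10, 10), dtype=np.int32)
        m[2:7, 2:7, 2:7] = 1
        cfg = PostprocessConfig(keep_largest_cc=True)
        once = postprocess(LabelMask(m), cfg)
        np.testing.assert_array_equal(once.data, m)
        twice = postprocess(once, cfg)
        np.testing.assert_array_equal(twice.data, once.data)

    def test_small_component_removal_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            m = (rng.random((16, 16, 16)) < 0.08).astype(np.int32)
            cfg = PostprocessConfig(keep_largest_cc=False, min_cc_voxels=5)
            out = postprocess(LabelMask(m), cfg)
            expected = np.zeros_like(m)
            for comp in _flood_fill_components(m > 0):
                if len(comp) >= 5:
                    for v in comp:
                        expected[v] = 1
            np.testing.assert_array_equal(out.data, expected)

    def test_largest_component_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            m = (rng.random((14, 14, 14)) < 0.05).astype(np.int32)
            if not m.any():
                continue
            out = postprocess(LabelMask(m), PostprocessConfig(keep_largest_cc=True))
            comps = _flood_fill_components(m > 0)
            biggest = max(comps, key=len)
            expected = np.zeros_like(m)
            for v in biggest:
                expected[v] = 1
            # scipy's argmax tie-break may differ; compare sizes and containment
            assert (out.data > 0).sum() == len(biggest)
            if len([c for c in comps if len(c) == len(biggest)]) == 1:
                np.testing.assert_array_equal(out.data, expected)

    def test_never_adds_voxels_and_empty_passthrough(self, rng):
        m = (rng.random((10, 10, 10)) < 0.1).astype(np.int32)
        out = postprocess(LabelMask(m), PostprocessConfig(keep_largest_cc=False, min_cc_voxels=3))
        assert not (out.data & ~m).any()
        empty = postprocess(LabelMask(np.zeros((4, 4, 4), dtype=np.int32)))
        assert not empty.data.any()


class TestRunCascade:
    def test_oracle_models_at_both_stages_recover_truth(self, noisy_phantom):
        image, mask = noisy_phantom
        pred, report = run_cascade(image, IntensityOracleModel(), IntensityOracleModel(),
                                   _cascade_cfg())
        assert dice_coefficient(pred.data == 1, mask.data == 1) >= 0.95
        assert report["voxels_after_postprocess"] <= report["voxels_before_postprocess"]
        assert report["total_seconds"] > 0

    def test_attention_config_mismatch_fails_before_compute(self, noisy_phantom):
        image, _ = noisy_phantom
        cfg = _cascade_cfg(attention={"use_oar_map": True})
        with pytest.raises(ValueError, match="configuration error"):
            run_cascade(image, IntensityOracleModel(), IntensityOracleModel(in_channels=1), cfg)

    def test_no_foreground_outside_reported_box(self, noisy_phantom):
        image, _ = noisy_phantom
        pred, report = run_cascade(image, IntensityOracleModel(), IntensityOracleModel(),
                                   _cascade_cfg())
        box = report["box"]
        inside = np.zeros(pred.shape, dtype=bool)
        inside[tuple(slice(l, h) for l, h in zip(box["lo"], box["hi"]))] = True
        assert not (pred.data[~inside] > 0).any()

    def test_attention_channels_flow_through_cascade(self, noisy_phantom):
        image, mask = noisy_phantom
        cfg = _cascade_cfg(attention={"use_oar_map": True, "use_boundary_map": True})
        oar = LabelMask((mask.data == 1).astype(np.int32), image.spacing, image.origin)
        model3 = IntensityOracleModel(in_channels=3)
        pred, _ = run_cascade(image, IntensityOracleModel(), model3, cfg,
                              oar_masks=[oar], coarse_target=mask)
        assert dice_coefficient(pred.data == 1, mask.data == 1) >= 0.95
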