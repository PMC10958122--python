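"""Specularity detection and pseudo-ground-truth mask construction."""

import numpy as np
import pytest

from endoinpaint import synthdata
from endoinpaint.specmask import (DetectionParams, PseudoGTSpec,
                                  detect_specular_mask, dilate_mask,
                                  generate_bezier_random_masks,
                                  make_pseudo_mask, make_pseudo_mask_sequence,
                                  structuring_element, translate_mask)


def _clip_with_highlights(seed=11):
    spec = synthdata.SyntheticSceneSpec(
        frame_count=4, frame_size=(64, 64), seed=seed,
        highlight_params=synthdata.HighlightParams(count=3, radius_range=(4, 7)),
    )
    return synthdata.generate_clip(spec)


class TestDetection:
    def test_bright_unsaturated_disc_is_detected_exactly(self):
        # uniform mid-red frame with one pure-white disc: the absolute rule
        # alone defines ground truth
        h = w = 40
        frame = np.full((h, w, 3), [0.45, 0.18, 0.15])
        yy, xx = np.mgrid[0:h, 0:w]
        disc = (yy - 20) ** 2 + (xx - 20) ** 2 <= 36
        frame[disc] = 1.0
        got = detect_specular_mask(frame)
        # the relative rule may widen detection by a ring near the edge;
        # every truly specular pixel must be flagged and nothing far away
        assert (got[disc] == 1).all()
        far = (yy - 20) ** 2 + (xx - 20) ** 2 > 15**2
        assert got[far].sum() == 0

    def test_detection_recovers_synthetic_highlight_cores(self):
        clean, masks, corrupted = _clip_with_highlights()
        got = detect_specular_mask(corrupted[0])
        true = masks[0].astype(bool)
        inter = np.logical_and(got > 0, true).sum()
        # most detected pixels lie on true highlights, and the saturated
        # cores are found
        assert inter / max(got.sum(), 1) > 0.8
        assert inter / true.sum() > 0.3

    def test_small_regions_are_removed(self):
        frame = np.full((32, 32, 3), 0.4)
        frame[5, 5] = 1.0  # single isolated bright pixel < min area 5
        assert detect_specular_mask(frame).sum() == 0

    def test_uniform_frame_yields_empty_mask(self):
        frame = np.full((32, 32, 3), [0.5, 0.25, 0.2])
        assert detect_specular_mask(frame).sum() == 0

    @pytest.mark.parametrize("bad", [dict(relative_ratio_thresh=1.0),
                                     dict(local_window=4),
                                     dict(absolute_intensity_thresh=1.5)])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            DetectionParams(**bad)


class TestStructuringElements:
    def test_diamond_is_l1_ball(self):
        se = structuring_element("diamond", 2)
        yy, xx = np.mgrid[-2:3, -2:3]
        assert np.array_equal(se > 0, np.abs(yy) + np.abs(xx) <= 2)

    def test_ball_is_l2_disc(self):
        se = structuring_element("ball", 3)
        yy, xx = np.mgrid[-3:4, -3:4]
        assert np.array_equal(se > 0, yy**2 + xx**2 <= 9)

    def test_ellipse_axes(self):
        se = structuring_element("ellipse", (5, 3))
        assert se.shape == (7, 11)  # 2b+1 rows, 2a+1 cols
        yy, xx = np.mgrid[-3:4, -5:6]
        assert np.array_equal(se > 0, (xx / 5) ** 2 + (yy / 3) ** 2 <= 1)

    def test_single_pixel_dilation_is_the_element(self):
        m = np.zeros((15, 15), np.uint8)
        m[7, 7] = 1
        out = dilate_mask(m, "ellipse", (5, 3))
        se = structuring_element("ellipse", (5, 3))
        assert np.array_equal(out[4:11, 2:13], se)


class TestTranslate:
    def test_interior_shift(self):
        m = np.zeros((10, 10), np.uint8)
        m[4, 4] = 1
        out = translate_mask(m, 2, -1)  # +2 cols, -1 row
        expect = np.zeros_like(m)
        expect[3, 6] = 1
        assert np.array_equal(out, expect)

    def test_border_crop(self):
        m = np.zeros((6, 6), np.uint8)
        m[0, 5] = 1
        assert translate_mask(m, 1, 0).sum() == 0  # shifted off the frame


class TestPseudoMask:
    def _seg(self):
        m = np.zeros((64, 64), np.uint8)
        yy, xx = np.mgrid[0:64, 0:64]
        m[(yy - 30) ** 2 + (xx - 20) ** 2 <= 16] = 1
        return m

    @pytest.mark.parametrize("variant", ["training", "evaluation"])
    def test_pseudo_mask_avoids_guarded_original(self, variant):
        seg = self._seg()
        spec = PseudoGTSpec(variant=variant)
        pm = make_pseudo_mask(seg, spec)
        guard = dilate_mask(seg, "ball", spec.guard_radius)
        assert pm.sum() > 0
        assert (pm & guard).sum() == 0  # only originally-valid texture covered

    def test_training_variant_oracle(self):
        seg = self._seg()
        spec = PseudoGTSpec(translation=(13, 0), variant="training")
        pm = make_pseudo_mask(seg, spec)
        guard = dilate_mask(seg, "ball", 3)
        expect = translate_mask(dilate_mask(seg, "ellipse", (5, 3)), 13, 0) & ~guard
        assert np.array_equal(pm, expect)

    def test_evaluation_variant_oracle(self):
        seg = self._seg()
        spec = PseudoGTSpec(translation=(13, 0), variant="evaluation")
        pm = make_pseudo_mask(seg, spec)
        guard = dilate_mask(seg, "ball", 3)
        step = translate_mask(seg, 13, 0) & ~guard
        expect = dilate_mask(step, "ellipse", (5, 3)) & ~guard
        assert np.array_equal(pm, expect)

    def test_sequence_uses_one_fixed_translation(self):
        _, masks, _ = _clip_with_highlights()
        pms, (dx, dy) = make_pseudo_mask_sequence(masks, PseudoGTSpec())
        assert (dx, dy) == (13, 0)  # 0.2 * 64 rounded
        for m, pm in zip(masks, pms):
            one = make_pseudo_mask(m, PseudoGTSpec(translation=(dx, dy)))
            assert np.array_equal(pm, one)

    def test_zero_translation_rejected(self):
        with pytest.raises(ValueError):
            PseudoGTSpec(translation=(0, 0))


class TestBezierMasks:
    def test_shapes_and_determinism(self):
        a = generate_bezier_random_masks(6, (64, 64), seed=4)
        b = generate_bezier_random_masks(6, (64, 64), seed=4)
        assert a.shape == (6, 64, 64) and a.dtype == np.uint8
        assert np.array_equal(a, b)
        assert all(m.sum() > 0 for m in a)

    def test_consecutive_frames_overlap(self):
        masks = generate_bezier_random_masks(10, (96, 96), seed=2)
        for t in range(9):
            a, b = masks[t] > 0, masks[t + 1] > 0
            iou = np.logical_and(a, b).sum() / np.logical_or(a, b).sum()
            assert iou >= 0.5  # temporally smooth motion

    def test_different_seeds_differ(self):
        a = generate_bezier_random_masks(3, (64, 64), seed=1)
        b = generate_bezier_random_masks(3, (64, 64), seed=2)
        assert not np.array_equal(a, b)
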