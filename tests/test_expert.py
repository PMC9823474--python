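"""Rule-based pupil detection pipeline."""

import dataclasses
import math

import numpy as np
import pytest

from eyeqc.expert import (
    ESParams,
    PupilDetection,
    classify_frame,
    find_pupil_candidates,
    preprocess,
    scale_params,
    select_pupil,
)
from eyeqc.geometry import EyeLabel
from eyeqc.synth import render_frame


def _disc_mask(side, cx, cy, r):
    Y, X = np.mgrid[0:side, 0:side]
    return (X + 0.5 - cx) ** 2 + (Y + 0.5 - cy) ** 2 <= r ** 2


class TestPreprocess:
    def test_blank_frame_gives_empty_mask(self, default_params):
        mask, ref = preprocess(np.zeros((520, 772), np.uint8), default_params)
        assert not mask.any()
        assert ref.max() == 0

    def test_saturated_frame_gives_empty_mask(self, default_params):
        mask, _ = preprocess(np.full((520, 520), 255, np.uint8), default_params)
        assert not mask.any()

    def test_nothing_beyond_lens_ring(self, default_params):
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 256, size=(520, 772), dtype=np.uint8)
        mask, _ = preprocess(frame, default_params)
        side = default_params.base_side
        Y, X = np.mgrid[0:side, 0:side]
        r2 = (X + 0.5 - side / 2) ** 2 + (Y + 0.5 - side / 2) ** 2
        assert not mask[r2 > default_params.ring_radius ** 2].any()

    def test_clean_pupil_yields_single_component_on_pupil(
        self, clean_spec, clean_frame, default_params
    ):
        from scipy import ndimage as ndi

        mask, _ = preprocess(clean_frame, default_params)
        labeled, n = ndi.label(mask, structure=np.ones((3, 3)))
        assert n == 1
        # oracle: the generator's own pupil ellipse, in cropped coordinates
        cx, cy = clean_spec.pupil_center_cropped()
        a, b = clean_spec.pupil_axes
        Y, X = np.mgrid[0:520, 0:520]
        pupil = ((X + 0.5 - cx) / a) ** 2 + ((Y + 0.5 - cy) / b) ** 2 <= 1.0
        overlap = (mask & pupil).sum()
        assert overlap / pupil.sum() > 0.8
        assert overlap / mask.sum() > 0.8

    def test_wrong_dtype_rejected(self, default_params):
        with pytest.raises(ValueError):
            preprocess(np.zeros((520, 772), np.float64), default_params)
        with pytest.raises(ValueError):
            preprocess(np.zeros((260, 260), np.uint8), default_params)


class TestCandidates:
    def _reference(self, side=520, level=255.0):
        return np.full((side, side), level)

    def test_size_filter(self, default_params):
        ref = self._reference(level=0.0)  # everything maximally dark
        for r, expect in [(10, 0), (55, 1), (170, 0)]:
            mask = _disc_mask(520, 260, 260, r)
            got = find_pupil_candidates(mask, ref, default_params)
            assert len(got) == expect, f"radius {r}"

    def test_darkness_filter(self, default_params):
        mask = _disc_mask(520, 260, 260, 55)
        bright = self._reference(level=240.0)  # darkness 15 < 50 -> rejected
        assert find_pupil_candidates(mask, bright, default_params) == []
        dark = self._reference(level=100.0)  # darkness 155 -> kept
        assert len(find_pupil_candidates(mask, dark, default_params)) == 1

    def test_detection_fields(self, default_params):
        mask = _disc_mask(520, 200, 300, 55)
        det = find_pupil_candidates(mask, self._reference(level=0.0), default_params)[0]
        assert det.center == pytest.approx((200, 300), abs=0.1)
        x0, y0, w, h = det.bounding_box
        assert x0 <= det.center[0] <= x0 + w
        assert y0 <= det.center[1] <= y0 + h
        assert 0.95 < det.circularity <= 1.0
        assert det.area == pytest.approx(math.pi * 55 ** 2, rel=0.02)
        assert det.darkness == pytest.approx(1.0)


class TestSelectPupil:
    def _det(self, **kw):
        base = dict(center=(100, 100), bounding_box=(50, 50, 100, 100),
                    hull=np.zeros((3, 2)), circularity=0.9, darkness=0.5, area=3000.0)
        base.update(kw)
        return PupilDetection(**base)

    def test_empty_gives_none(self):
        assert select_pupil([]) is None

    def test_single_candidate_returned(self):
        d = self._det()
        assert select_pupil([d]) is d
        assert d.score == pytest.approx(3.0)  # all criteria normalize to 1

    def test_bigger_area_wins_all_else_equal(self):
        a = self._det(area=3000.0)
        b = self._det(area=5000.0)
        assert select_pupil([a, b]) is b

    def test_equal_weight_sum(self):
        a = self._det(circularity=1.0, darkness=0.0, area=1000.0)
        b = self._det(circularity=0.0, darkness=1.0, area=2000.0)
        c = self._det(circularity=0.5, darkness=0.9, area=1500.0)
        best = select_pupil([a, b, c])
        # normalized scores: a = 1+0+0, b = 0+1+1, c = 0.5+0.9+0.5
        assert best is b

    def test_tie_breaks_leftmost_topmost(self):
        a = self._det(center=(200, 100))
        b = self._det(center=(100, 100))
        assert select_pupil([a, b]).center == (100, 100)


class TestClassifyFrame:
    def test_blank_frame_closed(self, default_params):
        label, det = classify_frame(np.zeros((520, 772), np.uint8), default_params)
        assert label is EyeLabel.CLOSED and det is None

    def test_clean_centered_correct(self, clean_frame, default_params):
        label, det = classify_frame(clean_frame, default_params)
        assert label is EyeLabel.CORRECT
        assert det is not None
        assert math.hypot(det.center[0] - 260, det.center[1] - 260) < 5

    def test_displaced_pupil_directional(self, clean_spec, default_params):
        spec = dataclasses.replace(clean_spec, pupil_center=(386.0 + 160.0, 260.0))
        label, det = classify_frame(render_frame(spec, 2), default_params)
        assert label is EyeLabel.RIGHT

    def test_squashed_pupil_closed_by_aspect_ratio(self, clean_spec, default_params):
        spec = dataclasses.replace(clean_spec, pupil_axes=(100.0, 38.0))
        label, det = classify_frame(render_frame(spec, 3), default_params)
        assert det is not None and det.aspect_ratio < default_params.aspect_ratio_closed
        assert label is EyeLabel.CLOSED

    def test_total_on_noise_frames(self, default_params):
        rng = np.random.default_rng(1)
        for _ in range(3):
            frame = rng.integers(0, 256, size=(520, 772), dtype=np.uint8)
            label, _ = classify_frame(frame, default_params)
            assert isinstance(label, EyeLabel)

    def test_deterministic(self, clean_frame, default_params):
        l1, d1 = classify_frame(clean_frame, default_params)
        l2, d2 = classify_frame(clean_frame, default_params)
        assert l1 is l2 and d1.center == d2.center and d1.score == d2.score


class TestScaleParams:
    def test_identity_at_base_side(self, default_params):
        assert scale_params(default_params, 520) == default_params

    def test_half_scale(self, default_params):
        p = scale_params(default_params, 260)
        assert p.gaussian_kernel == (11, 5)
        assert p.morph_kernel == 11
        assert p.inscribed_radius_range == (10.0, 75.0)
        assert p.ring_radius == pytest.approx(122.5)
        assert p.mask_threshold == default_params.mask_threshold

    def test_smallest_scale_floors_kernels(self, default_params):
        p = scale_params(default_params, 65)
        assert p.adaptive_block == 3
        assert p.gaussian_kernel[1] >= 3
        assert p.morph_kernel == 3

    def test_nonpositive_rejected(self, default_params):
        with pytest.raises(ValueError):
            scale_params(default_params, 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ESParams(gaussian_kernel=(20, 9))
        with pytest.raises(ValueError):
            ESParams(inscribed_radius_range=(150.0, 20.0))
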