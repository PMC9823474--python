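"""Synthetic frame rendering, ground truth, and dataset generation."""

import dataclasses

import numpy as np
import pytest

from eyeqc.geometry import EyeLabel, LABEL_ORDER, PupilObservation, assign_label
from eyeqc.synth import (
    DatasetProfile,
    GenerationError,
    SceneSpec,
    crop_square,
    generate_dataset,
    generate_frames,
    ground_truth,
    render_frame,
)


class TestRenderFrame:
    def test_deterministic(self, clean_spec):
        spec = dataclasses.replace(clean_spec, noise_sigma=4.0)
        a = render_frame(spec, seed=9)
        b = render_frame(spec, seed=9)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, render_frame(spec, seed=10))

    def test_outside_lens_black_without_noise(self, clean_spec, clean_frame):
        h, w = clean_frame.shape
        Y, X = np.mgrid[0:h, 0:w]
        lx, ly = clean_spec.lens_center
        outside = (X + 0.5 - lx) ** 2 + (Y + 0.5 - ly) ** 2 > clean_spec.lens_radius ** 2
        assert clean_frame[outside].max() == 0

    def test_pupil_darker_than_iris(self, clean_spec, clean_frame):
        cx, cy = map(int, clean_spec.pupil_center)
        assert clean_frame[cy, cx] == clean_spec.pupil_intensity
        ring = clean_frame[cy, cx + int(clean_spec.pupil_axes[0]) + 12]
        assert ring > clean_frame[cy, cx]

    def test_glints_saturated(self, clean_spec, clean_frame):
        assert (clean_frame == 255).sum() >= clean_spec.glint_count

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(pupil_intensity=200, iris_intensity=150)
        with pytest.raises(ValueError):
            SceneSpec(eyelid_coverage=1.5)
        with pytest.raises(ValueError):
            SceneSpec(pupil_center=(760.0, 260.0))  # center outside lens


def mc_visible_fraction(spec, n=200_000, seed=5):
    """Monte-Carlo oracle for the visible pupil-area fraction."""
    from eyeqc.synth import _lid_occluded, _upper_lid_edge

    rng = np.random.default_rng(seed)
    a, b = spec.pupil_axes
    pcx, pcy = spec.pupil_center
    # uniform points in the ellipse by rejection from the bounding box
    x = rng.uniform(-a, a, n)
    y = rng.uniform(-b, b, n)
    keep = (x / a) ** 2 + (y / b) ** 2 <= 1.0
    px, py = pcx + x[keep], pcy + y[keep]
    lx, ly = spec.lens_center
    vis = (px - lx) ** 2 + (py - ly) ** 2 <= spec.lens_radius ** 2
    edge = _upper_lid_edge(spec)
    if edge is not None:
        vis &= ~_lid_occluded(px, py, edge, pcx)
    return vis.mean()


class TestGroundTruth:
    def test_centered_uncovered_is_correct(self, clean_spec):
        gt = ground_truth(clean_spec)
        assert gt.visible_fraction == pytest.approx(1.0)
        assert gt.label is EyeLabel.CORRECT
        assert gt.pupil_center == pytest.approx((260.0, 260.0))

    def test_fully_covered_is_closed(self, clean_spec):
        spec = dataclasses.replace(clean_spec, eyelid_coverage=1.0)
        gt = ground_truth(spec)
        assert gt.visible_fraction <= 0.001
        assert gt.label is EyeLabel.CLOSED

    def test_displaced_pupil_is_directional(self, clean_spec):
        spec = dataclasses.replace(clean_spec, pupil_center=(386.0 + 150.0, 260.0))
        assert ground_truth(spec).label is EyeLabel.RIGHT

    @pytest.mark.parametrize("coverage", [0.1, 0.35, 0.62, 0.9])
    def test_fraction_matches_monte_carlo_oracle(self, clean_spec, coverage):
        spec = dataclasses.replace(clean_spec, eyelid_coverage=coverage)
        gt = ground_truth(spec)
        assert gt.visible_fraction == pytest.approx(1.0 - coverage, abs=5e-3)
        assert gt.visible_fraction == pytest.approx(mc_visible_fraction(spec), abs=5e-3)

    def test_lens_clipping_reduces_visibility(self, clean_spec):
        spec = dataclasses.replace(clean_spec, pupil_center=(386.0 + 200.0, 260.0))
        gt = ground_truth(spec)
        assert gt.visible_fraction < 1.0
        assert gt.visible_fraction == pytest.approx(mc_visible_fraction(spec), abs=5e-3)

    def test_coverage_monotone(self, clean_spec):
        fracs = [
            ground_truth(dataclasses.replace(clean_spec, eyelid_coverage=c)).visible_fraction
            for c in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestSampling:
    def test_labels_self_consistent(self, tiny_suite):
        for _, gt, spec, _ in tiny_suite:
            rederived = assign_label(
                PupilObservation(gt.pupil_center, gt.visible_fraction),
                spec.crop_geometry(),
            )
            assert rederived is gt.label

    def test_class_counts_conserved(self, tiny_suite):
        counts = {}
        for _, gt, _, _ in tiny_suite:
            counts[gt.label] = counts.get(gt.label, 0) + 1
        assert counts == {lab: 4 for lab in LABEL_ORDER}

    def test_reproducible_from_master_seed(self):
        c = {EyeLabel.CORRECT: 2, EyeLabel.UP: 2}
        a = generate_frames(c, seed=123)
        b = generate_frames(c, seed=123)
        for (fa, gta, sa, seeda), (fb, gtb, sb, seedb) in zip(a, b):
            assert np.array_equal(fa, fb)
            assert sa == sb and seeda == seedb and gta == gtb

    def test_infeasible_class_raises(self, monkeypatch):
        import eyeqc.synth as synth

        wrong = synth.GroundTruth((0.0, 0.0), 1.0, EyeLabel.DOWN)
        monkeypatch.setattr(synth, "ground_truth", lambda spec: wrong)
        with pytest.raises(GenerationError, match="correct"):
            synth.sample_scene(EyeLabel.CORRECT, np.random.default_rng(0))


class TestDatasetIO:
    def test_generate_dataset_roundtrip(self, tmp_path):
        counts = {EyeLabel.CORRECT: 3, EyeLabel.CLOSED: 2}
        mf = generate_dataset(counts, tmp_path, seed=11, partition="test")
        assert len(mf) == 5
        assert (mf["label"] == "correct").sum() == 3
        assert (tmp_path / "test_manifest.csv").exists()
        assert (tmp_path / "test_profile.json").exists()
        for rel in mf["path"]:
            assert (tmp_path / rel).exists()

    def test_identical_manifests_for_same_seed(self, tmp_path):
        counts = {EyeLabel.CORRECT: 2, EyeLabel.LEFT: 2}
        generate_dataset(counts, tmp_path / "a", seed=5)
        generate_dataset(counts, tmp_path / "b", seed=5)
        ta = (tmp_path / "a" / "test_manifest.csv").read_text()
        tb = (tmp_path / "b" / "test_manifest.csv").read_text()
        assert ta == tb

    def test_paper_like_profile(self):
        p = DatasetProfile.paper_like()
        assert sum(p.train.values()) == 10_476
        assert sum(p.test.values()) == 4_500
        assert p.train[EyeLabel.DOWN] == 265
        assert all(v == 750 for v in p.test.values())


def test_crop_square_centered():
    f = np.zeros((520, 772), dtype=np.uint8)
    f[:, 126] = 7
    sq = crop_square(f)
    assert sq.shape == (520, 520)
    assert (sq[:, 0] == 7).all()
    assert crop_square(sq) is sq
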