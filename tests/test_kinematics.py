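"""Glottal kinematics: segmentation, GAW, GVG, CQ, configuration labels."""

import numpy as np
import pytest

from glottkit.kinematics import (
    GlottisMaskStack,
    Glottovibrogram,
    classify_configuration,
    closed_quotient_profile,
    compute_gaw,
    compute_gvg,
    fold_displacements,
    segment_glottis,
    summarize_cq,
)
from glottkit.preprocess import HSVSequence
from glottkit.synth import SyntheticSpec, gen_hsv
from conftest import dice

DIMS = (120, 100)
FPS = 20000.0


def make_gvg(width, fps=FPS):
    width = np.asarray(width, dtype=float)
    n = width.shape[0]
    ap = np.linspace(0, 1, n) if n > 1 else np.zeros(1)
    return Glottovibrogram(width, fps, ap)


class TestSegmentGlottis:
    def test_dice_against_truth_masks(self):
        spec = SyntheticSpec(image_dims=DIMS, duration=0.005,
                             configuration="IIb", cq_target=0.5, seed=3)
        seq, truth = gen_hsv(spec)
        masks = segment_glottis(seq)
        gaw_true = truth.masks.sum(axis=(1, 2))
        for t in np.flatnonzero(gaw_true > 0.2 * gaw_true.max()):
            assert dice(masks.masks[t], truth.masks[t]) >= 0.9

    def test_fully_closed_frames_give_empty_masks(self):
        spec = SyntheticSpec(image_dims=DIMS, duration=0.005,
                             configuration="IIb", cq_target=0.6, seed=3)
        seq, truth = gen_hsv(spec)
        masks = segment_glottis(seq)
        truth_empty = truth.masks.sum(axis=(1, 2)) == 0
        assert truth_empty.any()
        measured_area = masks.masks.sum(axis=(1, 2))
        assert np.all(measured_area[truth_empty] == 0)

    def test_bright_glottis_polarity_symmetry(self):
        spec = SyntheticSpec(image_dims=DIMS, duration=0.003,
                             configuration="IIb", cq_target=0.4, seed=5)
        seq, _ = gen_hsv(spec)
        dark = segment_glottis(seq)
        inverted = HSVSequence(1.0 - seq.frames, seq.fps)
        bright = segment_glottis(inverted, bright_glottis=True)
        np.testing.assert_array_equal(dark.masks, bright.masks)

    def test_intensity_rescaling_invariance(self):
        spec = SyntheticSpec(image_dims=DIMS, duration=0.003,
                             configuration="IIb", cq_target=0.4, seed=5)
        seq, _ = gen_hsv(spec)
        a = segment_glottis(seq)
        scaled = HSVSequence(3.7 * seq.frames + 0.2, seq.fps)
        b = segment_glottis(scaled)
        np.testing.assert_array_equal(a.masks, b.masks)


class TestGawGvg:
    def test_empty_masks_give_zero_gaw(self):
        masks = GlottisMaskStack(np.zeros((5, 10, 10), bool), FPS)
        np.testing.assert_array_equal(compute_gaw(masks), np.zeros(5))

    def test_square_mask_counts_pixels(self):
        m = np.zeros((1, 20, 20), bool)
        m[0, 5:15, 5:15] = True
        assert compute_gaw(GlottisMaskStack(m, FPS))[0] == 100

    def test_rectangle_gvg_rows(self):
        m = np.zeros((2, 30, 30), bool)
        m[:, 10:21, 6:14] = True  # rows 10..20 of width 8
        gvg = compute_gvg(GlottisMaskStack(m, FPS))
        assert gvg.width.shape == (11, 2)
        assert np.all(gvg.width == 8)

    def test_gaw_equals_gvg_column_sums(self):
        spec = SyntheticSpec(image_dims=DIMS, duration=0.004, seed=1)
        seq, truth = gen_hsv(spec)
        r0, r1 = truth.glottis_rows
        masks = segment_glottis(seq, roi=(0, r0, DIMS[1], r1 - r0))
        np.testing.assert_array_equal(compute_gaw(masks),
                                      compute_gvg(masks).gaw)

    def test_orientation_flip(self):
        m = np.zeros((1, 30, 30), bool)
        m[0, 10:12, 10:20] = True
        m[0, 12:14, 10:15] = True
        top = compute_gvg(GlottisMaskStack(m, FPS, "top-posterior"))
        bottom = compute_gvg(GlottisMaskStack(m, FPS, "bottom-posterior"))
        np.testing.assert_array_equal(top.width, bottom.width[::-1])

    def test_gaw_period_matches_generator(self):
        from glottkit.signals import VoiceSignal, estimate_f0_autocorr
        spec = SyntheticSpec(image_dims=DIMS, duration=0.02,
                             configuration="IIb", cq_target=0.45, seed=2)
        seq, _ = gen_hsv(spec)
        gaw = compute_gaw(segment_glottis(seq))
        f = estimate_f0_autocorr(VoiceSignal(gaw, FPS, "gaw"),
                                 window_len=0.018)
        assert f == pytest.approx(spec.f_o, rel=0.01)


class TestFoldDisplacements:
    def test_left_plus_right_equals_row_extent(self):
        m = np.zeros((3, 20, 20), bool)
        m[:, 5:15, 8:13] = True
        masks = GlottisMaskStack(m, FPS)
        left, right = fold_displacements(masks)
        assert np.all(left[5:15] + right[5:15] == 5)

    def test_symmetric_gap_mirrors(self):
        spec = SyntheticSpec(image_dims=DIMS, duration=0.004,
                             configuration="IIb", cq_target=0.4, seed=5)
        seq, truth = gen_hsv(spec)
        masks = segment_glottis(seq)
        left, right = fold_displacements(masks)
        assert np.max(np.abs(left - right)) <= 1.0

    def test_static_rectangle_constant_traces(self):
        m = np.zeros((4, 20, 20), bool)
        m[:, 5:15, 8:13] = True
        left, right = fold_displacements(GlottisMaskStack(m, FPS))
        assert np.all(left == left[:, :1])
        assert np.all(right == right[:, :1])


class TestClosedQuotient:
    def test_never_closing_rows_have_zero_cq(self):
        t = np.arange(400)
        width = 5.0 + 3.0 * np.sin(2 * np.pi * 1000.0 * t / FPS)
        gvg = make_gvg(np.tile(width, (10, 1)))
        prof = closed_quotient_profile(gvg, f_o=1000.0)
        np.testing.assert_array_equal(prof.cq, 0.0)

    def test_square_wave_half_duty(self):
        period = 20  # samples at 1000 Hz, fps 20000
        t = np.arange(400)
        width = np.where((t % period) < period // 2, 6.0, 0.0)
        gvg = make_gvg(np.tile(width, (4, 1)))
        prof = closed_quotient_profile(gvg, f_o=FPS / period)
        assert prof.cq[0] == pytest.approx(0.5, abs=1.0 / period)
        assert prof.cycles_used >= 3

    def test_recovery_against_generator_truth(self):
        rng = np.random.default_rng(12)
        targets = tuple(rng.uniform(0.30, 0.73, 72))
        spec = SyntheticSpec(image_dims=DIMS, duration=0.02,
                             configuration="IIb", cq_target=targets, seed=12)
        seq, truth = gen_hsv(spec)
        r0, r1 = truth.glottis_rows
        masks = segment_glottis(seq, roi=(0, r0, DIMS[1], r1 - r0))
        prof = closed_quotient_profile(compute_gvg(masks), f_o=spec.f_o)
        assert prof.cq.size == truth.cq.size
        assert np.max(np.abs(prof.cq - truth.cq)) <= 0.03

    def test_too_few_cycles_rejected(self):
        width = np.tile(5.0 + 3.0 * np.sin(
            2 * np.pi * 1000.0 * np.arange(40) / FPS), (4, 1))
        with pytest.raises(ValueError, match="cycles"):
            closed_quotient_profile(make_gvg(width), f_o=1000.0)

    def test_insufficient_temporal_resolution_rejected(self):
        width = np.tile(5.0 + 3.0 * np.sin(
            2 * np.pi * 1000.0 * np.arange(400) / 5000.0), (4, 1))
        with pytest.raises(ValueError, match="temporal resolution"):
            closed_quotient_profile(make_gvg(width, fps=5000.0), f_o=1000.0)


class TestSummarizeCq:
    def test_constant_profile(self):
        prof = closed_quotient_profile(
            make_gvg(np.zeros((5, 400))), f_o=1000.0)
        # all-zero widths: every row always closed
        assert np.all(prof.cq == 1.0)
        s = summarize_cq([prof])
        assert s.median == s.p5 == s.p95 == 1.0

    def test_matches_brute_force_percentiles(self):
        from glottkit.kinematics import CQProfile
        rng = np.random.default_rng(7)
        profs = []
        for _ in range(5):
            cq = rng.uniform(0, 1, int(rng.integers(10, 30)))
            profs.append(CQProfile(cq, float(cq.mean()), 5, 0.5))
        pooled = np.concatenate([p.cq for p in profs])
        s = summarize_cq(profs)
        assert s.median == pytest.approx(np.percentile(pooled, 50))
        assert s.p5 == pytest.approx(np.percentile(pooled, 5))
        assert s.p95 == pytest.approx(np.percentile(pooled, 95))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_cq([])


class TestClassifyConfiguration:
    def _label_for(self, configuration, seed=20):
        spec = SyntheticSpec(image_dims=DIMS, duration=0.01,
                             configuration=configuration, seed=seed)
        seq, truth = gen_hsv(spec)
        r0, r1 = truth.glottis_rows
        masks = segment_glottis(seq, roi=(0, r0, DIMS[1], r1 - r0))
        return classify_configuration(compute_gvg(masks), f_o=spec.f_o)

    def test_posterior_gap_is_config_one(self):
        lab = self._label_for("I")
        assert lab.label == "I"
        assert lab.closed_phase_contact_fraction < 0.95

    def test_partial_opening_is_config_two_a(self):
        lab = self._label_for("IIa")
        assert lab.label == "IIa"
        assert lab.closed_phase_contact_fraction >= 0.95
        assert lab.open_phase_opening_fraction <= 0.70

    def test_full_opening_is_config_two_b(self):
        lab = self._label_for("IIb")
        assert lab.label == "IIb"
        assert lab.open_phase_opening_fraction > 0.70

    def test_rules_form_a_partition(self):
        """Any (contact, opening) pair maps to exactly one label."""
        for contact in np.linspace(0, 1, 9):
            for opening in np.linspace(0, 1, 9):
                labels = []
                if contact < 0.95:
                    labels.append("I")
                if contact >= 0.95 and opening <= 0.70:
                    labels.append("IIa")
                if contact >= 0.95 and opening > 0.70:
                    labels.append("IIb")
                assert len(labels) == 1

    def test_insufficient_cycles_rejected(self):
        width = np.tile(5.0 + 3.0 * np.sin(
            2 * np.pi * 1000.0 * np.arange(30) / FPS), (4, 1))
        with pytest.raises(ValueError, match="cycles"):
            classify_configuration(make_gvg(width), f_o=1000.0)
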