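import numpy as np
import pytest
from scipy import ndimage

from synkey.errors import FingerDetectionError, InvalidInputError, SegmentationError
from synkey.imaging import (
    FingerSegment,
    HandMask,
    ImagingConfig,
    RadialProfile,
    analyze_image,
    best_postures,
    centroid,
    crop_wrist,
    digit_outline,
    finger_error,
    posture_verify,
    segment_hand,
    split_fingers,
)
from synkey.population import session_synergies
from synkey.synthetic import RenderSpec, render_posture, subject_postures

GREEN = (0, 150, 60)


def green_image(h=120, w=120):
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[:, :] = GREEN
    return img


@pytest.fixture(scope="module")
def rendered_hand(geometry):
    """A straight-fingered hand silhouette rendered by the built-in renderer."""
    from synkey.handmodel import Posture

    return render_posture(RenderSpec(), geometry, Posture(np.zeros(10)))


class TestSegmentHand:
    def test_noiseless_key_recovers_exact_silhouette(self):
        img = green_image()
        img[20:80, 30:70] = 255
        mask = segment_hand(img).mask
        expected = np.zeros((120, 120), dtype=bool)
        expected[20:80, 30:70] = True
        assert np.array_equal(mask, expected)

    def test_interior_green_speckles_are_filled(self):
        img = green_image()
        img[20:80, 30:70] = 255
        img[40, 40] = GREEN
        img[60:62, 50:52] = GREEN
        mask = segment_hand(img).mask
        assert mask[40, 40] and mask[60, 50]

    def test_second_blob_is_discarded(self):
        img = green_image()
        img[20:80, 30:70] = 255
        img[100:105, 100:105] = 255  # small distractor
        mask = segment_hand(img).mask
        labels, n = ndimage.label(mask)  # component-count oracle
        assert n == 1
        assert not mask[102, 102]

    def test_all_background_rejected(self):
        with pytest.raises(SegmentationError):
            segment_hand(green_image())


class TestCropWrist:
    def _neck_mask(self):
        # The neck sits inside the lower quarter of the component.
        mask = np.zeros((100, 60), dtype=bool)
        mask[10:75, 10:50] = True  # hand blob
        mask[75:85, 25:35] = True  # narrow wrist neck
        mask[85:95, 15:45] = True  # wider forearm
        return HandMask(mask=mask)

    def test_crops_at_the_narrowest_neck_row(self):
        hand = self._neck_mask()
        widths = hand.mask.sum(axis=1)
        rows = np.flatnonzero(hand.mask.any(axis=1))
        lower = np.arange(rows[-1] - (rows[-1] - rows[0]) // 4, rows[-1] + 1)
        oracle = int(lower[np.argmin(widths[lower])])  # exhaustive width scan
        cropped = crop_wrist(hand)
        assert cropped.wrist_row == oracle
        assert not cropped.mask[oracle:].any()

    def test_idempotent_on_cropped_mask(self):
        cropped = crop_wrist(self._neck_mask())
        again = crop_wrist(cropped)
        assert np.array_equal(again.mask, cropped.mask)

    def test_fixed_row_override(self):
        hand = self._neck_mask()
        out = crop_wrist(hand, ImagingConfig(wrist_row=50))
        assert not out.mask[50:].any() and out.mask[:50].any()


class TestCentroid:
    def test_solid_square_centroid_is_its_centre(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:20, 30:40] = True
        assert centroid(mask) == pytest.approx((14.5, 34.5))

    def test_l_shape_matches_pixel_enumeration(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:30, 5:10] = True
        mask[25:30, 10:30] = True
        rows, cols = np.nonzero(mask)  # pixel-sum oracle
        assert centroid(mask) == pytest.approx((rows.mean(), cols.mean()))

    def test_translation_equivariance(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:20, 10:25] = True
        r0, c0 = centroid(mask)
        shifted = np.roll(np.roll(mask, 7, axis=0), 11, axis=1)
        r1, c1 = centroid(shifted)
        assert (r1 - r0, c1 - c0) == pytest.approx((7.0, 11.0))

    def test_empty_mask_rejected(self):
        with pytest.raises(SegmentationError):
            centroid(np.zeros((5, 5), dtype=bool))


class TestDigitOutline:
    def test_semicircular_dome_gives_flat_profile(self):
        # A half-disc over the centroid: constant boundary distance, so the
        # normalized profile is 1.0 everywhere in the digit region.
        h = w = 201
        yy, xx = np.mgrid[:h, :w]
        mask = ((yy - 150) ** 2 + (xx - 100) ** 2 <= 80**2) & (yy <= 150)
        mask |= (np.abs(yy - 160) <= 10) & (np.abs(xx - 100) <= 80)
        hand = HandMask(mask=mask)
        cfg = ImagingConfig(boundary_smooth_frac=0.0)
        profile = digit_outline(hand, center=(150.0, 100.0), config=cfg)
        assert profile.distances.min() == 1.0
        assert profile.distances.max() < 1.02

    def test_minimum_is_exactly_one_on_renders(self, rendered_hand):
        hand = crop_wrist(segment_hand(rendered_hand))
        profile = digit_outline(hand)
        assert profile.distances.min() == 1.0

    def test_rendered_hand_has_five_fingertip_peaks(self, rendered_hand):
        segs = analyze_image(rendered_hand)
        assert [s.label for s in segs] == ["thumb", "index", "middle", "ring", "pinky"]

    def test_angles_run_thumb_to_pinky(self, rendered_hand):
        profile = digit_outline(crop_wrist(segment_hand(rendered_hand)))
        assert profile.angles_deg[0] > profile.angles_deg[-1]


class TestSplitFingers:
    def _triangle_profile(self, peaks, width=10, height=1.0):
        n = (len(peaks) * 2 + 1) * width
        d = np.ones(n)
        for i, h in enumerate(peaks):
            centre = (2 * i + 1) * width
            for k in range(-width, width + 1):
                d[centre + k] = max(d[centre + k], 1.0 + h * (1 - abs(k) / width))
        return RadialProfile(
            angles_deg=np.linspace(170, 10, n), distances=d, centroid=(0.0, 0.0)
        )

    def test_five_triangular_peaks_split_at_analytic_minima(self):
        profile = self._triangle_profile([1.0, 0.8, 1.2, 0.9, 1.1])
        segs = split_fingers(profile, ImagingConfig(valley_quantum=1e-12))
        assert len(segs) == 5
        # Analytic minima: the flat floor between consecutive triangles;
        # the first floor sample after each peak bounds the next segment.
        assert sum(s.point_count for s in segs) == profile.distances.size
        for seg, height in zip(segs, [1.0, 0.8, 1.2, 0.9, 1.1]):
            assert seg.values.max() == pytest.approx(1.0 + height)

    def test_four_peaks_raise_with_count(self):
        profile = self._triangle_profile([1.0, 0.8, 1.2, 0.9])
        with pytest.raises(FingerDetectionError) as err:
            split_fingers(profile)
        assert err.value.count == 4

    def test_rendered_fingertips_land_in_their_segments(self, geometry, rendered_hand):
        import math

        hand = crop_wrist(segment_hand(rendered_hand))
        c = centroid(hand)
        profile = digit_outline(hand)
        segs = split_fingers(profile)
        # Renderer ground truth: fingertip world angles from the centroid.
        from synkey.handmodel import Posture, forward_kinematics

        chains = forward_kinematics(geometry, Posture(np.zeros(10)))
        res = rendered_hand.shape[0]
        scale = res / 260.0
        for seg, digit in zip(segs, ["thumb", "index", "middle", "ring", "pinky"]):
            tip = chains[digit][-1]
            tip_rc = ((130.0 + 10.0 - tip[1]) * scale, (tip[0] + 130.0) * scale)
            ang = math.degrees(
                math.atan2(c[0] - tip_rc[0], tip_rc[1] - c[1])
            )
            assert seg.angles_deg.min() - 3 <= ang <= seg.angles_deg.max() + 3


class TestFingerError:
    def test_identical_segments_have_zero_error(self, rng):
        v = rng.uniform(1, 3, 20)
        a = FingerSegment("index", v, np.arange(20.0))
        b = FingerSegment("index", v.copy(), np.arange(20.0))
        assert finger_error(a, b) == 0.0

    def test_tail_padding_rule_closed_form(self):
        a = FingerSegment("ring", np.array([1.0, 1.2, 1.5]), np.arange(3.0))
        b = FingerSegment("ring", np.array([1.0, 1.2]), np.arange(2.0))
        assert finger_error(a, b) == pytest.approx(1.5)

    def test_symmetry(self, rng):
        a = FingerSegment("pinky", rng.uniform(1, 3, 15), np.arange(15.0))
        b = FingerSegment("pinky", rng.uniform(1, 3, 11), np.arange(11.0))
        assert finger_error(a, b) == pytest.approx(finger_error(b, a))

    def test_label_mismatch_rejected(self):
        a = FingerSegment("ring", np.ones(3), np.arange(3.0))
        b = FingerSegment("pinky", np.ones(3), np.arange(3.0))
        with pytest.raises(InvalidInputError):
            finger_error(a, b)


class TestPostureVerify:
    def test_template_against_itself_is_accepted(self, rendered_hand):
        score = posture_verify(rendered_hand, rendered_hand, T_p=0.1)
        assert score.accepted and score.total == 0.0

    def test_total_equal_to_threshold_is_rejected(self, rendered_hand):
        score = posture_verify(rendered_hand, rendered_hand, T_p=0.0)
        assert not score.accepted  # strict "less than"

    def test_detection_failure_becomes_rejection_with_reason(self, rendered_hand):
        img = green_image(200, 200)
        img[50:150, 90:110] = 255  # a single bar: no five fingers
        score = posture_verify(rendered_hand, img, T_p=10.0)
        assert not score.accepted
        assert score.reason is not None
        assert not np.isfinite(score.total)


class TestBestPostures:
    def test_zero_error_posture_is_selected_first(self):
        true_e = {1: np.array([0.0, 0.0]), 2: np.array([1.0, 2.0])}
        false_e = {1: np.array([3.0, 4.0]), 2: np.array([3.0, 4.0])}
        result = best_postures(true_e, false_e, k=1)
        assert result.selected == [1]
        assert result.combined_eer == pytest.approx(0.0)

    def test_and_rule_monotonicity(self, rng):
        true_e = {p: rng.uniform(0, 2, 12) for p in range(4)}
        false_e = {p: rng.uniform(1, 4, 12) for p in range(4)}
        # Combined max-error over all postures dominates any single posture,
        # so FRR at a fixed threshold can only grow (AND rule) while FAR can
        # only shrink.
        thr = 1.5
        single_frr = [np.mean(true_e[p] >= thr) for p in range(4)]
        single_far = [np.mean(false_e[p] < thr) for p in range(4)]
        all_true = np.max(np.stack(list(true_e.values())), axis=0)
        all_false = np.max(np.stack(list(false_e.values())), axis=0)
        assert np.mean(all_true >= thr) >= max(single_frr) - 1e-12
        assert np.mean(all_false < thr) <= min(single_far) + 1e-12
        result = best_postures(true_e, false_e, k=4)
        assert 0.0 <= result.combined_eer <= 100.0


def test_scale_and_translation_invariance_of_profiles(geometry, default_sim):
    """Doubling the render resolution leaves the normalized profile intact."""
    sub = default_sim.subject_specs[0]
    tset = session_synergies(default_sim.population.subjects[0].sessions[0])
    posture = subject_postures(sub, tset, geometry)[0].posture
    img1 = render_posture(RenderSpec(resolution=320), geometry, posture,
                          sub.abduction_offsets)
    img2 = render_posture(RenderSpec(resolution=640), geometry, posture,
                          sub.abduction_offsets)
    p1 = digit_outline(crop_wrist(segment_hand(img1)))
    p2 = digit_outline(crop_wrist(segment_hand(img2)))
    assert p1.distances.size == p2.distances.size
    assert np.sqrt(np.mean((p1.distances - p2.distances) ** 2)) < 0.02
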