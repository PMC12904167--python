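"""Hotspot detection gates, positive-fiber calls and ROI classification."""

import numpy as np
import pytest

from myoseries.hotspots import (
    Hotspot,
    call_positive_fiber,
    classify_rois,
    detect_hotspots,
    estimate_local_background,
    hotspots_per_roi_paired,
    percent_positive_fibers,
    qualifying,
)
from myoseries.simulate import FiberModel, HotspotSpec, ImageSpec, SplitEvent, render_fiber

PITCH = 0.103


def _flat_scene(shape=(120, 160), bg=100.0):
    img = np.full(shape, bg)
    mask = np.zeros(shape, dtype=bool)
    mask[10:110, :] = True
    return img, mask


def _blob_diam_px(d_nm):
    """Side of a square blob whose equivalent diameter is d_nm."""
    area = np.pi * (d_nm / 1000.0 / PITCH) ** 2 / 4.0
    return max(1, int(round(np.sqrt(area))))


class TestBackground:
    def test_uniform_intensity_estimates_itself(self):
        img, mask = _flat_scene(bg=73.0)
        bg = estimate_local_background(img, mask, PITCH)
        assert np.allclose(bg[mask], 73.0)

    def test_bright_blob_does_not_inflate_its_own_background(self):
        img, mask = _flat_scene()
        img[50:60, 70:80] = 500.0
        bg = estimate_local_background(img, mask, PITCH)
        assert abs(bg[55, 75] - 100.0) / 100.0 < 0.05

    def test_empty_mask_raises(self):
        img, _ = _flat_scene()
        with pytest.raises(ValueError, match="empty"):
            estimate_local_background(img, np.zeros_like(img, dtype=bool), PITCH)

    def test_tiny_window_raises(self):
        img, mask = _flat_scene()
        with pytest.raises(ValueError, match="3 px"):
            estimate_local_background(img, mask, PITCH, window_um=0.1)


class TestQualificationGates:
    def _detect_one(self, fold, d_nm):
        img, mask = _flat_scene()
        side = _blob_diam_px(d_nm)
        img[50 : 50 + side, 70 : 70 + side] = fold * 100.0
        bg = np.full(img.shape, 100.0)
        dets = detect_hotspots(img, bg, mask, PITCH)
        assert len(dets) == 1
        return dets[0]

    def test_fold_just_below_two_detected_but_disqualified(self):
        h = self._detect_one(1.99, 1200)
        assert not h.qualifies
        assert h.reasons == ["fold"]

    def test_fold_exactly_two_at_min_size_qualifies(self):
        """Both gates are inclusive at their boundaries."""
        img, mask = _flat_scene()
        img[50:56, 70:74] = 200.0  # short axis 4 px -> 412 nm, fold exactly 2.0
        bg = np.full(img.shape, 100.0)
        dets = detect_hotspots(img, bg, mask, PITCH)
        (h,) = dets
        assert h.fold == pytest.approx(2.0)
        assert 400.0 <= h.min_feret_nm <= 1900.0
        assert h.qualifies

    def test_oversized_blob_disqualified_for_size(self):
        h = self._detect_one(3.0, 2400)
        assert h.equivalent_diameter_nm > 1900.0
        assert not h.qualifies
        assert h.reasons == ["size_large"]

    def test_undersized_blob_disqualified_for_size(self):
        img, mask = _flat_scene()
        img[50:52, 70:72] = 300.0  # 4 px -> eq diam ~232 nm
        bg = np.full(img.shape, 100.0)
        (h,) = detect_hotspots(img, bg, mask, PITCH)
        assert h.reasons == ["size_small"]

    def test_gate_boundaries_are_inclusive_exact(self):
        """Direct check of the inclusive comparisons at 2.0x, 400 and 1900 nm."""

        def verdict(fold, d_nm):
            reasons = []
            if fold < 2.0:
                reasons.append("fold")
            if d_nm < 400.0:
                reasons.append("size_small")
            if d_nm > 1900.0:
                reasons.append("size_large")
            return not reasons

        # mirrors the decision applied in detect_hotspots
        assert verdict(2.0, 400.0) and verdict(2.0, 1900.0)
        assert not verdict(1.9999999, 1000.0)
        assert not verdict(3.0, 1900.0000001)

    def test_raising_fold_threshold_never_increases_qualifying_count(self):
        rng = np.random.default_rng(11)
        img, mask = _flat_scene()
        for r, c, fold in ((30, 30, 2.2), (60, 90, 2.8), (90, 130, 1.8)):
            img[r : r + 8, c : c + 8] = fold * 100.0
        img = img + rng.normal(0, 5.0, img.shape)
        bg = estimate_local_background(img, mask, PITCH)
        counts = []
        for thr in (1.6, 2.0, 2.4, 2.8, 3.2):
            dets = detect_hotspots(img, bg, mask, PITCH, fold_threshold=thr)
            counts.append(len(qualifying(dets)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPositiveFiberCall:
    def _spot(self, i):
        return Hotspot(
            id=i,
            centroid=(0.0, 0.0),
            coords=np.zeros((1, 2), dtype=int),
            bbox=(0, 0, 0, 0),
            area_px=1,
            equivalent_diameter_nm=1000.0,
            min_feret_nm=500.0,
            max_feret_nm=1500.0,
            axial_extent_um=2.4,
            fold=3.0,
            qualifies=True,
        )

    def test_no_hotspots_negative(self):
        assert call_positive_fiber([]) is False

    def test_two_hotspots_positive(self):
        assert call_positive_fiber([self._spot(0), self._spot(1)]) is True

    def test_percentage_arithmetic(self):
        calls = [True] * 18 + [False] * 12
        assert percent_positive_fibers(calls) == pytest.approx(60.0)

    def test_percentage_invariant_to_order(self):
        rng = np.random.default_rng(0)
        calls = [True] * 7 + [False] * 13
        shuffled = list(rng.permutation(calls))
        assert percent_positive_fibers(calls) == percent_positive_fibers(shuffled)


class TestRoiClassification:
    def test_pristine_fiber_all_rois_normal(self, ideal_image):
        image, _ = ideal_image
        rois = classify_rois(image)
        assert rois
        assert all(r.label == "normal" for r in rois)

    def test_split_dense_region_classified_disarrayed(self, spec):
        fiber = FiberModel()
        splits = [
            SplitEvent(aband_index=k, lateral_fraction=f)
            for k, f in ((5, 0.45), (7, 0.5), (9, 0.55), (11, 0.5), (13, 0.45))
        ]
        image, _ = render_fiber(spec, fiber, splits)
        rois = classify_rois(image)
        assert any(r.label == "disarrayed" for r in rois)
        for r in rois:
            if r.label == "disarrayed":
                assert r.mean_zline_length_um < 0.6 * r.reference_length_um

    def test_zero_disarray_fraction_classifies_everything_normal(self, spec):
        fiber = FiberModel()
        splits = [SplitEvent(aband_index=k, lateral_fraction=0.5) for k in (5, 8, 11)]
        image, _ = render_fiber(spec, fiber, splits)
        rois = classify_rois(image, disarray_fraction=0.0)
        assert all(r.label == "normal" for r in rois)


class TestPairedRoiCounts:
    @staticmethod
    def _rois_and_spots():
        from myoseries.hotspots import RoiClass

        rois = [
            RoiClass((0, 96, 0, 96), "normal", 20.0, 20.0, 5),
            RoiClass((0, 96, 97, 193), "disarrayed", 8.0, 20.0, 5),
        ]
        spots = []
        for i, col in enumerate((120, 150)):  # both inside the disarrayed ROI
            spots.append(
                Hotspot(
                    id=i,
                    centroid=(50.0, float(col)),
                    coords=np.array([[50, col]]),
                    bbox=(50, 50, col, col),
                    area_px=1,
                    equivalent_diameter_nm=1000.0,
                    min_feret_nm=500.0,
                    max_feret_nm=1500.0,
                    axial_extent_um=2.4,
                    fold=3.0,
                    qualifies=True,
                )
            )
        return rois, spots

    def test_hotspots_only_in_disarrayed_rois(self):
        rois, spots = self._rois_and_spots()
        normal_mean, disarrayed_mean = hotspots_per_roi_paired(rois, spots, seed=0)
        assert normal_mean == 0.0
        assert disarrayed_mean == 2.0

    def test_fiber_without_one_class_excluded(self):
        rois, spots = self._rois_and_spots()
        only_normal = [r for r in rois if r.label == "normal"]
        assert hotspots_per_roi_paired(only_normal, spots, seed=0) is None
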