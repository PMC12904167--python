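"""Continuous Z-line segmentation, tracing and the disarray statistic."""

import numpy as np
import pytest

from myoseries.simulate import FiberModel, ImageSpec, SplitEvent, render_fiber
from myoseries.zline import (
    ContinuousZline,
    RoiSelection,
    extract_roi,
    mean_continuous_zline_length,
    roi_mean_zline_length,
    segment_zlines,
    select_roi,
    skeletonize_zlines,
    trace_continuous_zlines,
)

PITCH = 0.103


class TestRoiSelection:
    def test_default_extent_has_published_physical_size(self):
        roi = RoiSelection(center=(100, 200))
        assert roi.physical_extent_um(PITCH) == (pytest.approx(20.6), pytest.approx(41.2))

    def test_same_seed_same_roi(self, ideal_image):
        image, _ = ideal_image
        assert select_roi(image, rng_seed=5) == select_roi(image, rng_seed=5)

    def test_fiber_narrower_than_roi_raises(self, spec):
        narrow = FiberModel(width_um=10.0)  # ~97 px < 200 px transverse extent
        image, _ = render_fiber(spec, narrow)
        with pytest.raises(ValueError, match="transverse"):
            select_roi(image)


class TestSegmentation:
    def test_mask_covers_every_planted_zline_center(self, ideal_image, spec):
        image, truth = ideal_image
        mask, params = segment_zlines(image.zline, spec.pixel_pitch)
        assert params["threshold_method"] == "otsu"
        row = image.shape[0] // 2
        for p in truth.zline_positions[row]:
            c = int(round(p))
            assert mask[row, c - 1 : c + 2].any()

    def test_uniform_image_yields_empty_mask_and_flagged_downstream(self):
        flat = np.full((120, 160), 37.0)
        mask, _ = segment_zlines(flat, PITCH)
        assert not mask.any()
        with pytest.raises(ValueError, match="empty"):
            roi_mean_zline_length(flat, PITCH)

    def test_inversion_flag_restores_mask(self, ideal_image, spec):
        image, _ = ideal_image
        mask, _ = segment_zlines(image.zline, spec.pixel_pitch)
        inverted = image.zline.max() - image.zline
        mask_inv, _ = segment_zlines(inverted, spec.pixel_pitch, invert=True)
        agreement = (mask == mask_inv).mean()
        assert agreement > 0.99


class TestTracing:
    def test_ideal_striations_span_full_roi_extent(self, ideal_image, spec):
        image, _ = ideal_image
        roi = select_roi(image, rng_seed=1)
        raster = extract_roi(image.zline, roi)
        mask, _ = segment_zlines(raster, spec.pixel_pitch)
        lines = trace_continuous_zlines(skeletonize_zlines(mask), spec.pixel_pitch)
        tol = 2 * spec.pixel_pitch
        for ln in lines:
            assert ln.length_um == pytest.approx(20.6, abs=tol)

    def test_bisected_zlines_halve_the_mean(self, spec):
        """A lateral phase shear of half a sarcomere breaks every Z-line."""
        fiber = FiberModel(lateral_phase_break=(0.5, 1.2))
        image, _ = render_fiber(spec, fiber)
        roi = RoiSelection(center=(image.shape[0] / 2, image.shape[1] / 2))
        mean = roi_mean_zline_length(extract_roi(image.zline, roi), spec.pixel_pitch)
        assert mean == pytest.approx(10.3, abs=2 * spec.pixel_pitch)

    def test_single_isolated_pixel_is_zero_length_line(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 10] = True
        skel = skeletonize_zlines(mask)
        lines = trace_continuous_zlines(skel, PITCH)
        assert len(lines) == 1
        assert lines[0].length_um == 0.0

    def test_every_skeleton_pixel_in_exactly_one_line(self, split_image, spec):
        """Partition: no skeleton pixel is dropped or double-counted."""
        image, _ = split_image
        mask, _ = segment_zlines(image.zline, spec.pixel_pitch)
        skel = skeletonize_zlines(mask)
        lines = trace_continuous_zlines(skel, spec.pixel_pitch)
        seen = {}
        for ln in lines:
            for r, c in map(tuple, ln.path):
                seen[(r, c)] = seen.get((r, c), 0) + 1
        skel_pixels = {tuple(p) for p in np.argwhere(skel.skeleton)}
        assert set(seen) == skel_pixels
        assert max(seen.values()) == 1

    def test_theta_180_without_branches_gives_connected_components(self):
        from scipy.ndimage import label

        rng = np.random.default_rng(0)
        mask = np.zeros((60, 60), dtype=bool)
        for c in (10, 25, 40):  # disjoint wiggly vertical curves
            cols = c + np.cumsum(rng.integers(-1, 2, 50))
            mask[np.arange(5, 55), np.clip(cols, 0, 59)] = True
        skel = skeletonize_zlines(mask)
        skel.branch_points[:] = False  # consider only branchless skeletons
        keep = skel.skeleton & True
        n_components = label(keep, structure=np.ones((3, 3)))[1]
        lines = trace_continuous_zlines(skel, PITCH, theta_max_deg=180.0)
        assert len(lines) == n_components

    def test_rotation_equivariance_90_degrees(self, ideal_image, spec):
        image, _ = ideal_image
        roi = select_roi(image, rng_seed=2)
        raster = extract_roi(image.zline, roi)

        def lengths(r):
            mask, _ = segment_zlines(r, spec.pixel_pitch)
            lines = trace_continuous_zlines(skeletonize_zlines(mask), spec.pixel_pitch)
            return np.sort([ln.length_um for ln in lines])

        a = lengths(raster)
        b = lengths(np.rot90(raster))
        assert len(a) == len(b)
        assert np.max(np.abs(a - b)) <= 2 * spec.pixel_pitch


class TestMeanLength:
    def test_unweighted_mean(self):
        lines = [
            ContinuousZline(id=0, path=np.zeros((1, 2)), length_um=10.0),
            ContinuousZline(id=1, path=np.zeros((1, 2)), length_um=20.0),
        ]
        assert mean_continuous_zline_length(lines) == pytest.approx(15.0)

    def test_length_weighted_mean(self):
        lines = [
            ContinuousZline(id=0, path=np.zeros((1, 2)), length_um=10.0),
            ContinuousZline(id=1, path=np.zeros((1, 2)), length_um=20.0),
        ]
        assert mean_continuous_zline_length(lines, "length") == pytest.approx(
            (100 + 400) / 30
        )

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            mean_continuous_zline_length([])

    def test_planted_splits_depress_the_mean(self, ideal_image, split_image, spec):
        pristine, _ = ideal_image
        disarrayed, _ = split_image
        roi = RoiSelection(center=(160.0, 224.0))
        m_sham = roi_mean_zline_length(
            extract_roi(pristine.zline, roi), spec.pixel_pitch
        )
        m_mov = roi_mean_zline_length(
            extract_roi(disarrayed.zline, roi), spec.pixel_pitch
        )
        assert m_mov < m_sham
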