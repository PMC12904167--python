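"""The synthetic generator: planted geometry, noise model, cohort bookkeeping."""

import numpy as np
import pytest

from myoseries.hotspots import detect_hotspots, estimate_local_background
from myoseries.simulate import (
    CohortConfig,
    FiberModel,
    HotspotSpec,
    ImageSpec,
    SingleFiberTableParams,
    SplitEvent,
    add_noise,
    render_fiber,
    simulate_cohort,
    simulate_single_fiber_table,
)


class TestRenderFiber:
    def test_striation_period_matches_sarcomere_length(self, ideal_image, spec, fiber):
        """Channel-0 autocorrelation peaks at sarcomere_length / pixel_pitch."""
        image, _ = ideal_image
        row = image.zline[image.shape[0] // 2]
        x = row - row.mean()
        ac = np.correlate(x, x, "full")[len(x) - 1 :]
        lag = int(np.argmax(ac[5:]) + 5)
        expected = fiber.sarcomere_length_um / spec.pixel_pitch
        assert abs(lag - expected) <= 1.0

    def test_ground_truth_records_every_planted_hotspot(self, spec, fiber):
        hotspots = [
            HotspotSpec(model_class="yu", anchor_sarcomere=a, lateral_fraction=0.3)
            for a in (1, 6, 11)
        ]
        _, truth = render_fiber(spec, fiber, hotspots=hotspots)
        assert len(truth.hotspots) == 3
        assert [h.label for h in truth.hotspots] == ["yu"] * 3

    def test_hzone_hotspot_centered_on_zline(self, spec, fiber):
        """The hzone blob's axial centroid sits on the shared Z-line (+/- 1 px)."""
        hs = HotspotSpec(model_class="hzone", anchor_sarcomere=4, lateral_fraction=0.5)
        image, truth = render_fiber(spec, fiber, hotspots=[hs])
        rmin, rmax, cmin, cmax = truth.hotspots[0].bbox
        blob = image.nsp[rmin : rmax + 1, cmin : cmax + 1]
        cols = np.arange(cmin, cmax + 1)
        centroid = float((blob.sum(axis=0) * cols).sum() / blob.sum())
        zline_col = truth.base_zline_cols_px[5]  # Z-line between sarcomeres 4 and 5
        assert abs(centroid - zline_col) <= 1.0

    def test_conservation_of_zline_count_across_splits(self, split_image):
        """Count per lateral column = base + signed sum of crossed splits."""
        image, truth = split_image
        sl_px = truth.fiber.sarcomere_length_um / truth.image_spec.pixel_pitch
        top, bottom = truth.fiber_rows
        transition_bands = [
            (s.row_px - sl_px - 2, s.row_px + 2) for s in truth.splits
        ]
        for row in range(top + 1, bottom - 1, 7):
            if any(lo <= row <= hi for lo, hi in transition_bands):
                continue
            rendered = len(truth.zline_positions[row])
            assert rendered == truth.n_zlines_at_row(row)

    def test_noise_free_hotspot_masks_recovered_exactly(self, hotspot_image, spec):
        """Re-detecting planted hotspots in the clean render recovers every pixel."""
        image, truth = hotspot_image
        bg = estimate_local_background(image.nsp, image.fiber_mask, spec.pixel_pitch)
        dets = detect_hotspots(image.nsp, bg, image.fiber_mask, spec.pixel_pitch)
        assert len(dets) == len(truth.hotspots)
        for det, planted in zip(
            sorted(dets, key=lambda h: h.bbox[2]),
            sorted(truth.hotspots, key=lambda h: h.bbox[2]),
        ):
            assert (det.mask(image.shape) == planted.mask(image.shape)).all()

    def test_overlapping_hotspots_rejected_with_diagnostic(self, spec, fiber):
        clashing = [
            HotspotSpec(model_class="yu", anchor_sarcomere=4, lateral_fraction=0.5),
            HotspotSpec(model_class="rodier", anchor_sarcomere=4, lateral_fraction=0.5),
        ]
        with pytest.raises(ValueError, match="merge"):
            render_fiber(spec, fiber, hotspots=clashing)
        # merge_policy="allow" renders them anyway
        image, truth = render_fiber(
            spec, fiber, hotspots=clashing, merge_policy="allow"
        )
        assert len(truth.hotspots) == 2

    def test_same_gap_splits_rejected(self, spec, fiber):
        with pytest.raises(ValueError, match="same gap"):
            render_fiber(
                spec,
                fiber,
                [
                    SplitEvent(aband_index=3, lateral_fraction=0.3),
                    SplitEvent(aband_index=3, lateral_fraction=0.7),
                ],
            )

    def test_intensity_ordering_enforced(self):
        with pytest.raises(ValueError, match="zline > aband"):
            FiberModel(zline_intensity=100.0, aband_intensity=300.0)


class TestAddNoise:
    def test_zero_noise_is_identity(self, ideal_image):
        image, _ = ideal_image
        quiet = ImageSpec(psf_sigma=0.0, gaussian_sd=0.0, poisson_gain=0.0)
        out = add_noise(image, quiet)
        np.testing.assert_array_equal(out.data, image.data)

    def test_same_seed_bit_identical(self, ideal_image, spec):
        image, _ = ideal_image
        a = add_noise(image, spec)
        b = add_noise(image, spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_gaussian_sd_realized_on_flat_region(self, ideal_image):
        image, _ = ideal_image
        noisy = add_noise(
            image, ImageSpec(psf_sigma=0.0, gaussian_sd=5.0, poisson_gain=0.0, seed=3)
        )
        flat = slice(0, 10)  # rows outside the fiber are constant
        resid = (noisy.data[0, flat] - image.data[0, flat]).ravel()
        assert abs(resid.std() - 5.0) / 5.0 < 0.10


class TestCohort:
    def test_zero_density_sham_has_no_splits(self):
        cfg = CohortConfig(
            n_muscles_per_group=1,
            fibers_per_muscle=3,
            split_density_sham=0.0,
            hotspot_positive_fraction_sham=0.0,
        )
        ds = simulate_cohort(cfg, seed=1)
        for rec in ds.records:
            if rec.group == "sham":
                assert rec.truth.splits == []

    def test_pure_class_mix_labels_every_hotspot(self):
        cfg = CohortConfig(
            n_muscles_per_group=1,
            fibers_per_muscle=3,
            hotspot_class_mix={"yu": 1.0},
            hotspot_positive_fraction_mov=1.0,
            hotspot_positive_fraction_sham=1.0,
        )
        ds = simulate_cohort(cfg, seed=2)
        labels = [h.label for r in ds.records for h in r.truth.hotspots]
        assert labels and set(labels) == {"yu"}

    def test_manifest_rows_per_group(self):
        cfg = CohortConfig(
            n_muscles_per_group=3,
            fibers_per_muscle=30,
            image_spec=ImageSpec(shape=(128, 192)),
            fiber=FiberModel(width_um=8.0),
            noise=False,
        )
        ds = simulate_cohort(cfg, seed=3)
        manifest = ds.manifest
        assert (manifest.groupby("group").size() == 90).all()

    def test_impossible_density_raises(self):
        cfg = CohortConfig(n_muscles_per_group=1, fibers_per_muscle=1,
                           split_density_mov=5.0)
        with pytest.raises(ValueError, match="gaps"):
            simulate_cohort(cfg, seed=0)

    def test_same_seed_reproduces_dataset(self):
        cfg = CohortConfig(n_muscles_per_group=1, fibers_per_muscle=2)
        a = simulate_cohort(cfg, seed=9)
        b = simulate_cohort(cfg, seed=9)
        for ra, rb in zip(a.records, b.records):
            np.testing.assert_array_equal(ra.image.data, rb.image.data)
            assert ra.truth == rb.truth


class TestSingleFiberTable:
    def test_zero_cv_gives_group_means_exactly(self):
        params = SingleFiberTableParams(fiber_length_cv=0.0, sarcomere_length_cv=0.0)
        table = simulate_single_fiber_table(params, seed=0)
        sham = table[table.group == "sham"]["fiber_length_um"]
        mov = table[table.group == "mov"]["fiber_length_um"]
        assert (sham == params.fiber_length_mean_sham_um).all()
        assert np.allclose(mov, params.fiber_length_mean_sham_um * 1.075)

    def test_deterministic_limit_recovers_length_ratio(self):
        params = SingleFiberTableParams(fiber_length_cv=0.0, sarcomere_length_cv=0.0)
        table = simulate_single_fiber_table(params, seed=0)
        ratio = (
            table[table.group == "mov"]["fiber_length_um"].mean()
            / table[table.group == "sham"]["fiber_length_um"].mean()
        )
        assert ratio == pytest.approx(1.075, abs=1e-12)

    def test_lognormal_lengths_positive(self):
        params = SingleFiberTableParams(fiber_length_cv=0.5, n_per_group=200)
        table = simulate_single_fiber_table(params, seed=4)
        assert (table["fiber_length_um"] > 0).all()
        mean = table[table.group == "sham"]["fiber_length_um"].mean()
        assert mean == pytest.approx(params.fiber_length_mean_sham_um, rel=0.15)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            SingleFiberTableParams(fiber_length_cv=-0.1)
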