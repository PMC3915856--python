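"""PLA event calling: projection, ROI geometry, particle detection against a
brute-force oracle, the merged-blob counting rule, and density recovery."""

import math

import numpy as np
import pytest

from avfstudy import (
    background_correct,
    count_events,
    detect_particles,
    gen_vessel_image,
    max_project,
    place_rois,
)
from avfstudy.pla_quant import ROI, measure_pla_specimen
from avfstudy.pipeline import recover_interaction_timecourse
from avfstudy.synthetic import compartment_masks, default_calibration

from conftest import SMALL_PLA_RATES


# ---------------------------------------------------------------------------
# independent oracle: flood fill + re-application of the counting rules
# ---------------------------------------------------------------------------

def brute_force_events(image, threshold=100, min_area=2, max_single=50,
                       median_area=10):
    """Exhaustive 8-connected flood fill and rule application, written
    independently of the library path."""
    above = [[bool(v >= threshold) for v in row] for row in image.tolist()]
    nrows, ncols = image.shape
    seen = [[False] * ncols for _ in range(nrows)]
    events = 0
    particles = 0
    for r0 in range(nrows):
        for c0 in range(ncols):
            if not above[r0][c0] or seen[r0][c0]:
                continue
            stack, pixels = [(r0, c0)], []
            seen[r0][c0] = True
            while stack:
                r, c = stack.pop()
                pixels.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < nrows and 0 <= cc < ncols
                                and above[rr][cc] and not seen[rr][cc]):
                            seen[rr][cc] = True
                            stack.append((rr, cc))
            area = len(pixels)
            if area < min_area:
                continue
            particles += 1
            if area <= max_single:
                events += 1
            else:
                events += math.floor(area / median_area + 0.5)
    return particles, events


def _full_roi(shape):
    return ROI("full", "endothelium", np.ones(shape, bool))


class TestMaxProject:
    def test_identical_slices(self):
        slc = np.arange(64, dtype=np.uint8).reshape(8, 8)
        stack = np.stack([slc] * 4)
        assert np.array_equal(max_project(stack), slc)

    def test_single_bright_pixel_survives(self):
        stack = np.zeros((6, 16, 16), np.uint8)
        stack[3, 5, 9] = 250
        assert max_project(stack)[5, 9] == 250

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(1)
        stack = rng.integers(0, 255, (6, 12, 12)).astype(np.uint8)
        proj = max_project(stack)
        for r in range(12):
            for c in range(12):
                assert proj[r, c] == max(stack[z, r, c] for z in range(6))

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_project(np.zeros((0, 8, 8), np.uint8))


class TestPlaceRois:
    def test_six_rois_three_per_compartment(self, small_rois):
        assert len(small_rois) == 6
        comps = [r.compartment for r in small_rois]
        assert comps.count("endothelium") == 3
        assert comps.count("media") == 3

    def test_band_depth_follows_pixel_size(self, small_ph, small_seg):
        rois = place_rois(small_seg, small_ph.pixel_size_um)
        cy, cx = small_ph.center
        for roi in rois[:3]:
            rr, cc = np.nonzero(roi.mask)
            radial = np.hypot(rr - cy, cc - cx)
            depth = round(5.0 / small_ph.pixel_size_um)
            assert radial.max() <= small_ph.lumen_radius_px + depth + 1.0
            assert radial.min() >= small_ph.lumen_radius_px - 1.0

    def test_areas_match_analytic_geometry(self, small_ph, small_seg):
        rois = place_rois(small_seg, small_ph.pixel_size_um)
        r_l = small_ph.lumen_radius_px
        depth = round(5.0 / small_ph.pixel_size_um)
        band_analytic = (100.0 / 360.0) * math.pi * ((r_l + depth) ** 2 - r_l**2)
        for roi in rois[:3]:
            assert roi.area_px == pytest.approx(band_analytic, rel=0.02)
        for roi in rois[3:]:
            # circle: pi r^2 with the radius place_rois derived
            rr, cc = np.nonzero(roi.mask)
            radius = (roi.area_px / math.pi) ** 0.5
            assert roi.area_px == pytest.approx(math.pi * radius**2, rel=0.02)

    def test_rotation_equivariance(self, small_seg):
        base = place_rois(small_seg, 1.0, angle_offset_deg=20.0)
        rotated = place_rois(np.rot90(small_seg), 1.0,
                             angle_offset_deg=20.0 - 90.0)
        for a, b in zip(base, rotated):
            assert np.array_equal(np.rot90(a.mask), b.mask)

    def test_rois_do_not_overlap(self, small_rois):
        combined = np.zeros(small_rois[0].mask.shape, int)
        for roi in small_rois:
            combined += roi.mask
        assert combined.max() == 1

    def test_media_too_thin_error_reports_feasible_area(self, small_seg):
        with pytest.raises(ValueError, match="maximum feasible"):
            place_rois(small_seg, 1.0, circle_area_mm2=0.5)

    def test_area_bounds_enforced(self, small_seg):
        with pytest.raises(ValueError, match="bounds"):
            place_rois(small_seg, 1.0, area_bounds_mm2=(0.5, 1.0))


class TestDetectParticles:
    def test_blank_image(self):
        img = np.zeros((32, 32), np.uint8)
        assert detect_particles(img, _full_roi(img.shape)) == []

    def test_single_square(self):
        img = np.zeros((32, 32), np.uint8)
        img[10:13, 10:13] = 255
        parts = detect_particles(img, _full_roi(img.shape))
        assert len(parts) == 1
        assert parts[0].area_px == 9
        assert parts[0].peak == 255

    def test_single_pixel_discarded(self):
        img = np.zeros((32, 32), np.uint8)
        img[5, 5] = 255
        assert detect_particles(img, _full_roi(img.shape)) == []

    def test_connectivity_option(self):
        img = np.zeros((32, 32), np.uint8)
        img[5, 5] = img[6, 6] = 255  # diagonal pair
        eight = detect_particles(img, _full_roi(img.shape), connectivity=2)
        four = detect_particles(img, _full_roi(img.shape), connectivity=1)
        assert len(eight) == 1 and eight[0].area_px == 2
        assert four == []  # two 1-px components, both below the 2-px gate

    def test_centroid_rule_for_straddling_particles(self):
        img = np.zeros((32, 32), np.uint8)
        img[10, 8:13] = 255  # 5-px bar centered at column 10
        left = ROI("left", "endothelium",
                   np.pad(np.ones((32, 11), bool), ((0, 0), (0, 21))))
        right = ROI("right", "endothelium",
                    np.pad(np.ones((32, 21), bool), ((0, 0), (11, 0))))
        in_left = detect_particles(img, left)
        in_right = detect_particles(img, right)
        assert len(in_left) == 1 and in_left[0].area_px == 5
        assert in_right == []

    def test_matches_brute_force_oracle_on_random_fields(self):
        rng = np.random.default_rng(12)
        for trial in range(500):
            img = np.zeros((64, 64), np.uint8)
            # scatter of rectangles, some huge enough to merge
            for _ in range(rng.integers(1, 12)):
                r, c = rng.integers(0, 60, 2)
                h, w = rng.integers(1, 9, 2)
                img[r:r + h, c:c + w] = rng.integers(100, 256)
            noise = rng.integers(0, 140, img.shape)
            img = np.maximum(img, noise.astype(np.uint8))
            roi = _full_roi(img.shape)
            parts = detect_particles(img, roi)
            events = count_events(parts)
            oracle_particles, oracle_events = brute_force_events(img)
            assert len(parts) == oracle_particles
            assert events == oracle_events


class TestCountEvents:
    @pytest.mark.parametrize(
        "areas,expected",
        [
            ([10, 10, 10], 3),
            ([500], 50),
            ([2, 50, 51], 7),   # 1 + 1 + round(5.1)
            ([55], 6),          # ties round up
            ([], 0),
        ],
    )
    def test_rule_application(self, areas, expected):
        assert count_events(areas) == expected

    def test_merged_blob_area_over_events_is_ten(self):
        img = np.zeros((64, 64), np.uint8)
        img[10:30, 10:35] = 200  # one connected 500-px blob
        parts = detect_particles(img, _full_roi(img.shape))
        assert len(parts) == 1 and parts[0].area_px == 500
        events = count_events(parts)
        assert parts[0].area_px / events == pytest.approx(10.0)

    def test_fractional_mode(self):
        assert count_events([51], fractional=True) == pytest.approx(5.1)

    def test_adding_disjoint_spot_never_decreases_count(self):
        img = np.zeros((64, 64), np.uint8)
        img[5:8, 5:8] = 200
        before = count_events(detect_particles(img, _full_roi(img.shape)))
        img[40:43, 40:43] = 200
        after = count_events(detect_particles(img, _full_roi(img.shape)))
        assert after >= before

    def test_raising_threshold_never_increases_particles(self):
        # spot fields: each spot has one gray level, so a higher threshold
        # drops whole spots and can never split one
        rng = np.random.default_rng(5)
        img = np.zeros((96, 96), np.uint8)
        for _ in range(20):
            r, c = rng.integers(2, 90, 2)
            img[r:r + 3, c:c + 3] = rng.integers(100, 256)
        roi = _full_roi(img.shape)
        n_lo = len(detect_particles(img, roi, threshold=100))
        for thr in (120, 160, 200, 240):
            n = len(detect_particles(img, roi, threshold=thr))
            assert n <= n_lo
            n_lo = n

    def test_translation_invariance_of_counts(self):
        rng = np.random.default_rng(8)
        img = np.zeros((64, 64), np.uint8)
        for _ in range(8):
            r, c = rng.integers(5, 50, 2)
            img[r:r + 3, c:c + 3] = 200
        roi = ROI("r", "endothelium",
                  ROI.from_circle("c", "media", (32, 32), 20, img.shape).mask)
        shifted = np.roll(img, (4, 6), axis=(0, 1))
        roi_shifted = ROI("r", "endothelium",
                          np.roll(roi.mask, (4, 6), axis=(0, 1)))
        a = count_events(detect_particles(img, roi))
        b = count_events(detect_particles(shifted, roi_shifted))
        assert a == b


class TestBackgroundCorrect:
    def test_subtraction(self):
        assert background_correct(120.0, 20.0) == 100.0
        assert background_correct(33.0, 33.0) == 0.0
        assert background_correct(10.0, 30.0) == -20.0  # retained

    def test_corrected_density_recovers_true_rate(self, small_ph, small_rois):
        """With nonspecific background present, raw - control converges on
        the seeded specific rate (no-merge fields, >= 20 seeds)."""
        truth = SMALL_PLA_RATES["endothelium"]
        vals = []
        for seed in range(24):
            _, pla, nc, _ = gen_vessel_image(
                small_ph, 0.0, dict(SMALL_PLA_RATES), seed,
                nonspecific_rate_mm2=400.0, merged_fraction=0.0)
            df = measure_pla_specimen(pla, nc, small_rois)
            vals.append(float(df.loc[df["compartment"] == "endothelium",
                                     "corrected_density"].iloc[0]))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - truth) <= 4 * se

    def test_missing_control_is_an_error(self, small_ph, small_rois):
        _, pla, _, _ = gen_vessel_image(small_ph, 0.0, dict(SMALL_PLA_RATES), 1)
        with pytest.raises(ValueError, match="control"):
            measure_pla_specimen(pla, None, small_rois)


class TestDensityNormalization:
    def test_halving_roi_area_preserves_expected_density(self):
        """A homogeneous spot field gives the same density in a full and a
        half ROI, within Poisson error (averaged over seeds)."""
        full_d, half_d = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            img = np.zeros((200, 200), np.uint8)
            for _ in range(120):
                r, c = rng.integers(2, 196, 2)
                img[r:r + 2, c:c + 2] = 200
            full = ROI("f", "endothelium", np.ones(img.shape, bool))
            half_mask = np.zeros(img.shape, bool)
            half_mask[:100] = True
            half = ROI("h", "endothelium", half_mask)
            full_d.append(count_events(detect_particles(img, full)) / full.area_mm2)
            half_d.append(count_events(detect_particles(img, half)) / half.area_mm2)
        ratio = np.mean(half_d) / np.mean(full_d)
        assert ratio == pytest.approx(1.0, abs=0.1)


class TestPlaTimecourseRecovery:
    def test_endothelium_only_effect_leaves_media_flat(self, small_ph):
        """A +150% interaction increase confined to the endothelium shows up
        only in the endothelial time-course (averaged over seeded replicate
        studies; small-phantom counts are Poisson-noisy)."""
        endo_vals, media_vals = [], []
        for seed in range(6):
            profile = default_calibration(
                seed=seed, time_grid_days=(-1, 84),
                interaction_timecourses={"pair1": {84: 150}},
                interaction_effect_compartment="endothelium",
                pla_base_rate_mm2={"endothelium": 6000.0, "media": 6000.0})
            tc = recover_interaction_timecourse(profile, "pair1",
                                                phantom=small_ph)
            day84 = tc[tc["day"] == 84].set_index("compartment")
            endo_vals.append(day84.loc["endothelium", "pct_change"])
            media_vals.append(day84.loc["media", "pct_change"])
        assert np.mean(endo_vals) > 90
        assert abs(np.mean(media_vals)) < 45

    def test_day84_percent_change_recovered_across_seeds(self, small_ph):
        """The +23% day-84 effect is recovered on average across seeded
        replicate studies (small phantoms are count-noisy; the bound is the
        aggregate sampling error)."""
        profile0 = default_calibration(pla_base_rate_mm2=dict(SMALL_PLA_RATES))
        truth = profile0.interaction_effect("Notch1-Delta1", 84)
        grid = (-1, 84)
        vals = []
        for seed in range(20):
            profile = default_calibration(
                seed=seed, time_grid_days=grid,
                pla_base_rate_mm2=dict(SMALL_PLA_RATES))
            tc = recover_interaction_timecourse(profile, "Notch1-Delta1",
                                                phantom=small_ph)
            endo = tc[(tc["compartment"] == "endothelium") & (tc["day"] == 84)]
            vals.append(float(endo["pct_change"].iloc[0]))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - truth) <= 3 * se
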