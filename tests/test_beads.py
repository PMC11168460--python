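"""Bead quantification: detection, circle fitting, radial profiles,
adjacency exclusion, min-max scoring, QC filtering, and the scoring
invariants (shift invariance, gain equivariance, oracle equivalence)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beadpull import beads as bq
from beadpull.synth import BeadSceneSpec, BeadSpec, generate_bead_scene

from conftest import disk_mask, ray_minmax_oracle, single_bead_scene


def grid_scene(n=5, noise_sd=0.0, seed=0, rim=80.0):
    """n disjoint beads on a grid."""
    beads = [
        BeadSpec(
            center=(40.0 + 60 * (i % 3), 40.0 + 60 * (i // 3)),
            radius=18.0,
            rim_intensity={"EGFP": rim},
            core_intensity={"EGFP": 5.0},
        )
        for i in range(n)
    ]
    spec = BeadSceneSpec(
        image_shape=(170, 230),
        beads=beads,
        background_level={"EGFP": 10.0},
        noise_sd=noise_sd,
        seed=seed,
    )
    return generate_bead_scene(spec)


class TestDetectBeads:
    def test_finds_all_disjoint_beads_with_true_centroids(self):
        scene, truth = grid_scene(n=5)
        mask = bq.detect_beads(scene.channels["EGFP"])
        assert mask.max() == 5
        got = sorted(
            (bq.fit_circular_roi(mask, k).center for k in range(1, 6))
        )
        want = sorted(zip(truth.objects.center_x, truth.objects.center_y))
        for (gx, gy), (wx, wy) in zip(got, want):
            assert abs(gx - wx) <= 1.0 and abs(gy - wy) <= 1.0

    def test_constant_image_gives_empty_mask(self):
        mask = bq.detect_beads(np.full((100, 100), 7.0))
        assert mask.max() == 0

    def test_merged_doublet_discarded_by_fill_fraction(self):
        # two beads rendered in contact form one low-circularity component
        beads = [
            BeadSpec(center=(60.0, 60.0), radius=20.0,
                     rim_intensity={"EGFP": 100.0},
                     core_intensity={"EGFP": 100.0}),
            BeadSpec(center=(98.0, 60.0), radius=20.0,
                     rim_intensity={"EGFP": 100.0},
                     core_intensity={"EGFP": 100.0}),
        ]
        spec = BeadSceneSpec(
            image_shape=(160, 160), beads=beads,
            background_level={"EGFP": 0.0}, allow_adjacent=True,
        )
        scene, _ = generate_bead_scene(spec)
        mask = bq.detect_beads(scene.channels["EGFP"])
        assert mask.max() == 0  # the merged component fails the shape gate

    def test_unknown_backend_rejected(self):
        with pytest.raises(KeyError, match="unknown detection backend"):
            bq.detect_beads(np.zeros((10, 10)), backend="nope")

    def test_registered_backend_honoured_and_failure_names_image(self):
        def broken(image):
            raise RuntimeError("model not loaded")

        bq.register_backend("broken", broken)
        with pytest.raises(RuntimeError, match=r"pos7.*model not loaded"):
            bq.detect_beads(np.zeros((10, 10)), backend="broken", image_id="pos7")


class TestFitCircularROI:
    def test_disk_radius_recovered_within_half_px(self):
        mask = disk_mask((80, 80), (40.0, 40.0), 20.0).astype(int)
        roi = bq.fit_circular_roi(mask, 1)
        assert roi.radius == pytest.approx(20.0, abs=0.5)
        assert roi.center == pytest.approx((40.0, 40.0), abs=0.1)

    def test_half_disk_center_is_mask_centroid(self):
        full = disk_mask((80, 80), (40.0, 40.0), 20.0)
        half = full.copy()
        half[:, 41:] = False  # keep x <= 40
        roi = bq.fit_circular_roi(half.astype(int), 1)
        ys, xs = np.nonzero(half)
        assert roi.center[0] == pytest.approx(xs.mean(), abs=1e-12)
        assert roi.center[1] == pytest.approx(ys.mean(), abs=1e-12)
        assert roi.center[0] < 40.0  # off the disk's geometric center

    def test_absent_label_raises(self):
        with pytest.raises(ValueError, match="label 3"):
            bq.fit_circular_roi(np.zeros((10, 10), int), 3)

    def test_one_px_label_is_below_minimum_radius(self):
        mask = np.zeros((10, 10), int)
        mask[5, 5] = 1
        roi = bq.fit_circular_roi(mask, 1)
        assert roi.radius < bq.MIN_RADIUS_PX


class TestDrawProfiles:
    def test_angles_equally_spaced_from_zero(self):
        roi = bq.BeadROI(1, (60.0, 60.0), 20.0)
        profiles = bq.draw_profiles(roi, np.zeros((120, 120)), n_lines=8)
        assert [p.angle for p in profiles] == pytest.approx(
            [i * np.pi / 4 for i in range(8)]
        )

    def test_sample_count_matches_extension_arithmetic(self):
        # radius 20, extension 0.2, step 1 -> distances 0..24 = 25 samples
        roi = bq.BeadROI(1, (60.0, 60.0), 20.0)
        profiles = bq.draw_profiles(
            roi, np.zeros((120, 120)), n_lines=4, extension_frac=0.2, step=1.0
        )
        assert all(len(p.samples) == 25 for p in profiles)
        assert all(p.distances[-1] == 24.0 for p in profiles)

    def test_interior_bead_has_no_out_of_bounds(self):
        roi = bq.BeadROI(1, (60.0, 60.0), 20.0)
        profiles = bq.draw_profiles(roi, np.zeros((120, 120)))
        assert not any(p.excluded for p in profiles)

    def test_border_bead_profiles_marked_out_of_bounds(self):
        roi = bq.BeadROI(1, (5.0, 60.0), 20.0)
        profiles = bq.draw_profiles(roi, np.zeros((120, 120)))
        oob = [p for p in profiles if p.excluded]
        assert oob and all(p.reason == "out-of-bounds" for p in oob)
        assert not profiles[0].excluded  # the +x ray stays inside


class TestExcludeAdjacent:
    def _own(self, shape=(200, 200)):
        mask = disk_mask(shape, (100.0, 100.0), 15.0).astype(int)
        return mask

    def test_isolated_bead_keeps_all_profiles(self):
        mask = self._own()
        roi = bq.fit_circular_roi(mask, 1)
        profiles = bq.draw_profiles(roi, np.zeros(mask.shape))
        profiles = bq.exclude_adjacent(profiles, mask, 1)
        assert sum(p.excluded for p in profiles) == 0

    def test_single_neighbor_excludes_exactly_the_predicted_ray(self):
        # neighbour disk centred on the +x ray at distance 22, radius 5:
        # only the angle-0 ray (samples out to 18 px) can touch it
        mask = self._own()
        mask[disk_mask(mask.shape, (122.0, 100.0), 5.0)] = 2
        roi = bq.BeadROI(1, (100.0, 100.0), 15.0)
        profiles = bq.draw_profiles(roi, np.zeros(mask.shape))
        profiles = bq.exclude_adjacent(profiles, mask, 1)
        excluded = [p.angle for p in profiles if p.excluded]
        assert excluded == [0.0]
        assert all(
            p.reason == "adjacent-bead" for p in profiles if p.excluded
        )

    def test_fully_ringed_bead_retains_zero_profiles(self):
        mask = self._own()
        for i in range(8):
            ang = i * np.pi / 4
            cx = 100.0 + 16.5 * np.cos(ang)
            cy = 100.0 + 16.5 * np.sin(ang)
            mask[disk_mask(mask.shape, (cx, cy), 5.0) & (mask == 0)] = 2 + i
        roi = bq.BeadROI(1, (100.0, 100.0), 15.0)
        profiles = bq.draw_profiles(roi, np.zeros(mask.shape))
        profiles = bq.exclude_adjacent(profiles, mask, 1)
        assert all(p.excluded for p in profiles)
        m = bq.summarize_bead(profiles, bead_id=1)
        assert m.n_profiles_retained == 0
        assert m.exclusion_reason == "no-retained-profiles"

    def test_missing_own_label_raises(self):
        roi = bq.BeadROI(1, (100.0, 100.0), 15.0)
        profiles = bq.draw_profiles(roi, np.zeros((200, 200)))
        with pytest.raises(ValueError, match="own label 9"):
            bq.exclude_adjacent(profiles, self._own(), 9)


class TestScoreAndSummarize:
    @pytest.mark.parametrize(
        "samples, expected",
        [([5.0, 5.0, 5.0], 0.0), ([10.0, 80.0, 30.0], 70.0)],
    )
    def test_min_max_arithmetic(self, samples, expected):
        p = bq.LineProfile(
            1, 0.0, np.arange(len(samples), dtype=float), np.array(samples)
        )
        assert bq.score_profile(p) == expected

    def test_excluded_profile_refused(self):
        p = bq.LineProfile(
            1, 0.0, np.arange(3.0), np.zeros(3), excluded=True,
            reason="adjacent-bead",
        )
        with pytest.raises(ValueError, match="excluded"):
            bq.score_profile(p)

    def test_noise_free_coated_bead_scores_rim_everywhere(self, clean_bead_scene):
        scene, _ = clean_bead_scene
        table, profiles = bq.quantify_scene(scene.channels["EGFP"])
        assert len(table) == 1
        assert table.loc[0, "mean_score"] == pytest.approx(100.0, abs=1e-9)
        assert table.loc[0, "sd_score"] == pytest.approx(0.0, abs=1e-9)
        for p in profiles:
            assert bq.score_profile(p) == pytest.approx(100.0, abs=1e-9)

    def test_summary_matches_brute_force_mean_sd(self, rng):
        scores = rng.uniform(0, 100, size=12)
        profiles = [
            bq.LineProfile(1, 0.0, np.array([0.0, 1.0]), np.array([0.0, s]))
            for s in scores
        ]
        m = bq.summarize_bead(profiles, bead_id=1)
        # independent arithmetic oracle
        mean = sum(scores) / len(scores)
        sd = (sum((s - mean) ** 2 for s in scores) / (len(scores) - 1)) ** 0.5
        assert m.mean_score == pytest.approx(mean, abs=1e-9)
        assert m.sd_score == pytest.approx(sd, abs=1e-9)

    def test_single_profile_sd_zero_by_convention(self):
        p = bq.LineProfile(1, 0.0, np.array([0.0, 1.0]), np.array([0.0, 30.0]))
        m = bq.summarize_bead([p], bead_id=1)
        assert m.n_profiles_retained == 1
        assert m.sd_score == 0.0


class TestQCFilter:
    def _bead(self, bead_id, mean, sd):
        m = bq.BeadMeasurement(bead_id=bead_id)
        m.mean_score, m.sd_score = mean, sd
        m.n_profiles_retained = 8
        m.qc_pass = sd < mean / 2
        return m

    def test_boundary_cases_at_half_mean(self):
        beads = [
            self._bead(1, 100.0, 49.9),
            self._bead(2, 100.0, 50.0),
            self._bead(3, 100.0, 50.1),
        ]
        retained, report = bq.qc_filter(beads)
        assert [b.bead_id for b in retained] == [1]
        assert sorted(report["bead_id"]) == [2, 3]

    def test_zero_mean_bead_excluded(self):
        retained, report = bq.qc_filter([self._bead(1, 0.0, 0.0)])
        assert retained == []
        assert report.loc[0, "reason"] == "sd>=mean/2"

    def test_matches_brute_force_rule_on_mixed_table(self, rng):
        beads = [
            self._bead(i, m, s)
            for i, (m, s) in enumerate(
                zip(rng.uniform(1, 100, 20), rng.uniform(0, 60, 20))
            )
        ]
        retained, _ = bq.qc_filter(beads)
        want = {b.bead_id for b in beads if b.sd_score < b.mean_score / 2.0}
        assert {b.bead_id for b in retained} == want

    def test_idempotent(self, rng):
        beads = [
            self._bead(i, m, s)
            for i, (m, s) in enumerate(
                zip(rng.uniform(1, 100, 15), rng.uniform(0, 60, 15))
            )
        ]
        once, _ = bq.qc_filter(beads)
        twice, _ = bq.qc_filter(once)
        assert [b.bead_id for b in twice] == [b.bead_id for b in once]


class TestScoringInvariants:
    @given(shift=st.floats(0.0, 500.0), seed=st.integers(0, 50))
    @settings(max_examples=15, deadline=None)
    def test_shift_invariance(self, shift, seed):
        scene, _ = single_bead_scene(noise_sd=3.0, seed=seed, background=50.0)
        img = scene.channels["EGFP"]
        mask = bq.detect_beads(img)
        if mask.max() == 0:
            return
        roi = bq.fit_circular_roi(mask, 1)
        base = [
            bq.score_profile(p)
            for p in bq.draw_profiles(roi, img) if not p.excluded
        ]
        shifted = [
            bq.score_profile(p)
            for p in bq.draw_profiles(roi, img + shift) if not p.excluded
        ]
        assert shifted == pytest.approx(base, abs=1e-9)

    @given(gain=st.floats(0.0, 10.0), seed=st.integers(0, 50))
    @settings(max_examples=15, deadline=None)
    def test_gain_equivariance(self, gain, seed):
        scene, _ = single_bead_scene(noise_sd=3.0, seed=seed, background=50.0)
        img = scene.channels["EGFP"]
        roi = bq.BeadROI(1, (60.0, 60.0), 20.0)
        base = np.array(
            [bq.score_profile(p) for p in bq.draw_profiles(roi, img)]
        )
        scaled = np.array(
            [bq.score_profile(p) for p in bq.draw_profiles(roi, img * gain)]
        )
        assert scaled == pytest.approx(gain * base, rel=1e-9, abs=1e-9)

    def test_pipeline_equals_rasterized_ray_oracle(self):
        scene, _ = single_bead_scene(noise_sd=5.0, seed=3, background=30.0)
        img = scene.channels["EGFP"]
        mask = bq.detect_beads(img)
        roi = bq.fit_circular_roi(mask, 1)
        profiles = bq.draw_profiles(roi, img)
        for p in profiles:
            want = ray_minmax_oracle(img, p.origin, p.angle, p.distances)
            assert bq.score_profile(p) == pytest.approx(want, abs=1e-9)
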