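"""Phantom generators: determinism, ground-truth consistency, noise model."""

import numpy as np
import pytest

from markreg import (
    CardiacPhantomSpec,
    JawPhantomSpec,
    ObserverSpec,
    RigidTransform,
    fit_rigid,
    fre,
    make_cardiac_pair,
    make_cardiac_truth,
    make_jaw_phantom,
    place_landmarks,
    resample_through_transform,
)
from markreg.synthetic import us_cone_mask
from markreg.volume import physical_coordinates, physical_extent


class TestCardiacPair:
    def test_determinism_bit_identical(self, small_cardiac_spec):
        ct1, us1, _ = make_cardiac_pair(small_cardiac_spec)
        ct2, us2, _ = make_cardiac_pair(small_cardiac_spec)
        for a, b in zip(ct1.frames + us1.frames, ct2.frames + us2.frames):
            np.testing.assert_array_equal(a.data, b.data)

    def test_landmark_truth_maps_through_transform(self):
        truth = make_cardiac_truth(CardiacPhantomSpec())
        for phase in (0.0, 0.4, 0.9):
            ct_lm = truth.ct_landmarks(phase)
            us_lm = truth.us_landmarks(phase)
            mapped = truth.true_transform.apply(us_lm.points)
            np.testing.assert_allclose(mapped, ct_lm.points, atol=1e-9)
            assert ct_lm.labels == us_lm.labels
            assert len(ct_lm) >= 12

    def test_gated_phases_and_free_running(self, small_cardiac_spec):
        ct, us, truth = make_cardiac_pair(small_cardiac_spec)
        assert ct.source == "ECG_GATED"
        np.testing.assert_allclose(ct.phase, np.arange(10) / 10)
        assert us.source == "FREE_RUNNING"
        assert us.phase is None  # phases are truth-only, hidden from consumers
        assert len(truth.us_frame_phases) == us.n_frames

    def test_same_scene_correlates_inside_cone(self):
        """Clean pair, identity pose, matched phases: CT and US intensities
        agree (r > 0.99) on the common grid inside the cone."""
        spec = CardiacPhantomSpec(
            ct_shape=(96, 96, 48),
            us_shape=(80, 80, 120),
            noise_sd=0.0,
            true_transform=RigidTransform.identity(),
        )
        ct, us, truth = make_cardiac_pair(spec)
        idx = int(np.argmin(np.abs(truth.us_frame_phases - 0.9)))
        ct_frame, us_frame = ct.frames[9], us.frames[idx]
        fused = resample_through_transform(us_frame, ct_frame, truth.true_transform)
        pts = physical_coordinates(ct_frame)
        lo, hi = physical_extent(us_frame)
        inside = np.all((pts > lo + 1.0) & (pts < hi - 1.0), axis=-1)
        cone = us_cone_mask(spec, pts, us_frame.physical_center(), margin_mm=1.5)
        msk = inside & cone
        r = np.corrcoef(ct_frame.data[msk], fused.data[msk])[0, 1]
        assert r > 0.99

    def test_annulus_pulsation_amplitude(self):
        """Ring diameter measured on the rendered frames (thresholded ring
        voxels near the annulus plane) swings by amplitude x mean."""
        spec = CardiacPhantomSpec(
            ct_shape=(112, 112, 24),
            ct_spacing=(0.47, 0.47, 1.0),
            noise_sd=0.0,
            true_transform=RigidTransform.identity(),
        )
        ct, _, _ = make_cardiac_pair(spec)

        def diameter(frame):
            pts = physical_coordinates(frame)
            ring = (frame.data > 380) & (np.abs(pts[..., 2]) <= 0.75)
            rho = np.sqrt(pts[..., 0] ** 2 + pts[..., 1] ** 2)
            return 2.0 * float(rho[ring].mean())

        d_max = diameter(ct.frames[0])  # phase 0.0: maximal dilation
        d_min = diameter(ct.frames[5])  # phase 0.5: minimal
        expected = spec.annulus_pulsation_amplitude * spec.annulus_diameter_mean
        assert abs((d_max - d_min) - expected) < 1.0  # within a voxel

    def test_end_to_end_noiseless_recovery(self):
        """Temporal match + rigid fit on truth landmarks recovers the
        generator transform to 0.01 deg / 0.01 mm with FRE < 1e-6."""
        truth = make_cardiac_truth(CardiacPhantomSpec(seed=3))
        pairing = truth.pairing(0.9)
        t = fit_rigid(pairing)
        dp = t.params - truth.true_transform.params
        assert np.all(np.abs(dp[:3]) < 0.01)
        assert np.all(np.abs(dp[3:]) < 0.01)
        assert fre(t, pairing) < 1e-6

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CardiacPhantomSpec(annulus_pulsation_amplitude=1.5)
        with pytest.raises(ValueError):
            CardiacPhantomSpec(n_ct_phases=1)


class TestObserverModel:
    def test_zero_noise_is_exact(self):
        truth = make_cardiac_truth(CardiacPhantomSpec()).pairing(0.9)
        placed = place_landmarks(truth, ObserverSpec(sigma_mm=0.0), n=10)
        np.testing.assert_array_equal(placed.fixed.points, truth.fixed.points[:10])
        np.testing.assert_array_equal(placed.moving.points, truth.moving.points[:10])

    def test_noise_variance_calibrated(self):
        """Mean squared placement error per coordinate converges to sigma^2
        (Monte-Carlo against the stated distribution)."""
        truth = make_cardiac_truth(CardiacPhantomSpec()).pairing(0.9)
        sigma = 1.0
        obs = ObserverSpec(sigma_mm=sigma, seed=42)
        sq = []
        for trial in range(1000):
            placed = place_landmarks(truth, obs, n=10, trial=trial)
            sq.append(((placed.moving.points - truth.moving.points[:10]) ** 2).mean())
        assert np.mean(sq) == pytest.approx(sigma**2, rel=0.05)

    def test_index_inflation_scales_later_landmarks(self):
        truth = make_cardiac_truth(CardiacPhantomSpec()).pairing(0.9)
        obs = ObserverSpec(sigma_mm=1.0, index_inflation=0.5, seed=1)
        first, last = [], []
        for trial in range(2000):
            placed = place_landmarks(truth, obs, n=10, trial=trial)
            err = placed.moving.points - truth.moving.points[:10]
            first.append((err[0] ** 2).mean())
            last.append((err[9] ** 2).mean())
        ratio = np.mean(last) / np.mean(first)
        assert ratio == pytest.approx((1 + 0.5 * 9) ** 2, rel=0.15)

    def test_deterministic_given_keys(self):
        truth = make_cardiac_truth(CardiacPhantomSpec()).pairing(0.9)
        obs = ObserverSpec(sigma_mm=1.0, seed=7)
        a = place_landmarks(truth, obs, 8, trial=3, user="alice")
        b = place_landmarks(truth, obs, 8, trial=3, user="alice")
        c = place_landmarks(truth, obs, 8, trial=3, user="bob")
        np.testing.assert_array_equal(a.fixed.points, b.fixed.points)
        assert not np.array_equal(a.fixed.points, c.fixed.points)

    def test_too_many_landmarks_rejected(self):
        truth = make_cardiac_truth(CardiacPhantomSpec()).pairing(0.9)
        with pytest.raises(ValueError, match="truth has only"):
            place_landmarks(truth, ObserverSpec(), n=99)


class TestJawPhantom:
    def test_symmetric_construction_is_mirror_symmetric(self):
        spec = JawPhantomSpec(
            asymmetry_transform=RigidTransform.identity(), defect_extent=0.0
        )
        ct, _ = make_jaw_phantom(spec)
        np.testing.assert_array_equal(ct.data, ct.data[::-1, :, :])

    def test_defect_confined_to_one_side(self):
        ct, truth = make_jaw_phantom(JawPhantomSpec(seed=5))
        lower, upper = truth.bone_thresholds
        bone_now = (ct.data >= lower) & (ct.data <= upper)
        diff = truth.pre_defect_mask & ~bone_now
        assert diff.any()  # the defect removed some bone
        xs = physical_coordinates(ct)[..., 0]
        assert np.all(xs[diff] > truth.plane_position)  # all on the defect side
        dice = 2 * (bone_now & truth.pre_defect_mask).sum() / (
            bone_now.sum() + truth.pre_defect_mask.sum()
        )
        assert dice < 1.0

    def test_bone_mask_count_matches_bruteforce(self):
        ct, truth = make_jaw_phantom(JawPhantomSpec(seed=5))
        lower, upper = truth.bone_thresholds
        k = int(((ct.data >= lower) & (ct.data <= upper)).sum())
        from markreg import threshold_segment

        assert threshold_segment(ct, lower, upper).count == k

    def test_landmark_correspondence_is_exact_asymmetry(self):
        _, truth = make_jaw_phantom(JawPhantomSpec(seed=5))
        mapped = truth.asymmetry_transform.apply(truth.landmarks_mirrored.points)
        np.testing.assert_allclose(mapped, truth.landmarks_original.points, atol=1e-12)
        assert len(truth.landmarks_original) >= 6

    def test_determinism(self):
        a, _ = make_jaw_phantom(JawPhantomSpec(seed=9, noise_sd=5.0))
        b, _ = make_jaw_phantom(JawPhantomSpec(seed=9, noise_sd=5.0))
        np.testing.assert_array_equal(a.data, b.data)
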