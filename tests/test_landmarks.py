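"""Rigid fiducial registration, transform algebra and landmark I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from markreg import (
    DegenerateLandmarksError,
    LandmarkPairing,
    LandmarkSet,
    RigidTransform,
    Volume,
    apply_transform,
    fit_rigid,
    read_landmarks,
    read_transform,
    resample_through_transform,
    transform_params,
    write_landmarks,
    write_transform,
)
from markreg.metrics import fre

from conftest import random_pairing, random_rigid


class TestFitRigid:
    def test_identity_on_equal_sets(self, rng):
        pts = LandmarkSet(rng.uniform(-10, 10, (5, 3)))
        pairing = LandmarkPairing(pts, LandmarkSet(pts.points.copy(), list(pts.labels)))
        t = fit_rigid(pairing)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-12)

    def test_pure_translation(self):
        moving = LandmarkSet([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        fixed = LandmarkSet(moving.points + [1.0, 2.0, 3.0], list(moving.labels))
        t = fit_rigid(LandmarkPairing(fixed, moving))
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, [1, 2, 3], atol=1e-12)

    def test_rz90_with_translation(self):
        """Four non-coplanar points through a known Rz(90)+t map are
        recovered exactly (generator comparison at 1e-9, zero residual)."""
        gen = RigidTransform.from_params([90.0, 0.0, 0.0, 5.0, -2.0, 1.0])
        moving = LandmarkSet([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]])
        fixed = LandmarkSet(gen.apply(moving.points), list(moving.labels))
        t = fit_rigid(LandmarkPairing(fixed, moving))
        np.testing.assert_allclose(t.rotation, gen.rotation, atol=1e-9)
        np.testing.assert_allclose(t.translation, gen.translation, atol=1e-9)
        assert fre(t, LandmarkPairing(fixed, moving)) < 1e-9

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 15))
    def test_exact_recovery_property(self, seed, n):
        """Noiseless transformed point sets are recovered to 1e-9."""
        rng = np.random.default_rng(seed)
        gen = random_rigid(rng)
        pairing = random_pairing(rng, n, gen)
        t = fit_rigid(pairing)
        assert np.linalg.norm(t.rotation - gen.rotation) < 1e-9
        assert np.linalg.norm(t.translation - gen.translation) < 1e-9

    def test_role_swap_gives_inverse(self, rng):
        gen = random_rigid(rng)
        pairing = random_pairing(rng, 8, gen, sigma=1.0)
        t = fit_rigid(pairing)
        t_rev = fit_rigid(LandmarkPairing(pairing.moving, pairing.fixed))
        inv = t.inverse()
        np.testing.assert_allclose(t_rev.rotation, inv.rotation, atol=1e-6)
        np.testing.assert_allclose(t_rev.translation, inv.translation, atol=1e-4)

    def test_equivariance_under_common_rotation(self, rng):
        """Pre-rotating both clouds by Q conjugates the recovered rotation."""
        gen = random_rigid(rng)
        pairing = random_pairing(rng, 6, gen, sigma=0.5)
        q = random_rigid(rng, max_translation=0.0)
        rot_pair = LandmarkPairing(
            LandmarkSet(q.apply(pairing.fixed.points), list(pairing.fixed.labels)),
            LandmarkSet(q.apply(pairing.moving.points), list(pairing.moving.labels)),
        )
        t = fit_rigid(pairing)
        t_rot = fit_rigid(rot_pair)
        np.testing.assert_allclose(
            t_rot.rotation, q.rotation @ t.rotation @ q.rotation.T, atol=1e-9
        )

    def test_reflection_branch_gives_proper_rotation(self, rng):
        """A near-reflective correspondence still yields det = +1."""
        moving_pts = rng.uniform(-10, 10, (8, 3))
        moving_pts[:, 2] *= 0.01  # nearly planar
        reflected = moving_pts * [1.0, 1.0, -1.0]
        moving = LandmarkSet(moving_pts)
        fixed = LandmarkSet(reflected + rng.normal(0, 0.05, reflected.shape), list(moving.labels))
        t = fit_rigid(LandmarkPairing(fixed, moving))
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        moving = LandmarkSet([[0, 0, 0], [1, 0, 0]])
        fixed = LandmarkSet([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(DegenerateLandmarksError):
            fit_rigid(LandmarkPairing(fixed, moving))

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        pairing = LandmarkPairing(LandmarkSet(pts.copy()), LandmarkSet(pts.copy()))
        with pytest.raises(DegenerateLandmarksError, match="collinear"):
            fit_rigid(pairing)


class TestTransform:
    def test_identity_params(self):
        np.testing.assert_array_equal(transform_params(RigidTransform.identity()), np.zeros(6))

    def test_pure_translation_params(self):
        t = RigidTransform(np.eye(3), np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(t.params, [0, 0, 0, 1, 2, 3])

    def test_rz30_params(self):
        a = np.deg2rad(30)
        rz = np.array(
            [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
        )
        t = RigidTransform(rz, np.zeros(3))
        np.testing.assert_allclose(t.params, [30, 0, 0, 0, 0, 0], atol=1e-12)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_params_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        t = random_rigid(rng)
        back = RigidTransform.from_params(t.params)
        np.testing.assert_allclose(back.rotation, t.rotation, atol=1e-9)
        np.testing.assert_allclose(back.translation, t.translation, atol=1e-9)

    def test_gimbal_lock_flagged(self):
        t = RigidTransform.from_params([10.0, 90.0, 0.0, 0, 0, 0])
        with pytest.warns(UserWarning, match="gimbal"):
            transform_params(t)

    def test_apply_and_inverse(self, rng):
        t = random_rigid(rng)
        pts = LandmarkSet(rng.uniform(-10, 10, (5, 3)))
        there = apply_transform(t, pts)
        back = apply_transform(t.inverse(), there)
        np.testing.assert_allclose(back.points, pts.points, atol=1e-9)
        assert back.labels == pts.labels

    def test_rz90_maps_x_to_y(self):
        t = RigidTransform.from_params([90.0, 0, 0, 0, 0, 0])
        np.testing.assert_allclose(t.apply(np.array([1.0, 0, 0])), [0, 1, 0], atol=1e-12)

    def test_improper_rotation_rejected(self):
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestLandmarkIO:
    @pytest.mark.parametrize("ext", ["fcsv", "mrk.json", "csv"])
    def test_roundtrip(self, tmp_path, rng, ext):
        lset = LandmarkSet(rng.uniform(-40, 40, (6, 3)), [f"P{i}" for i in range(6)])
        path = write_landmarks(lset, tmp_path / f"lm.{ext}")
        back = read_landmarks(path)
        np.testing.assert_allclose(back.points, lset.points, atol=1e-12)
        assert back.labels == lset.labels

    def test_ras_fcsv_converted_to_lps(self, tmp_path):
        text = (
            "# Markups fiducial file version = 4.11\n"
            "# CoordinateSystem = RAS\n"
            "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n"
            "n0,10.0,-5.0,3.0,0,0,0,1,1,1,0,A,,\n"
        )
        path = tmp_path / "ras.fcsv"
        path.write_text(text)
        lset = read_landmarks(path)
        np.testing.assert_allclose(lset.points[0], [-10.0, 5.0, 3.0])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            LandmarkSet([[0, 0, 0], [1, 1, 1]], ["A", "A"])

    def test_pairing_label_mismatch(self):
        a = LandmarkSet([[0, 0, 0]], ["A"])
        b = LandmarkSet([[0, 0, 0]], ["B"])
        with pytest.raises(ValueError, match="labels"):
            LandmarkPairing(a, b)


class TestTransformIO:
    @pytest.mark.parametrize("ext", ["txt", "tfm"])
    def test_roundtrip(self, tmp_path, rng, ext):
        t = random_rigid(rng)
        path = write_transform(t, tmp_path / f"t.{ext}")
        back = read_transform(path)
        np.testing.assert_allclose(back.rotation, t.rotation, atol=1e-9)
        np.testing.assert_allclose(back.translation, t.translation, atol=1e-9)


class TestResampleThroughTransform:
    def test_identity_is_identity(self, smooth_volume):
        out = resample_through_transform(
            smooth_volume, smooth_volume, RigidTransform.identity(), "LINEAR"
        )
        np.testing.assert_allclose(out.data, smooth_volume.data, atol=1e-6)

    def test_translated_sphere_moves(self):
        shape = (40, 40, 40)
        idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
        phys = idx * 1.0 - 20.0
        sphere = (np.sum((phys - [-5.0, 0, 0]) ** 2, axis=-1) < 36).astype(float)
        moving = Volume(data=sphere, spacing=(1, 1, 1), origin=(-20, -20, -20))
        d = np.array([6.0, 3.0, -4.0])
        t = RigidTransform(np.eye(3), d)
        out = resample_through_transform(moving, moving, t, "LINEAR")
        w = out.data.sum()
        centroid = np.array(
            [(out.data * phys[..., i]).sum() / w for i in range(3)]
        )
        np.testing.assert_allclose(centroid, [-5.0, 0, 0] + d, atol=1.0)

    def test_empty_overlap_warns(self, smooth_volume):
        t = RigidTransform(np.eye(3), np.array([1e4, 0.0, 0.0]))
        with pytest.warns(UserWarning, match="overlap"):
            resample_through_transform(smooth_volume, smooth_volume, t)
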