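"""Rigid-transform algebra and the rotation/translation error metric."""

import numpy as np
import pytest

import spinereg as sr
from spinereg.transforms import (apply_transform, compose, euler_rotation,
                                 invert, registration_error)

from conftest import random_rigid


try:
    from hypothesis import given, settings, strategies as st

    angles = st.floats(min_value=-180.0, max_value=180.0,
                       allow_nan=False, allow_infinity=False)
    coords = st.floats(min_value=-200.0, max_value=200.0,
                       allow_nan=False, allow_infinity=False)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.tuples(angles, angles, angles),
           st.tuples(coords, coords, coords),
           st.tuples(coords, coords, coords))
    def test_inverse_roundtrip_and_rigidity_property(euler, trans, point):
        t = sr.RigidTransform(euler_rotation(euler), trans)
        p = np.asarray(point)
        back = invert(t).apply(t.apply(p))
        assert np.abs(back - p).max() < 1e-9
        assert abs(np.linalg.norm(t.apply(p) - t.apply(p * 0.5))
                   - np.linalg.norm(p - p * 0.5)) < 1e-9
except ImportError:  # pragma: no cover - hypothesis is a test extra
    pass


def test_identity_inverts_to_identity():
    ident = sr.RigidTransform.identity()
    assert np.allclose(invert(ident).matrix, np.eye(4))


def test_z_rotations_compose_additively():
    t10 = sr.RigidTransform(euler_rotation((0, 0, 10)))
    t20 = sr.RigidTransform(euler_rotation((0, 0, 20)))
    t30 = compose(t10, t20)
    assert np.allclose(t30.rotation, euler_rotation((0, 0, 30)), atol=1e-12)


def test_translation_moves_origin():
    t = sr.RigidTransform(np.eye(3), (3, 4, 0))
    assert np.allclose(t.apply(np.zeros(3)), [3, 4, 0])


def test_compose_with_inverse_is_identity_over_random_draws():
    rng = np.random.default_rng(0)
    for _ in range(100):
        t = random_rigid(rng)
        back = compose(t, invert(t))
        assert np.abs(back.matrix - np.eye(4)).max() < 1e-9


def test_group_associativity_on_sampled_triples():
    rng = np.random.default_rng(1)
    for _ in range(20):
        a, b, c = (random_rigid(rng) for _ in range(3))
        left = compose(compose(a, b), c)
        right = compose(a, compose(b, c))
        assert np.abs(left.matrix - right.matrix).max() < 1e-9


def test_apply_transform_is_rigid(rng):
    cloud = sr.PointCloud(rng.normal(scale=30, size=(60, 3)), rng.uniform(size=60))
    moved = apply_transform(cloud, random_rigid(rng))
    d_before = np.linalg.norm(cloud.points[:, None] - cloud.points[None], axis=-1)
    d_after = np.linalg.norm(moved.points[:, None] - moved.points[None], axis=-1)
    assert np.abs(d_before - d_after).max() < 1e-6
    assert np.array_equal(moved.features, cloud.features)


def test_apply_then_inverse_restores_cloud(rng):
    cloud = sr.PointCloud(rng.normal(size=(40, 3)))
    t = random_rigid(rng)
    back = apply_transform(apply_transform(cloud, t), invert(t))
    assert np.abs(back.points - cloud.points).max() < 1e-9


def test_invalid_rotations_rejected():
    with pytest.raises(ValueError, match="orthonormal"):
        sr.RigidTransform(np.eye(3) + 1e-3)
    reflection = np.diag([1.0, 1.0, -1.0])
    with pytest.raises(ValueError, match="determinant"):
        sr.RigidTransform(reflection)


class TestRegistrationError:
    def test_exact_match_is_zero(self, rng):
        t = random_rigid(rng)
        err = registration_error(t, t)
        assert err.rotation_error_deg < 1e-9
        assert err.translation_error_mm < 1e-9

    def test_thirty_degree_rotation_offset(self):
        t = sr.RigidTransform(euler_rotation((0, 0, 30)))
        err = registration_error(t, sr.RigidTransform.identity())
        assert err.rotation_error_deg == pytest.approx(30.0, abs=1e-9)

    def test_pythagorean_translation_offset(self):
        t = sr.RigidTransform(np.eye(3), (3, 4, 0))
        err = registration_error(t, sr.RigidTransform.identity())
        assert err.translation_error_mm == pytest.approx(5.0, abs=1e-12)

    def test_left_invariance(self, rng):
        # conjugation S (T T_G^-1) S^-1 preserves the rotation angle for any
        # rigid S; the translation norm is preserved when S is a pure
        # rotation (a left translation mixes into dt through I - dR)
        from spinereg.transforms import random_rotation
        for _ in range(25):
            t, t_gt, s = (random_rigid(rng) for _ in range(3))
            base = registration_error(t, t_gt)
            shifted = registration_error(compose(s, t), compose(s, t_gt))
            assert base.rotation_error_deg == pytest.approx(
                shifted.rotation_error_deg, abs=1e-9)
            s_rot = sr.RigidTransform(random_rotation(rng))
            rotated = registration_error(compose(s_rot, t), compose(s_rot, t_gt))
            assert base.translation_error_mm == pytest.approx(
                rotated.translation_error_mm, abs=1e-9)

    def test_arccos_argument_clamped(self):
        # numerically identical rotations can push trace fractionally past 3
        r = euler_rotation((1e-9, 0, 0))
        err = registration_error(sr.RigidTransform(r), sr.RigidTransform(np.eye(3)))
        assert np.isfinite(err.rotation_error_deg)

    def test_error_bounds_validated(self):
        with pytest.raises(ValueError):
            sr.RegistrationError(-1.0, 0.0)
        with pytest.raises(ValueError):
            sr.RegistrationError(0.0, -0.5)
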