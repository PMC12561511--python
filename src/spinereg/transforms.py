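"""Rigid-transform algebra and the rotation/translation error metric.

The error metric compares an estimated transform ``T`` against a ground-truth
transform ``T_G`` through the residual motion ``dT = T  T_G^{-1}``:

    e_r = arccos((trace(dR) - 1) / 2)   [degrees]
    e_t = || dt ||                      [mm]

The arccos argument is clamped to [-1, 1] to absorb floating-point drift.
"""

from __future__ import annotations

import numpy as np

from .types import PointCloud, RegistrationError, RigidTransform


def compose(t1: RigidTransform, t2: RigidTransform) -> RigidTransform:
    """``t1`` after ``t2``: (t1 ∘ t2)(p) = t1(t2(p))."""
    return t1.compose(t2)


def invert(t: RigidTransform) -> RigidTransform:
    return t.invert()


def apply_transform(cloud: PointCloud, t: RigidTransform) -> PointCloud:
    """Rigidly move a cloud; the feature channel is carried through unchanged."""
    return PointCloud(t.apply(cloud.points), cloud.features, cloud.source_tag)


def rotation_angle_deg(rotation: np.ndarray) -> float:
    """Geodesic angle (degrees) of a rotation matrix about its axis."""
    arg = (np.trace(rotation) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(arg, -1.0, 1.0))))


def registration_error(t: RigidTransform, t_gt: RigidTransform) -> RegistrationError:
    """Rotation / translation error of ``t`` against ground truth ``t_gt``."""
    delta = t.compose(t_gt.invert())
    return RegistrationError(
        rotation_error_deg=rotation_angle_deg(delta.rotation),
        translation_error_mm=float(np.linalg.norm(delta.translation)),
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian with sign fix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q


def euler_rotation(angles_deg: np.ndarray | tuple[float, float, float]) -> np.ndarray:
    """Rotation from extrinsic x-y-z Euler angles in degrees (Rz @ Ry @ Rx)."""
    ax, ay, az = np.radians(np.asarray(angles_deg, dtype=np.float64))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx
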