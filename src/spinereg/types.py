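"""Core domain types: point clouds, rigid transforms, registration errors.

All coordinates are millimetres throughout the package; no unit conversion
happens anywhere. Rotations are stored as proper orthonormal 3x3 matrices and
validated on construction (fail loudly rather than re-orthonormalize).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Tolerance for the orthonormality / determinant check on rotations.
ROTATION_TOL = 1e-6

SOURCE_TAGS = ("preop", "intraop", "synthetic")


@dataclass
class PointCloud:
    """A 3D surface point cloud in millimetres.

    Parameters
    ----------
    points
        ``(n, 3)`` array of coordinates, ``n >= 1``, all finite.
    features
        Optional ``(n,)`` per-point scalar channel. When produced by the
        curvature module this is the surface-variation value
        ``sigma = lambda_3 / (lambda_1 + lambda_2 + lambda_3)`` and lies in
        ``[0, 1/3]``.
    source_tag
        Free label; conventionally one of ``"preop"``, ``"intraop"``,
        ``"synthetic"``.
    """

    points: np.ndarray
    features: np.ndarray | None = None
    source_tag: str = "synthetic"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (n, 3); got shape {self.points.shape}")
        if len(self.points) < 1:
            raise ValueError("point cloud must contain at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point cloud contains non-finite coordinates")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=np.float64).reshape(-1)
            if len(self.features) != len(self.points):
                raise ValueError(
                    f"features length {len(self.features)} does not match "
                    f"point count {len(self.points)}"
                )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n(self) -> int:
        return len(self.points)

    def subset(self, indices: np.ndarray) -> "PointCloud":
        """Cloud restricted to ``indices`` (features carried through)."""
        idx = np.asarray(indices, dtype=np.intp)
        feats = self.features[idx] if self.features is not None else None
        return PointCloud(self.points[idx], feats, self.source_tag)

    def with_features(self, features: np.ndarray) -> "PointCloud":
        return PointCloud(self.points, features, self.source_tag)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def bounding_sphere_radius(self) -> float:
        """Radius of the centroid-centred bounding sphere (mm)."""
        return float(np.linalg.norm(self.points - self.centroid(), axis=1).max())


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=np.float64)
    if rotation.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3; got shape {rotation.shape}")
    if not np.all(np.isfinite(rotation)):
        raise ValueError("rotation contains non-finite entries")
    err = np.abs(rotation @ rotation.T - np.eye(3)).max()
    if err > ROTATION_TOL:
        raise ValueError(
            f"rotation is not orthonormal (max deviation {err:.3g} > {ROTATION_TOL:g}); "
            "refusing to re-orthonormalize"
        )
    det = np.linalg.det(rotation)
    if abs(det - 1.0) > ROTATION_TOL:
        raise ValueError(f"rotation determinant {det:.9f} != +1; improper rotation rejected")
    return rotation


@dataclass
class RigidTransform:
    """A proper rigid motion ``p -> R p + t`` (rotation in SO(3), t in mm)."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = _check_rotation(self.rotation)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite(self.translation)):
            raise ValueError("translation contains non-finite entries")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (row-major convention)."""
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.shape != (4, 4):
            raise ValueError(f"expected 4x4 homogeneous matrix; got {matrix.shape}")
        if not np.allclose(matrix[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("last row of homogeneous matrix must be [0 0 0 1]")
        return cls(matrix[:3, :3], matrix[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        out = np.eye(4)
        out[:3, :3] = self.rotation
        out[:3, 3] = self.translation
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array (or a single 3-vector) of points."""
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self`` after ``other``: (self ∘ other)(p) = self(other(p))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)


@dataclass
class RegistrationError:
    """Geodesic rotation error e_r (degrees) and translation error e_t (mm)."""

    rotation_error_deg: float
    translation_error_mm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rotation_error_deg <= 180.0 + 1e-9):
            raise ValueError(f"rotation error {self.rotation_error_deg} outside [0, 180] degrees")
        if self.translation_error_mm < 0.0:
            raise ValueError(f"translation error {self.translation_error_mm} is negative")

    def as_tuple(self) -> tuple[float, float]:
        return (self.rotation_error_deg, self.translation_error_mm)
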