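"""Synthetic vertebra-phantom registration pairs with ground truth.

The phantom is a parametric, deliberately non-anatomical stand-in for a CT
reconstructed spine surface. Each vertebra is an ellipsoidal body blended
(smooth-min of signed distance fields) with 1-3 elongated capsule
protrusions — a long "spinous process" and optional transverse processes —
plus a field of smooth Gaussian surface bumps that breaks rotational
symmetry and gives the curvature feature something to discriminate.
Registration pairs stack several vertebrae so that a surgically exposed
spinous-process patch occupies the study's 1.3-4.3% of the pre-operative
points.

A pair emulates the cross-source, low-overlap surgical regime: the
pre-operative cloud samples the whole stack; the intra-operative cloud is an
independently resampled patch around the middle spinous process (the exposed
site), sized so a target fraction of the pre-operative points fall inside
it, resampled at a different density, moved by a random rigid pose
(rotations up to +/-170 degrees per axis, translations up to +/-115 mm) and
optionally perturbed with isotropic Gaussian noise. The stored ground truth
maps intra-operative coordinates back into the pre-operative frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .sampling import median_nn_spacing
from .transforms import euler_rotation
from .types import PointCloud, RigidTransform

DEFAULT_OVERLAP_RANGE = (0.013, 0.043)


# ---------------------------------------------------------------- geometry

@dataclass
class _Capsule:
    p0: np.ndarray
    p1: np.ndarray
    radius: float

    def sdf(self, p: np.ndarray) -> np.ndarray:
        ba = self.p1 - self.p0
        pa = p - self.p0
        h = np.clip((pa @ ba) / (ba @ ba), 0.0, 1.0)
        return np.linalg.norm(pa - h[:, None] * ba, axis=1) - self.radius

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def area(self) -> float:
        return 2 * np.pi * self.radius * self.length + 4 * np.pi * self.radius ** 2


class _VertebraGeometry:
    """Implicit blended surface of one synthetic vertebra, placed in the
    stack frame by ``offset`` and a per-vertebra ``rotation`` (the
    inter-vertebral tilt of a curved spine)."""

    def __init__(self, rng: np.random.Generator, offset: np.ndarray | None = None):
        self.offset = np.zeros(3) if offset is None else np.asarray(offset, dtype=np.float64)
        self.rotation = np.eye(3)
        self.axes = np.array([rng.uniform(18, 23), rng.uniform(13.5, 17), rng.uniform(10.5, 14)])
        ay = self.axes[1]
        # spinous process: long capsule off the -y pole, drooping in z
        length = rng.uniform(15, 20)
        drop = rng.uniform(4, 8)
        self.spinous = _Capsule(
            np.array([0.0, -0.55 * ay, -1.0]),
            np.array([rng.uniform(-2, 2), -(ay + length), -drop]),
            rng.uniform(3.4, 4.2),
        )
        self.capsules = [self.spinous]
        for side in (-1.0, 1.0)[: int(rng.integers(0, 3))]:
            ax = self.axes[0]
            self.capsules.append(_Capsule(
                np.array([side * 0.5 * ax, -2.0, 1.0]),
                np.array([side * (ax + rng.uniform(6, 10)), rng.uniform(-6, 0),
                          rng.uniform(1, 5)]),
                rng.uniform(2.6, 3.2),
            ))
        self.blend_k = 2.0
        # asymmetry bumps anchored on the primitive surfaces
        anchors = self._sample_primitives(600, rng)
        pick = rng.choice(len(anchors), size=40, replace=False)
        self.bump_centers = anchors[pick]
        self.bump_amps = rng.uniform(0.7, 1.5, size=40) * rng.choice([-1.0, 1.0], size=40)
        self.bump_widths = rng.uniform(2.5, 5.0, size=40)

    # ---------------- signed distance field (local frame)
    def _ellipsoid_sdf(self, p: np.ndarray) -> np.ndarray:
        k0 = np.linalg.norm(p / self.axes, axis=1)
        k1 = np.linalg.norm(p / self.axes ** 2, axis=1)
        return np.where(k1 > 0, k0 * (k0 - 1.0) / np.maximum(k1, 1e-12), -self.axes.min())

    def _sdf_local(self, p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(p, dtype=np.float64))
        parts = [self._ellipsoid_sdf(p)] + [c.sdf(p) for c in self.capsules]
        stacked = np.stack(parts)
        k = self.blend_k
        m = stacked.min(axis=0)
        f = m - k * np.log(np.exp(-(stacked - m) / k).sum(axis=0))
        d2 = ((p[:, None, :] - self.bump_centers[None]) ** 2).sum(axis=-1)
        return f - (self.bump_amps * np.exp(-d2 / (2 * self.bump_widths ** 2))).sum(axis=1)

    def sdf(self, p: np.ndarray) -> np.ndarray:
        return self._sdf_local((np.atleast_2d(p) - self.offset) @ self.rotation)

    def _grad_local(self, p: np.ndarray, h: float = 1e-3) -> np.ndarray:
        g = np.empty_like(p)
        for axis in range(3):
            dp = np.zeros(3)
            dp[axis] = h
            g[:, axis] = (self._sdf_local(p + dp) - self._sdf_local(p - dp)) / (2 * h)
        return g

    def _project_local(self, p: np.ndarray, iters: int = 5) -> np.ndarray:
        """Newton projection of points onto the blended isosurface f = 0."""
        p = np.array(p, dtype=np.float64)
        for _ in range(iters):
            f = self._sdf_local(p)
            g = self._grad_local(p)
            gn = np.maximum((g * g).sum(axis=1), 1e-9)
            p -= (f / gn)[:, None] * g
        return p

    # ---------------- surface sampling (local frame helpers)
    def _ellipsoid_area(self) -> float:
        a, b, c = self.axes
        q = 1.6075
        return float(4 * np.pi * (((a * b) ** q + (a * c) ** q + (b * c) ** q) / 3) ** (1 / q))

    @property
    def area(self) -> float:
        return self._ellipsoid_area() + sum(c.area for c in self.capsules)

    def _sample_primitives(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Area-uniform samples on the pre-blend primitive surfaces."""
        areas = [self._ellipsoid_area()] + [c.area for c in self.capsules]
        counts = rng.multinomial(n, np.asarray(areas) / sum(areas))
        out = []
        if counts[0]:
            out.append(self._sample_ellipsoid(counts[0], rng))
        for c, m in zip(self.capsules, counts[1:]):
            if m:
                out.append(self._sample_capsule(c, m, rng))
        return np.concatenate(out, axis=0)

    def _sample_ellipsoid(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a1, a2, a3 = self.axes
        wmax = max(a2 * a3, a1 * a3, a1 * a2)
        pts = []
        need = n
        while need > 0:
            u = rng.normal(size=(3 * need + 16, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            w = np.sqrt((a2 * a3 * u[:, 0]) ** 2 + (a1 * a3 * u[:, 1]) ** 2
                        + (a1 * a2 * u[:, 2]) ** 2)
            keep = u[rng.uniform(0, wmax, size=len(u)) < w]
            pts.append(keep[:need] * self.axes)
            need -= len(keep[:need])
        return np.concatenate(pts, axis=0)

    def _sample_capsule(self, c: _Capsule, n: int, rng: np.random.Generator) -> np.ndarray:
        axis = (c.p1 - c.p0) / c.length
        tmp = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(axis, tmp)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        area_cyl = 2 * np.pi * c.radius * c.length
        n_cyl = rng.binomial(n, area_cyl / c.area)
        theta = rng.uniform(0, 2 * np.pi, size=n_cyl)
        z = rng.uniform(0, c.length, size=n_cyl)
        cyl = (c.p0 + z[:, None] * axis
               + c.radius * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2))
        u = rng.normal(size=(n - n_cyl, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        ends = np.where((u @ axis)[:, None] >= 0, c.p1, c.p0)
        caps = ends + c.radius * u
        return np.concatenate([cyl, caps], axis=0)

    def sample_surface(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """~n area-uniform points on the blended surface (exactly n returned)."""
        collected = []
        total = 0
        attempts = 0
        while total < n and attempts < 50:
            attempts += 1
            raw = self._sample_primitives(int(1.6 * (n - total)) + 64, rng)
            raw = raw[self._sdf_local(raw) > -1.0]  # drop points swallowed by the blend
            proj = self._project_local(raw)
            good = proj[np.abs(self._sdf_local(proj)) < 0.05]
            collected.append(good)
            total += len(good)
        pts = np.concatenate(collected, axis=0)
        if len(pts) < n:
            raise RuntimeError("surface sampling failed to reach the requested count")
        return pts[rng.choice(len(pts), size=n, replace=False)] @ self.rotation.T + self.offset

    @property
    def spinous_tip(self) -> np.ndarray:
        return self.rotation @ self.spinous.p1 + self.offset


class PhantomGeometry:
    """A stack of synthetic vertebrae along the cranio-caudal (z) axis.

    ``n_vertebrae=1`` gives a single vertebra. The stack's ``exposed_tip`` is
    the spinous-process tip of the middle vertebra — the surgically exposed
    site registration pairs crop around.
    """

    def __init__(self, seed: int, n_vertebrae: int = 1, gap_mm: float = 4.0):
        if n_vertebrae < 1:
            raise ValueError("n_vertebrae must be at least 1")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
        self.vertebrae: list[_VertebraGeometry] = []
        z = 0.0
        tilt = np.zeros(3)
        for i in range(n_vertebrae):
            v = _VertebraGeometry(rng)
            if self.vertebrae:
                prev = self.vertebrae[-1]
                z += prev.axes[2] + v.axes[2] + gap_mm
                # physiological curvature: each level tilts further about the
                # lateral (x) axis with small jitter about the other axes
                tilt = tilt + np.array([rng.uniform(5.0, 12.0),
                                        rng.uniform(-3.0, 3.0),
                                        rng.uniform(-3.0, 3.0)])
            v.offset = np.array([0.0, 0.0, z])
            v.rotation = euler_rotation(tilt)
            self.vertebrae.append(v)
        self.middle = self.vertebrae[(n_vertebrae - 1) // 2]

    def sdf(self, p: np.ndarray) -> np.ndarray:
        return np.min(np.stack([v.sdf(p) for v in self.vertebrae]), axis=0)

    @property
    def exposed_tip(self) -> np.ndarray:
        return self.middle.spinous_tip

    def sample_surface(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """~Area-uniform samples over the whole stack (exactly n returned)."""
        areas = np.array([v.area for v in self.vertebrae])
        counts = rng.multinomial(n + min(n // 10, 500), areas / areas.sum())
        parts = [v.sample_surface(c, rng) for v, c in zip(self.vertebrae, counts) if c]
        pts = np.concatenate(parts, axis=0)
        if len(self.vertebrae) > 1:
            pts = pts[self.sdf(pts) > -0.05]  # cull samples swallowed by a neighbor
        if len(pts) < n:
            raise RuntimeError("stack sampling failed to reach the requested count")
        return pts[rng.choice(len(pts), size=n, replace=False)]

    def sample_patch(self, center: np.ndarray, radius: float, n: int,
                     rng: np.random.Generator) -> np.ndarray:
        """n independent surface samples within the ball around ``center``
        (drawn from the middle vertebra, which carries the exposed process)."""
        chunks: list[np.ndarray] = []
        got = 0
        for _ in range(200):
            if got >= n:
                break
            batch = self.middle.sample_surface(max(4000, 4 * (n - got)), rng)
            inside = batch[np.linalg.norm(batch - center, axis=1) <= radius]
            if len(self.vertebrae) > 1 and len(inside):
                inside = inside[self.sdf(inside) > -0.05]
            chunks.append(inside)
            got += len(inside)
        pts = np.concatenate(chunks, axis=0)
        if len(pts) < n:
            raise RuntimeError("could not collect enough patch samples")
        return pts[:n]


# ---------------------------------------------------------------- specs

@dataclass
class PairSpec:
    """Study conditions for one synthetic registration pair."""

    seed: int = 0
    n_preop: int = 16000
    n_intraop: int | None = None
    n_vertebrae: int = 4
    overlap_target: float | None = None      # None: drawn from 1.3-4.3%
    rotation_range_deg: float = 170.0
    translation_range_mm: float = 115.0
    noise_sigma_mm: float = 0.0
    density_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.overlap_target is not None and not (0 < self.overlap_target <= 1):
            raise ValueError("overlap_target must lie in (0, 1]")
        if self.noise_sigma_mm < 0:
            raise ValueError("noise_sigma_mm must be non-negative")
        if self.density_ratio <= 0:
            raise ValueError("density_ratio must be positive")


@dataclass
class SyntheticPair:
    preop: PointCloud
    intraop: PointCloud
    ground_truth: RigidTransform     # maps intraop coordinates into the preop frame
    achieved_overlap: float
    spec: PairSpec | None = None


# ---------------------------------------------------------------- operations

def make_phantom(seed: int, n_points: int = 6000, n_vertebrae: int = 1) -> PointCloud:
    """Deterministic vertebra-phantom surface cloud (mm)."""
    if n_points < 500:
        raise ValueError("n_points must be at least 500")
    geom = PhantomGeometry(seed, n_vertebrae)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    return PointCloud(geom.sample_surface(n_points, rng), source_tag="synthetic")


def add_noise(cloud: PointCloud, sigma_mm: float, rng: np.random.Generator) -> PointCloud:
    """Isotropic per-coordinate Gaussian perturbation."""
    if sigma_mm == 0:
        return cloud
    return PointCloud(cloud.points + rng.normal(0.0, sigma_mm, size=cloud.points.shape),
                      cloud.features, cloud.source_tag)


def draw_pose(spec: PairSpec, rng: np.random.Generator
              ) -> tuple[RigidTransform, np.ndarray]:
    """The random initial pose of a pair: per-axis Euler rotations and
    translations drawn uniformly within the configured ranges."""
    angles = rng.uniform(-spec.rotation_range_deg, spec.rotation_range_deg, size=3)
    translation = rng.uniform(-spec.translation_range_mm, spec.translation_range_mm,
                              size=3)
    return RigidTransform(euler_rotation(angles), translation), angles


def make_pair(spec: PairSpec) -> SyntheticPair:
    """Generate one cross-source, low-overlap registration pair."""
    geom = PhantomGeometry(spec.seed, spec.n_vertebrae)
    ss = np.random.SeedSequence([spec.seed, 2])
    rng_pre, rng_target, rng_intra, rng_pose, rng_noise = (
        np.random.default_rng(c) for c in ss.spawn(5))
    preop_pts = geom.sample_surface(spec.n_preop, rng_pre)

    target = spec.overlap_target
    if target is None:
        target = float(rng_target.uniform(*DEFAULT_OVERLAP_RANGE))
    m = int(round(target * spec.n_preop))
    m_max = spec.n_preop // 3
    if m < 8 or m > m_max:
        lo, hi = 8 / spec.n_preop, m_max / spec.n_preop
        raise ValueError(
            f"overlap_target {target:.4f} unreachable at n_preop={spec.n_preop}; "
            f"feasible range is [{lo:.4f}, {hi:.4f}]")

    tree = cKDTree(preop_pts)
    _, tip_i = tree.query(geom.exposed_tip)
    center = preop_pts[tip_i]
    dists, _ = tree.query(center, k=m)
    r_patch = float(np.atleast_1d(dists)[-1])

    if spec.density_ratio == 1.0 and spec.n_intraop is None:
        idx = np.asarray(tree.query_ball_point(center, r_patch * (1 + 1e-12)), dtype=np.intp)
        base = preop_pts[np.sort(idx)]
    else:
        n_intra = spec.n_intraop or int(round(spec.density_ratio * m))
        base = geom.sample_patch(center, r_patch, n_intra, rng_intra)

    pose, angles = draw_pose(spec, rng_pose)
    intraop_pts = pose.apply(base)
    if spec.noise_sigma_mm > 0:
        intraop_pts = intraop_pts + rng_noise.normal(0.0, spec.noise_sigma_mm,
                                                     size=intraop_pts.shape)
    preop = PointCloud(preop_pts, source_tag="preop")
    intraop = PointCloud(intraop_pts, source_tag="intraop")
    ground_truth = pose.invert()
    achieved = overlap_ratio(preop, intraop, ground_truth)
    if abs(achieved / target - 1.0) > 0.3:
        warnings.warn(
            f"achieved overlap {achieved:.4f} deviates more than 30% from target {target:.4f}")
    return SyntheticPair(preop, intraop, ground_truth, achieved, spec)


def overlap_ratio(preop: PointCloud, intraop: PointCloud, t_gt: RigidTransform,
                  tau: float | None = None) -> float:
    """Fraction of pre-operative points with a transformed intra-operative
    point within ``tau`` mm (default: 2x the preop median NN spacing)."""
    if tau is None:
        tau = 2.0 * median_nn_spacing(preop.points)
    if tau <= 0:
        raise ValueError("tau must be positive")
    moved = t_gt.apply(intraop.points)
    d, _ = cKDTree(moved).query(preop.points, distance_upper_bound=tau * (1 + 1e-12))
    return float(np.mean(np.isfinite(d) & (d <= tau)))
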