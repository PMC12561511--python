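"""Farthest point sampling, local-region decomposition, density equalization.

The pre-operative cloud is decomposed into candidate local regions: greedy
farthest point sampling (FPS) picks ``k`` well-spread sample points and each
region is the closed ball of radius ``r`` around one sample. Cross-source
density mismatch is removed by voxel-grid down-sampling of the denser cloud
until its median nearest-neighbor spacing is within 20% of the reference's.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .types import PointCloud

logger = logging.getLogger(__name__)


@dataclass
class LocalRegionSet:
    """FPS sample points and their closed-ball index regions into a cloud."""

    sample_points: np.ndarray          # (k, 3)
    regions: list[np.ndarray] = field(default_factory=list)  # index arrays
    region_radius: float = 0.0

    def __post_init__(self) -> None:
        self.sample_points = np.asarray(self.sample_points, dtype=np.float64)
        if self.sample_points.ndim != 2 or self.sample_points.shape[1] != 3:
            raise ValueError("sample_points must be (k, 3)")
        if len(self.sample_points) < 1:
            raise ValueError("need at least one sample point")
        if len(self.regions) != len(self.sample_points):
            raise ValueError("one region per sample point required")
        self.regions = [np.asarray(r, dtype=np.intp) for r in self.regions]
        for i, r in enumerate(self.regions):
            if len(r) == 0:
                raise ValueError(f"region {i} is empty")

    def __len__(self) -> int:
        return len(self.sample_points)


def farthest_point_sample(cloud: PointCloud | np.ndarray, k: int,
                          seed_index: int = 0) -> np.ndarray:
    """Greedy max-min FPS: ``k`` distinct indices in selection order.

    The first index is ``seed_index``; each next index maximizes the minimum
    distance to the already-selected set, ties broken by lowest index.
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, dtype=np.float64)
    n = len(pts)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, n={n}]")
    if not 0 <= seed_index < n:
        raise ValueError(f"seed_index {seed_index} outside [0, {n})")
    selected = np.empty(k, dtype=np.intp)
    selected[0] = seed_index
    min_d2 = np.sum((pts - pts[seed_index]) ** 2, axis=1)
    for i in range(1, k):
        nxt = int(np.argmax(min_d2))  # argmax returns the lowest tied index
        selected[i] = nxt
        d2 = np.sum((pts - pts[nxt]) ** 2, axis=1)
        np.minimum(min_d2, d2, out=min_d2)
    return selected


def extract_regions(cloud: PointCloud, k: int, region_radius: float,
                    seed_index: int = 0) -> LocalRegionSet:
    """FPS samples plus their closed-ball (<= r) neighborhoods as regions."""
    if region_radius <= 0:
        raise ValueError("region_radius must be positive")
    sample_idx = farthest_point_sample(cloud, k, seed_index)
    samples = cloud.points[sample_idx]
    tree = cKDTree(cloud.points)
    regions = []
    for s in samples:
        cand = np.asarray(tree.query_ball_point(s, region_radius * (1 + 1e-12)), dtype=np.intp)
        d = np.linalg.norm(cloud.points[cand] - s, axis=1)
        regions.append(np.sort(cand[d <= region_radius]))
    return LocalRegionSet(samples, regions, region_radius)


def median_nn_spacing(points: np.ndarray) -> float:
    """Median distance to the nearest distinct neighbor (mm)."""
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 2:
        raise ValueError("spacing undefined for fewer than 2 points")
    d, _ = cKDTree(pts).query(pts, k=2)
    return float(np.median(d[:, 1]))


def voxel_downsample(cloud: PointCloud, voxel_size: float) -> PointCloud:
    """Deterministic voxel-grid down-sampling.

    Each voxel is represented by its medoid (the member point nearest the
    voxel centroid), so output points remain actual surface samples and the
    feature channel carries through untouched. Output ordered by voxel key.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    pts = cloud.points
    keys = np.floor((pts - pts.min(axis=0)) / voxel_size).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    m = len(counts)
    acc = np.zeros((m, 3))
    np.add.at(acc, inverse, pts)
    acc /= counts[:, None]
    d2 = np.sum((pts - acc[inverse]) ** 2, axis=1)
    # medoid per voxel: lowest d2, ties by lowest point index
    order = np.lexsort((np.arange(len(pts)), d2, inverse))
    first = np.searchsorted(inverse[order], np.arange(m))
    medoid = np.sort(order[first])
    return cloud.subset(medoid)


def equalize_density(dense: PointCloud, reference: PointCloud,
                     tolerance: float = 0.2, max_bisect: int = 20) -> PointCloud:
    """Down-sample ``dense`` until its median NN spacing matches ``reference``.

    The voxel edge is bisected until the spacing ratio lies within
    ``1 +/- tolerance``. If the reference spacing cannot be reached (the
    reference is denser than ``dense``, or degenerate), ``dense`` is returned
    unchanged with a warning.
    """
    if len(reference) < 2 or len(dense) < 2:
        warnings.warn("equalize_density: degenerate cloud; returning dense unchanged")
        return dense
    s_ref = median_nn_spacing(reference.points)
    s_dense = median_nn_spacing(dense.points)
    if s_dense >= (1 - tolerance) * s_ref:
        if s_dense > (1 + tolerance) * s_ref:
            warnings.warn(
                f"equalize_density: dense cloud spacing {s_dense:.3g} mm already coarser "
                f"than reference {s_ref:.3g} mm; cannot up-sample, returning unchanged"
            )
        return dense
    lo, hi = 0.25 * s_ref, 4.0 * s_ref
    best, best_err = dense, abs(s_dense / s_ref - 1.0)
    for _ in range(max_bisect):
        v = 0.5 * (lo + hi)
        cand = voxel_downsample(dense, v)
        if len(cand) < 2:
            hi = v
            continue
        ratio = median_nn_spacing(cand.points) / s_ref
        err = abs(ratio - 1.0)
        if err < best_err:
            best, best_err = cand, err
        if err <= tolerance * 0.5:
            break
        if ratio < 1.0:
            lo = v
        else:
            hi = v
    if best_err > tolerance:
        warnings.warn(
            f"equalize_density: best achievable spacing ratio off by {best_err:.2%}; "
            "returning closest match"
        )
    return best
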