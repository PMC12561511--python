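"""Surface-variation curvature from local covariance eigenvalues.

For each point the covariance of its radius neighborhood (query point
included, neighborhood centroid as mean) is formed and its eigenvalues
``lambda_1 >= lambda_2 >= lambda_3 >= 0`` computed. The curvature feature is

    sigma = lambda_3 / (lambda_1 + lambda_2 + lambda_3)  in  [0, 1/3]

— 0 on a locally planar patch, 1/3 for an isotropic neighborhood. The ratio
is invariant to rigid motion and uniform scaling. Points with fewer than
``min_neighbors`` neighbors are assigned sigma = 0 (flat prior); their count
is logged per cloud.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .types import PointCloud

logger = logging.getLogger(__name__)


@dataclass
class CurvatureConfig:
    """Neighborhood for the covariance: radius in mm (default 5) and the
    minimum neighbor count below which sigma falls back to 0."""

    neighborhood_radius: float = 5.0
    min_neighbors: int = 5

    def __post_init__(self) -> None:
        if self.neighborhood_radius <= 0:
            raise ValueError("neighborhood_radius must be positive")
        if self.min_neighbors < 3:
            raise ValueError("min_neighbors must be at least 3")


def surface_variation(neighborhood: np.ndarray) -> float:
    """sigma of one neighborhood given as an (k, 3) array of points."""
    pts = np.asarray(neighborhood, dtype=np.float64)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    evals = np.linalg.eigvalsh(cov)  # ascending
    total = evals.sum()
    if total <= 0.0:
        return 0.0
    return float(max(evals[0], 0.0) / total)


def compute_curvature(cloud: PointCloud, cfg: CurvatureConfig | None = None) -> PointCloud:
    """Return a copy of ``cloud`` with sigma in the feature channel.

    The neighborhood scatter matrices are accumulated with bincounts over
    the flattened neighbor lists, so dense clouds stay fast.
    """
    cfg = cfg or CurvatureConfig()
    pts = cloud.points
    n = len(pts)
    tree = cKDTree(pts)
    neighbor_lists = tree.query_ball_point(pts, cfg.neighborhood_radius)
    counts = np.fromiter((len(l) for l in neighbor_lists), dtype=np.int64, count=n)
    owner = np.repeat(np.arange(n), counts)
    flat = np.fromiter((j for l in neighbor_lists for j in l),
                       dtype=np.int64, count=counts.sum())
    nb = pts[flat]
    sums = np.stack([np.bincount(owner, weights=nb[:, a], minlength=n)
                     for a in range(3)], axis=1)                      # (n, 3)
    prods = np.stack([np.bincount(owner, weights=nb[:, a] * nb[:, b], minlength=n)
                      for a in range(3) for b in range(a, 3)], axis=1)  # (n, 6)
    mu = sums / np.maximum(counts, 1)[:, None]
    cov = np.empty((n, 3, 3))
    pairs = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
    for col, (a, b) in enumerate(pairs):
        val = prods[:, col] - counts * mu[:, a] * mu[:, b]
        cov[:, a, b] = val
        cov[:, b, a] = val
    evals = np.linalg.eigvalsh(cov)  # ascending, batched
    total = evals.sum(axis=1)
    sigma = np.where(total > 0, np.maximum(evals[:, 0], 0.0) / np.where(total > 0, total, 1.0), 0.0)
    degenerate = counts < cfg.min_neighbors
    sigma[degenerate] = 0.0
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.info(
            "curvature: %d/%d points had < %d neighbors within %.3g mm (sigma set to 0)",
            n_degenerate, len(pts), cfg.min_neighbors, cfg.neighborhood_radius,
        )
    return cloud.with_features(sigma)


def smooth_field(points: np.ndarray, values: np.ndarray, radius: float) -> np.ndarray:
    """Neighborhood-average a per-point scalar field (variance reduction for
    estimators computed from finite samplings)."""
    if radius <= 0:
        return np.asarray(values, dtype=np.float64)
    tree = cKDTree(points)
    out = np.empty(len(points))
    for i, idx in enumerate(tree.query_ball_point(points, radius)):
        out[i] = values[idx].mean()
    return out


def ensure_curvature(cloud: PointCloud, cfg: CurvatureConfig | None = None) -> PointCloud:
    """Compute curvature unless the cloud already carries a feature channel."""
    if cloud.features is not None:
        return cloud
    return compute_curvature(cloud, cfg)
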