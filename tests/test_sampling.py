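"""FPS, local-region extraction and density equalization against brute-force
oracles."""

import numpy as np
import pytest

import spinereg as sr
from spinereg.sampling import (equalize_density, extract_regions,
                               farthest_point_sample, median_nn_spacing,
                               voxel_downsample)


def brute_force_fps(pts: np.ndarray, k: int, seed_index: int) -> list[int]:
    """Greedy max-min selection scanning every candidate, ties by lowest index."""
    chosen = [seed_index]
    while len(chosen) < k:
        best, best_d = None, -1.0
        for i in range(len(pts)):
            if i in chosen:
                continue
            d = min(np.linalg.norm(pts[i] - pts[j]) for j in chosen)
            if d > best_d + 1e-12:
                best, best_d = i, d
        chosen.append(best)
    return chosen


class TestFPS:
    def test_k_equals_n_covers_all(self, rng):
        pts = rng.normal(size=(12, 3))
        idx = farthest_point_sample(pts, 12)
        assert sorted(idx) == list(range(12))

    def test_collinear_points_tie_break(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        idx = farthest_point_sample(pts, 3, seed_index=0)
        # 0, far end 9, then midpoint: positions 4 and 5 tie, lowest index wins
        assert list(idx) == [0, 9, 4]

    def test_single_sample(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0]])
        assert list(farthest_point_sample(pts, 1, seed_index=0)) == [0]

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(8):
            n = int(rng.integers(5, 20))
            pts = rng.normal(size=(n, 3))
            k = int(rng.integers(2, n + 1))
            assert list(farthest_point_sample(pts, k)) == brute_force_fps(pts, k, 0)

    def test_k_out_of_range(self, rng):
        pts = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            farthest_point_sample(pts, 6)
        with pytest.raises(ValueError):
            farthest_point_sample(pts, 0)

    def test_permutation_robust_up_to_seed_point(self, rng):
        pts = rng.normal(size=(30, 3))
        perm = rng.permutation(30)
        idx_orig = farthest_point_sample(pts, 8, seed_index=0)
        seed_new = int(np.nonzero(perm == 0)[0][0])
        idx_perm = farthest_point_sample(pts[perm], 8, seed_index=seed_new)
        assert np.array_equal(perm[idx_perm], idx_orig)

    def test_maxmin_beats_random_subsets(self, rng):
        pts = rng.normal(size=(80, 3))
        k = 8

        def maxmin(sub):
            d = np.linalg.norm(pts[sub][:, None] - pts[sub][None], axis=-1)
            np.fill_diagonal(d, np.inf)
            return d.min(axis=1).min()

        fps_score = maxmin(farthest_point_sample(pts, k))
        for _ in range(50):
            rand = rng.choice(80, size=k, replace=False)
            assert fps_score >= maxmin(rand) - 1e-12


class TestRegions:
    def test_radius_covering_whole_cloud(self, rng):
        cloud = sr.PointCloud(rng.normal(size=(40, 3)))
        diameter = np.linalg.norm(
            cloud.points[:, None] - cloud.points[None], axis=-1).max()
        regions = extract_regions(cloud, 3, diameter)
        for r in regions.regions:
            assert len(r) == 40

    def test_point_beyond_radius_excluded(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [5.001, 0, 0]])
        regions = extract_regions(sr.PointCloud(pts), 1, 5.0, seed_index=0)
        assert 2 not in regions.regions[0]

    def test_membership_matches_brute_force(self, rng):
        cloud = sr.PointCloud(rng.normal(scale=5, size=(200, 3)))
        regions = extract_regions(cloud, 5, 4.0)
        for sample, idx in zip(regions.sample_points, regions.regions):
            d = np.linalg.norm(cloud.points - sample, axis=1)
            assert np.array_equal(np.sort(idx), np.nonzero(d <= 4.0)[0])

    def test_each_region_contains_its_sample(self, rng):
        cloud = sr.PointCloud(rng.normal(size=(60, 3)))
        regions = extract_regions(cloud, 6, 0.5)
        for sample, idx in zip(regions.sample_points, regions.regions):
            assert any(np.allclose(cloud.points[i], sample) for i in idx)

    def test_union_covers_cloud_when_fps_spacing_small(self, rng):
        cloud = sr.PointCloud(rng.uniform(0, 10, size=(150, 3)))
        idx = farthest_point_sample(cloud, 30)
        d = np.linalg.norm(cloud.points[:, None] - cloud.points[idx][None], axis=-1)
        maxmin = d.min(axis=1).max()
        regions = extract_regions(cloud, 30, maxmin + 1e-9)
        assert len(np.unique(np.concatenate(regions.regions))) == 150

    def test_invalid_radius(self, rng):
        with pytest.raises(ValueError):
            extract_regions(sr.PointCloud(rng.normal(size=(10, 3))), 2, 0.0)


class TestEqualizeDensity:
    def test_same_cloud_left_unchanged(self, rng):
        cloud = sr.PointCloud(rng.uniform(0, 20, size=(300, 3)))
        out = equalize_density(cloud, cloud)
        ratio = median_nn_spacing(out.points) / median_nn_spacing(cloud.points)
        assert 0.8 <= ratio <= 1.25

    def test_oversampled_cloud_downsampled_to_reference(self, phantom, rng):
        dense = sr.PointCloud(np.vstack([
            phantom.points + rng.normal(scale=0.05, size=phantom.points.shape)
            for _ in range(10)]))
        out = equalize_density(dense, phantom)
        ratio = median_nn_spacing(out.points) / median_nn_spacing(phantom.points)
        assert 0.8 <= ratio <= 1.25
        assert len(out) < len(dense)

    def test_single_point_reference_warns(self, rng):
        dense = sr.PointCloud(rng.normal(size=(100, 3)))
        ref = sr.PointCloud(np.zeros((1, 3)))
        with pytest.warns(UserWarning, match="degenerate"):
            out = equalize_density(dense, ref)
        assert out is dense

    def test_sparser_than_reference_warns_and_returns_unchanged(self, rng):
        sparse = sr.PointCloud(rng.uniform(0, 100, size=(50, 3)))
        ref = sr.PointCloud(rng.uniform(0, 10, size=(500, 3)))
        with pytest.warns(UserWarning, match="coarser"):
            out = equalize_density(sparse, ref)
        assert out is sparse


def test_voxel_downsample_returns_input_subset(phantom):
    out = voxel_downsample(phantom, 3.0)
    assert len(out) < len(phantom)
    # medoid representatives are actual input points
    view = {tuple(p) for p in np.round(phantom.points, 9)}
    assert all(tuple(p) in view for p in np.round(out.points, 9))


def test_voxel_downsample_deterministic(phantom):
    a = voxel_downsample(phantom, 2.0)
    b = voxel_downsample(phantom, 2.0)
    assert np.array_equal(a.points, b.points)
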