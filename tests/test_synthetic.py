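"""Phantom generator: determinism, overlap control, noise model, pose ranges."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import spinereg as sr
from spinereg.curvature import compute_curvature
from spinereg.synthetic import (DEFAULT_OVERLAP_RANGE, PairSpec, add_noise,
                                draw_pose, make_pair, make_phantom, overlap_ratio)
from spinereg.transforms import registration_error


class TestPhantom:
    def test_deterministic(self):
        a = make_phantom(seed=5, n_points=900)
        b = make_phantom(seed=5, n_points=900)
        assert np.array_equal(a.points, b.points)

    def test_point_count_exact(self):
        assert len(make_phantom(seed=2, n_points=731)) == 731

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            make_phantom(seed=0, n_points=100)

    def test_curvature_spread(self, phantom):
        sigma = compute_curvature(phantom).features
        assert sigma.max() - sigma.min() >= 0.05

    def test_different_seeds_differ(self):
        a = make_phantom(seed=1, n_points=800)
        b = make_phantom(seed=2, n_points=800)
        assert not np.array_equal(a.points, b.points)


class TestMakePair:
    def test_bit_identical_under_seed(self):
        spec = PairSpec(seed=8, n_preop=3000)
        a, b = make_pair(spec), make_pair(spec)
        assert np.array_equal(a.preop.points, b.preop.points)
        assert np.array_equal(a.intraop.points, b.intraop.points)
        assert np.array_equal(a.ground_truth.matrix, b.ground_truth.matrix)
        assert a.achieved_overlap == b.achieved_overlap

    def test_identity_pose_unit_density_gives_exact_subset(self):
        spec = PairSpec(seed=9, n_preop=3000, overlap_target=0.03,
                        density_ratio=1.0, rotation_range_deg=1e-12,
                        translation_range_mm=1e-12, noise_sigma_mm=0.0)
        pair = make_pair(spec)
        d, _ = cKDTree(pair.preop.points).query(pair.intraop.points)
        assert d.max() < 1e-9

    def test_ground_truth_maps_intraop_onto_preop_surface(self, small_pair):
        err = registration_error(small_pair.ground_truth, small_pair.ground_truth)
        assert err.rotation_error_deg < 1e-5
        moved = small_pair.ground_truth.apply(small_pair.intraop.points)
        d, _ = cKDTree(small_pair.preop.points).query(moved)
        assert np.median(d) < 2.0  # resampled patch sits on the sampled surface

    @pytest.mark.parametrize("seed", range(6))
    def test_achieved_overlap_near_target(self, seed):
        spec = PairSpec(seed=200 + seed, n_preop=4000, overlap_target=0.03)
        pair = make_pair(spec)
        assert abs(pair.achieved_overlap / 0.03 - 1.0) <= 0.3

    def test_unreachable_overlap_names_feasible_range(self):
        with pytest.raises(ValueError, match="feasible range"):
            make_pair(PairSpec(seed=0, n_preop=3000, overlap_target=0.001))

    def test_noise_variance_matches_sigma(self, rng):
        cloud = sr.PointCloud(np.zeros((4000, 3)))
        sigma = 0.75
        noisy = add_noise(cloud, sigma, rng)
        var = noisy.points.var(axis=0)
        assert np.all(np.abs(var / sigma ** 2 - 1.0) < 0.1)

    def test_noise_free_pair_lies_on_surface(self):
        spec = PairSpec(seed=3, n_preop=3000, noise_sigma_mm=0.5)
        noisy = make_pair(spec)
        clean = make_pair(PairSpec(seed=3, n_preop=3000, noise_sigma_mm=0.0))
        # same geometry and pose, only the perturbation differs
        assert np.array_equal(noisy.ground_truth.matrix, clean.ground_truth.matrix)
        assert not np.array_equal(noisy.intraop.points, clean.intraop.points)


def test_pose_distribution_coverage():
    spec = PairSpec(seed=0)
    mags = []
    trans = []
    for s in range(200):
        rng = np.random.default_rng(s)
        pose, angles = draw_pose(spec, rng)
        mags.append(np.abs(angles))
        trans.append(np.abs(pose.invert().translation))
    mags, trans = np.array(mags), np.array(trans)
    assert mags.min() <= 10.0 and mags.max() >= 150.0
    assert trans.min() <= 10.0 and trans.max() >= 100.0
    assert np.all(mags <= spec.rotation_range_deg)


class TestOverlapRatio:
    def test_identical_clouds_full_overlap(self, phantom):
        ident = sr.RigidTransform.identity()
        assert overlap_ratio(phantom, phantom, ident) == 1.0

    def test_exact_half(self, phantom):
        half = phantom.subset(np.arange(len(phantom) // 2))
        ident = sr.RigidTransform.identity()
        ratio = overlap_ratio(phantom, half, ident)
        # every kept point covers itself; nearby dropped points may fall
        # inside tau of a kept one, so the ratio is at least one half
        assert ratio >= 0.5

    def test_disjoint_half_is_exact(self, rng):
        pts = rng.uniform(0, 100, size=(400, 3))
        cloud = sr.PointCloud(pts)
        half = sr.PointCloud(pts[:200])
        ratio = overlap_ratio(cloud, half, sr.RigidTransform.identity(), tau=1e-6)
        assert ratio == pytest.approx(0.5)

    def test_matches_brute_force(self, rng):
        preop = sr.PointCloud(rng.uniform(0, 30, size=(150, 3)))
        crop = sr.PointCloud(rng.uniform(0, 30, size=(40, 3)))
        tau = 3.0
        ident = sr.RigidTransform.identity()
        got = overlap_ratio(preop, crop, ident, tau=tau)
        d = np.linalg.norm(preop.points[:, None] - crop.points[None], axis=-1)
        expected = np.mean(d.min(axis=1) <= tau)
        assert got == pytest.approx(expected)

    def test_tau_must_be_positive(self, phantom):
        with pytest.raises(ValueError):
            overlap_ratio(phantom, phantom, sr.RigidTransform.identity(), tau=0.0)


def test_spec_validation():
    with pytest.raises(ValueError):
        PairSpec(overlap_target=0.0)
    with pytest.raises(ValueError):
        PairSpec(noise_sigma_mm=-0.1)
    with pytest.raises(ValueError):
        PairSpec(density_ratio=0.0)
    assert DEFAULT_OVERLAP_RANGE == (0.013, 0.043)
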