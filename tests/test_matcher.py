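"""Curvature-feature matcher: softmax matching, correspondence extraction,
encoder contracts, attention behavior, and a miniature training run."""

import numpy as np
import pytest

import spinereg as sr
from spinereg.curvature import compute_curvature
from spinereg.matcher import (CurvatureMatcher, EncoderConfig, KeypointSet,
                              MatchMatrix, SALayerConfig, TrainingConfig,
                              attend, encode, extract_correspondences,
                              load_model, match, save_model,
                              small_encoder_config, small_training_config,
                              train)


def tiny_config() -> EncoderConfig:
    return EncoderConfig(
        sa_layers=(SALayerConfig(48, 6.0, (8, 16)), SALayerConfig(24, 12.0, (16, 16)),
                   SALayerConfig(8, 24.0, (16, 16))),
        fp_mlp_widths=(16,), feature_dim=16, attention_heads=2, attention_blocks=1,
        group_size=8, points_per_cloud=256)


@pytest.fixture(scope="module")
def model():
    return CurvatureMatcher(tiny_config(), seed=0)


@pytest.fixture(scope="module")
def curved_phantom():
    return compute_curvature(sr.make_phantom(seed=3, n_points=800))


class TestMatch:
    def test_single_keypoint(self):
        kp = KeypointSet(np.zeros((1, 3)), np.ones((1, 4)))
        phi = match(kp, kp, temperature=1.0)
        assert np.allclose(phi.probabilities, [[1.0]])

    def test_identical_features_give_uniform_rows(self, rng):
        feats = np.tile(rng.normal(size=4), (6, 1))
        kp = KeypointSet(rng.normal(size=(6, 3)), feats)
        phi = match(kp, kp, temperature=0.5)
        assert np.allclose(phi.probabilities, 1 / 6)

    def test_two_by_two_closed_form(self):
        # dot products [[2,0],[0,2]] at T=1: diagonal = e^2/(e^2+1)
        f_src = np.array([[2.0, 0.0], [0.0, 2.0]])
        f_tgt = np.eye(2)
        phi = match(KeypointSet(np.zeros((2, 3)), f_src),
                    KeypointSet(np.zeros((2, 3)), f_tgt), temperature=1.0)
        expected = np.exp(2) / (np.exp(2) + 1)
        assert phi.probabilities[0, 0] == pytest.approx(expected, abs=1e-12)
        assert phi.probabilities[1, 1] == pytest.approx(expected, abs=1e-12)

    def test_rows_stochastic(self, rng):
        phi = match(KeypointSet(rng.normal(size=(9, 3)), rng.normal(size=(9, 8))),
                    KeypointSet(rng.normal(size=(7, 3)), rng.normal(size=(7, 8))),
                    temperature=0.1)
        assert np.abs(phi.probabilities.sum(axis=1) - 1.0).max() < 1e-6
        assert phi.probabilities.min() >= 0.0

    def test_permuting_targets_permutes_columns(self, rng):
        src = KeypointSet(rng.normal(size=(5, 3)), rng.normal(size=(5, 6)))
        tgt_feats = rng.normal(size=(8, 6))
        tgt_pts = rng.normal(size=(8, 3))
        perm = rng.permutation(8)
        phi = match(src, KeypointSet(tgt_pts, tgt_feats), 0.3)
        phi_perm = match(src, KeypointSet(tgt_pts[perm], tgt_feats[perm]), 0.3)
        assert np.allclose(phi_perm.probabilities, phi.probabilities[:, perm])

    def test_temperature_must_be_positive(self, rng):
        kp = KeypointSet(rng.normal(size=(3, 3)), rng.normal(size=(3, 4)))
        with pytest.raises(ValueError):
            match(kp, kp, temperature=0.0)

    def test_match_matrix_validates_rows(self):
        with pytest.raises(ValueError, match="sum"):
            MatchMatrix(np.array([[0.5, 0.4]]), 1.0)


class TestExtractCorrespondences:
    def test_diagonal_dominant_gives_identity_pairs(self, rng):
        n = 6
        p = np.full((n, n), 0.01)
        np.fill_diagonal(p, 1.0)
        p /= p.sum(axis=1, keepdims=True)
        phi = MatchMatrix(p, 1.0)
        kp = KeypointSet(rng.normal(size=(n, 3)), rng.normal(size=(n, 4)))
        corr = extract_correspondences(phi, kp, kp, min_prob=0.0)
        assert np.array_equal(corr, np.column_stack([np.arange(n), np.arange(n)]))

    def test_uniform_matrix_with_high_threshold_is_empty(self, rng):
        n = 5
        phi = MatchMatrix(np.full((n, n), 1 / n), 1.0)
        kp = KeypointSet(rng.normal(size=(n, 3)), rng.normal(size=(n, 4)))
        corr = extract_correspondences(phi, kp, kp, min_prob=1 / n + 0.01)
        assert len(corr) == 0

    def test_matches_brute_force_mutual_argmax(self, rng):
        for _ in range(10):
            p = rng.uniform(size=(8, 8))
            p /= p.sum(axis=1, keepdims=True)
            phi = MatchMatrix(p, 1.0)
            kp = KeypointSet(rng.normal(size=(8, 3)), rng.normal(size=(8, 4)))
            corr = extract_correspondences(phi, kp, kp, min_prob=0.1)
            expected = []
            for i in range(8):
                j = int(np.argmax(p[i]))
                if int(np.argmax(p[:, j])) == i and p[i, j] >= 0.1:
                    expected.append((i, j))
            assert [tuple(c) for c in corr] == expected


class TestEncode:
    def test_requires_curvature(self, model):
        cloud = sr.make_phantom(seed=5, n_points=600)
        with pytest.raises(ValueError, match="curvature"):
            encode(cloud, model)

    def test_deterministic(self, model, curved_phantom):
        a = encode(curved_phantom, model)
        b = encode(curved_phantom, model)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.features, b.features)

    def test_keypoint_count_and_subset(self, model, curved_phantom):
        kp = encode(curved_phantom, model)
        assert len(kp) == model.cfg.sa_layers[0].n_out
        assert kp.features.shape == (len(kp), model.cfg.feature_dim)
        cloud_set = {tuple(p) for p in curved_phantom.points}
        assert all(tuple(p) in cloud_set for p in kp.coords)

    def test_cloud_below_sa3_size_rejected(self, model, rng):
        small = sr.PointCloud(rng.normal(size=(5, 3)), rng.uniform(size=5))
        with pytest.raises(ValueError, match="smaller"):
            encode(small, model)

    def test_curvature_inputs_rigid_invariant(self, model, curved_phantom, rng):
        """Descriptors transfer across rigid motion: encoding a moved copy
        yields identical features at the matching keypoints."""
        from conftest import random_rigid
        t = random_rigid(rng)
        moved = sr.apply_transform(curved_phantom, t)
        kp_a = encode(curved_phantom, model)
        kp_b = encode(moved, model)
        # FPS seeding is index-based, so keypoints correspond 1:1
        assert np.abs(t.apply(kp_a.coords) - kp_b.coords).max() < 1e-6
        assert np.abs(kp_a.features - kp_b.features).max() < 1e-6


class TestAttend:
    def test_coordinates_unchanged(self, model, curved_phantom, rng):
        kp = encode(curved_phantom, model)
        other = KeypointSet(rng.normal(size=(10, 3)),
                            rng.normal(size=(10, model.cfg.feature_dim)))
        out_a, out_b = attend(kp, other, model)
        assert np.array_equal(out_a.coords, kp.coords)
        assert np.array_equal(out_b.coords, other.coords)

    def test_swap_symmetry(self, model, rng):
        d = model.cfg.feature_dim
        a = KeypointSet(rng.normal(size=(6, 3)), rng.normal(size=(6, d)))
        b = KeypointSet(rng.normal(size=(9, 3)), rng.normal(size=(9, d)))
        ab = attend(a, b, model)
        ba = attend(b, a, model)
        assert np.allclose(ab[0].features, ba[1].features)
        assert np.allclose(ab[1].features, ba[0].features)

    def test_cross_dependence(self, model, rng):
        d = model.cfg.feature_dim
        a = KeypointSet(rng.normal(size=(6, 3)), rng.normal(size=(6, d)))
        b_feats = rng.normal(size=(9, d))
        b = KeypointSet(rng.normal(size=(9, 3)), b_feats)
        base, _ = attend(a, b, model)
        perturbed = b_feats.copy()
        perturbed[0] += 1.0
        bumped, _ = attend(a, KeypointSet(b.coords, perturbed), model)
        assert np.abs(base.features - bumped.features).max() > 1e-8


class TestTraining:
    @pytest.fixture(scope="class")
    def mini_dataset(self):
        pairs = [sr.make_pair(sr.PairSpec(seed=40 + i, n_preop=3000,
                                          overlap_target=0.04))
                 for i in range(8)]
        return sr.training_triples_from_pairs(pairs, n_crops=2, seed=0)

    def test_loss_decreases_and_is_reproducible(self, mini_dataset):
        cfg = small_training_config(epochs=6)
        a = train(mini_dataset, tiny_config(), cfg)
        b = train(mini_dataset, tiny_config(), cfg)
        assert a.history[-1][2] < a.history[0][2]
        assert a.history == b.history

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], tiny_config(), TrainingConfig())

    def test_no_ground_truth_correspondences_rejected(self, mini_dataset):
        src, tgt, _ = mini_dataset[0]
        # a transform that maps the source a metre away from the target
        far = sr.RigidTransform(np.eye(3), (1000.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="correspondence"):
            train([(src, tgt, far)], tiny_config(), small_training_config(epochs=1))

    def test_save_load_round_trip(self, mini_dataset, tmp_path, curved_phantom):
        model = train(mini_dataset, tiny_config(), small_training_config(epochs=2))
        path = tmp_path / "model.npz"
        save_model(model, str(path))
        back = load_model(str(path))
        kp_a = encode(curved_phantom, model)
        kp_b = encode(curved_phantom, back)
        assert np.array_equal(kp_a.features, kp_b.features)
        assert back.temperature == pytest.approx(model.temperature)

    def test_trained_matcher_beats_uniform_on_held_out_pair(self, mini_dataset):
        """Probability mass on true correspondences exceeds the uniform
        baseline by a clear factor after a short training run."""
        model = train(mini_dataset, tiny_config(), small_training_config(epochs=15))
        pair = sr.make_pair(sr.PairSpec(seed=99, n_preop=3000, overlap_target=0.04))
        src, tgt, t_gt = sr.training_triples_from_pairs([pair], seed=0)[0]
        kp_s, kp_t, phi, _ = sr.match_pair(model, src, tgt)
        moved = t_gt.apply(kp_s.coords)
        d = np.linalg.norm(moved[:, None] - kp_t.coords[None], axis=-1)
        mask = d <= 2.0
        assert mask.any()
        gt_mass = phi.probabilities[mask].mean()
        uniform = 1.0 / phi.probabilities.shape[1]
        # a few dozen optimizer steps on a miniature model: expect a clear
        # but modest enrichment here (the full-scale run is checked in the
        # acceptance suite)
        assert gt_mass > 2 * uniform


def test_config_validation():
    with pytest.raises(ValueError, match="decreasing"):
        EncoderConfig(sa_layers=(SALayerConfig(8, 1, (4,)), SALayerConfig(16, 2, (4,)),
                                 SALayerConfig(4, 3, (4,))))
    with pytest.raises(ValueError, match="feature_dim"):
        EncoderConfig(feature_dim=4)
    with pytest.raises(ValueError, match="positive"):
        TrainingConfig(learning_rate=0.0)


def test_small_encoder_config_is_valid():
    cfg = small_encoder_config()
    assert len(cfg.sa_layers) == 3
    assert cfg.feature_dim >= 8
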