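"""Curvature-feature point matching (CFL-PM): the learned correspondence core.

A point-wise feature encoder (three Set Abstraction layers + one Feature
Propagation layer) turns a cloud with per-point curvature into a keypoint
subset with descriptors; self/cross graph attention conditions the
descriptors of each cloud on the other; a temperature softmax over descriptor
similarities gives the match-probability matrix

    phi = softmax(f_X . f_Y^T / T),    phi_ij = P(source i matches target j),

whose mutual argmaxes become correspondences for RANSAC pose estimation.

Two deliberate representation choices (see docs/methods.md): grouped
neighbors enter the SA perceptrons as (distance-to-center, curvature) pairs —
rigid-invariant by construction, so descriptors transfer across arbitrary
initial poses — and the model's similarity uses L2-normalized descriptors
(cosine / T) with a learnable log-temperature initialized at 1e-2.

Training minimizes the symmetric negative log-likelihood of the ground-truth
correspondences (pairs of keypoints within ``correspondence_radius`` mm under
the ground-truth transform) with Adam, learning rate halved on a fixed epoch
schedule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from . import nn
from .curvature import CurvatureConfig, ensure_curvature, smooth_field
from .nn import Tensor, concatenate, gather_rows
from .sampling import farthest_point_sample
from .types import PointCloud, RigidTransform

logger = logging.getLogger(__name__)

MODEL_SCHEMA = "spinereg-model-1"


# ---------------------------------------------------------------- configs

@dataclass
class SALayerConfig:
    """One Set Abstraction layer: keep ``n_out`` FPS points, group neighbors
    within ``radius`` mm, encode with a shared perceptron of ``mlp_widths``."""

    n_out: int
    radius: float
    mlp_widths: tuple[int, ...]


@dataclass
class EncoderConfig:
    sa_layers: tuple[SALayerConfig, SALayerConfig, SALayerConfig] = (
        SALayerConfig(512, 5.0, (32, 32, 64)),
        SALayerConfig(128, 10.0, (64, 64, 128)),
        SALayerConfig(32, 20.0, (128, 128, 256)),
    )
    fp_mlp_widths: tuple[int, ...] = (128,)
    feature_dim: int = 64
    attention_heads: int = 4
    attention_blocks: int = 2
    group_size: int = 16
    points_per_cloud: int = 2048
    sigma_smooth_radius: float = 3.0   # mm; 0 disables curvature-field smoothing

    def __post_init__(self) -> None:
        self.sa_layers = tuple(
            sa if isinstance(sa, SALayerConfig) else SALayerConfig(*sa)
            for sa in self.sa_layers
        )
        if len(self.sa_layers) != 3:
            raise ValueError("exactly 3 SA layers required")
        n_outs = [sa.n_out for sa in self.sa_layers]
        if not (n_outs[0] > n_outs[1] > n_outs[2]):
            raise ValueError(f"SA n_out must be strictly decreasing; got {n_outs}")
        if self.feature_dim < 8:
            raise ValueError("feature_dim must be at least 8")


def small_encoder_config() -> EncoderConfig:
    """Desk-scale encoder for CPU-only experiments on small phantom clouds."""
    return EncoderConfig(
        sa_layers=(
            SALayerConfig(192, 6.0, (16, 32)),
            SALayerConfig(56, 12.0, (32, 48)),
            SALayerConfig(16, 24.0, (48, 48)),
        ),
        fp_mlp_widths=(64,),
        feature_dim=32,
        attention_heads=4,
        attention_blocks=1,
        group_size=32,
        points_per_cloud=1024,
    )


def small_training_config(epochs: int = 20, seed: int = 0) -> "TrainingConfig":
    """Training conditions matched to the desk-scale encoder: with only a few
    dozen small training pairs the optimizer takes two orders of magnitude
    fewer steps than a full-scale run, so the step size is raised to 1e-2,
    the softmax temperature starts at 0.05, and the ground-truth
    correspondence radius shrinks to the keypoint-spacing scale (2 mm)."""
    return TrainingConfig(learning_rate=1e-2, batch_size=2, epochs=epochs,
                          temperature_init=0.05, correspondence_radius=2.0,
                          seed=seed)


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-4
    lr_halving_epochs: int = 5
    batch_size: int = 4
    epochs: int = 100
    temperature_init: float = 1e-2
    correspondence_radius: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "lr_halving_epochs", "batch_size", "epochs",
                     "temperature_init", "correspondence_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------- data types

@dataclass
class KeypointSet:
    """Keypoint coordinates (subset of the input cloud) with descriptors."""

    coords: np.ndarray     # (N, 3)
    features: np.ndarray   # (N, d)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if len(self.features) != len(self.coords):
            raise ValueError("features row count must match coords")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("keypoint features contain non-finite values")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class MatchMatrix:
    """Row-stochastic match probabilities phi and the temperature used."""

    probabilities: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        row_sums = self.probabilities.sum(axis=-1)
        if np.abs(row_sums - 1.0).max() > 1e-6:
            raise ValueError("match-matrix rows must sum to 1")
        if self.probabilities.min() < -1e-12 or self.probabilities.max() > 1 + 1e-12:
            raise ValueError("match probabilities outside [0, 1]")

    @property
    def shape(self):
        return self.probabilities.shape


# ---------------------------------------------------------------- model

def _local_frame_coords(offsets: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Neighbor offsets in per-center cylindrical surface coordinates.

    For each group the surface normal is the smallest covariance
    eigenvector, sign-fixed by the spatial skew of the group (convexity).
    Each neighbor offset is then reduced to (tangential radius, signed
    normal height) — invariant to rigid motion AND to any rotation of the
    tangent plane. Full in-plane frames were tried and rejected: their sign
    disambiguation occasionally flips coherently between two independent
    samplings of the same surface, which produces confident mirrored
    matches and catastrophic coarse poses. ``sigma`` is accepted for
    signature stability (a curvature-oriented tangent axis is a natural
    extension) but unused.
    """
    cov = np.einsum("mki,mkj->mij", offsets, offsets)
    _, vecs = np.linalg.eigh(cov)                   # ascending eigenvalues
    normal = vecs[:, :, 0]
    skew = (np.einsum("mki,mi->mk", offsets, normal) ** 3).sum(axis=1)
    normal = normal * np.where(skew >= 0, 1.0, -1.0)[:, None]
    height = np.einsum("mki,mi->mk", offsets, normal)
    radial = np.sqrt(np.maximum(
        np.einsum("mki,mki->mk", offsets, offsets) - height ** 2, 0.0))
    return np.stack([radial, height], axis=-1)


def _group(points: np.ndarray, centers_idx: np.ndarray, radius: float,
           group_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Neighbor indices and distances per center: up to ``group_size`` nearest
    within ``radius``; slots beyond the radius fall back to the center itself
    (distance 0), keeping arrays rectangular."""
    k = min(group_size, len(points))
    tree = cKDTree(points)
    dist, idx = tree.query(points[centers_idx], k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    out_of_ball = dist > radius
    idx = np.where(out_of_ball, centers_idx[:, None], idx)
    dist = np.where(out_of_ball, 0.0, dist)
    return idx.astype(np.intp), dist


class CurvatureMatcher(nn.Module):
    """The trainable CFL-PM model (encoder + graph attention + temperature)."""

    #: input scaling: sigma in [0, 1/3] is stretched to O(1) so the curvature
    #: channel is commensurate with the normalized-distance channel
    curvature_scale = 10.0

    def __init__(self, cfg: EncoderConfig | None = None, seed: int = 0):
        self.cfg = cfg or EncoderConfig()
        rng = np.random.default_rng(seed)
        c_in = 1  # curvature channel
        self.sa_mlps = []
        for sa in self.cfg.sa_layers:
            widths = [c_in + 2, *sa.mlp_widths]  # +2: cylindrical offset channels
            self.sa_mlps.append(nn.MLP(widths, rng))
            c_in = 2 * sa.mlp_widths[-1]         # max-pool and mean-pool halves
        d1 = 2 * self.cfg.sa_layers[0].mlp_widths[-1]
        d3 = 2 * self.cfg.sa_layers[2].mlp_widths[-1]
        self.fp_mlp = nn.MLP([d1 + d3, *self.cfg.fp_mlp_widths, self.cfg.feature_dim],
                             rng, relu_last=False)
        self.self_blocks = [nn.AttentionBlock(self.cfg.feature_dim, self.cfg.attention_heads, rng)
                            for _ in range(self.cfg.attention_blocks)]
        self.cross_blocks = [nn.AttentionBlock(self.cfg.feature_dim, self.cfg.attention_heads, rng)
                             for _ in range(self.cfg.attention_blocks)]
        self.log_temperature = Tensor(np.log(1e-2), requires_grad=True)
        self.history: list[tuple[int, float, float]] = []

    # ------------------------------------------------ encoding
    def encode_plan(self, points: np.ndarray, curvature: np.ndarray,
                    n_keypoints: int | None = None) -> dict:
        """Weight-independent encoding geometry: FPS selections, neighbor
        groups in curvature-oriented local frames, and FP interpolation
        weights. Reusable across forward passes."""
        n = len(points)
        sa3_n = self.cfg.sa_layers[2].n_out
        if n < sa3_n:
            raise ValueError(f"cloud of {n} points is smaller than SA3 n_out={sa3_n}")
        plan: dict = {"levels": []}
        coords = np.asarray(points, dtype=np.float64)
        sigma_all = smooth_field(coords, np.asarray(curvature, dtype=np.float64),
                                 self.cfg.sigma_smooth_radius)
        plan["sigma"] = sigma_all
        glob = np.arange(n)
        for li, sa in enumerate(self.cfg.sa_layers):
            m = min(sa.n_out, len(coords))
            if li == 0 and n_keypoints is not None:
                m = min(n_keypoints, len(coords))
            centers = farthest_point_sample(coords, m)
            idx, dist = _group(coords, centers, sa.radius, self.cfg.group_size)
            offsets = coords[idx] - coords[centers][:, None, :]
            local = _local_frame_coords(offsets, sigma_all[glob[idx]])
            plan["levels"].append({"idx": idx, "local": local})
            coords = coords[centers]
            glob = glob[centers]
            plan["levels"][-1]["coords"] = coords
        kp_coords = plan["levels"][0]["coords"]
        sa3_coords = plan["levels"][2]["coords"]
        k = min(3, len(sa3_coords))
        d, nbr = cKDTree(sa3_coords).query(kp_coords, k=k)
        if k == 1:
            d, nbr = d[:, None], nbr[:, None]
        w = 1.0 / np.maximum(d, 1e-10)
        plan["fp_idx"] = nbr.astype(np.intp)
        plan["fp_w"] = w / w.sum(axis=1, keepdims=True)
        plan["keypoints"] = kp_coords
        return plan

    def encode_from_plan(self, plan: dict) -> Tensor:
        """Differentiable part of the encoder: features for the plan's keypoints."""
        feats = Tensor(plan["sigma"][:, None] * self.curvature_scale)
        level_feats = []
        for li, (level, mlp) in enumerate(zip(plan["levels"], self.sa_mlps)):
            grouped = gather_rows(feats, level["idx"])             # (m, k, c)
            radius = self.cfg.sa_layers[li].radius
            geo = Tensor(level["local"] / radius)                  # (m, k, 2)
            h = mlp(concatenate([grouped, geo], axis=-1))          # (m, k, w)
            feats = concatenate([h.max(axis=1), h.mean(axis=1)], axis=-1)  # (m, 2w)
            level_feats.append(feats)
        interp = (gather_rows(level_feats[2], plan["fp_idx"])
                  * Tensor(plan["fp_w"][:, :, None])).sum(axis=1)
        fused = concatenate([level_feats[0], interp], axis=-1)
        return self.fp_mlp(fused)

    def encode_t(self, points: np.ndarray, curvature: np.ndarray,
                 n_keypoints: int | None = None) -> tuple[np.ndarray, Tensor]:
        plan = self.encode_plan(points, curvature, n_keypoints)
        return plan["keypoints"], self.encode_from_plan(plan)

    # ------------------------------------------------ attention
    def attend_t(self, fx: Tensor, fy: Tensor) -> tuple[Tensor, Tensor]:
        for self_blk, cross_blk in zip(self.self_blocks, self.cross_blocks):
            fx = self_blk(fx, fx)
            fy = self_blk(fy, fy)
            fx, fy = cross_blk(fx, fy), cross_blk(fy, fx)
        return fx, fy

    # ------------------------------------------------ similarity
    @property
    def temperature(self) -> float:
        return float(np.exp(self.log_temperature.data))

    def similarity_t(self, fx: Tensor, fy: Tensor) -> Tensor:
        """Pre-softmax logits: cosine of per-cloud mean-centred descriptors / T.

        Centring removes the large shared component that ReLU feature stacks
        accumulate (without it all pairwise cosines start near 1 and the
        matching softmax sits in a collapsed basin the optimizer cannot
        leave); both clouds undergo the same operation so matching stays
        symmetric.
        """
        fx = fx - fx.mean(axis=0, keepdims=True)
        fy = fy - fy.mean(axis=0, keepdims=True)
        fxn = fx * (fx * fx).sum(axis=-1, keepdims=True).pow(-0.5)
        fyn = fy * (fy * fy).sum(axis=-1, keepdims=True).pow(-0.5)
        return (fxn @ fyn.swapaxes(-1, -2)) * (-self.log_temperature).exp()


# ---------------------------------------------------------------- operations

def encode(cloud: PointCloud, model: CurvatureMatcher,
           n_keypoints: int | None = None) -> KeypointSet:
    """Encode a curvature-bearing cloud into keypoints + descriptors.

    Keypoint coordinates are the FPS subset selected by the first SA layer
    (``n_keypoints`` overrides its configured output count downward).
    """
    if cloud.features is None:
        raise ValueError("encode requires a cloud with curvature features; "
                         "run compute_curvature first")
    coords, feats = model.encode_t(cloud.points, cloud.features, n_keypoints)
    if len(coords) < 3:
        raise ValueError("fewer than 3 keypoints produced; cloud too small")
    return KeypointSet(coords, feats.data)


def attend(src: KeypointSet, tgt: KeypointSet,
           model: CurvatureMatcher) -> tuple[KeypointSet, KeypointSet]:
    """Self + cross graph attention; coordinates pass through unchanged."""
    fx, fy = model.attend_t(Tensor(src.features), Tensor(tgt.features))
    return (KeypointSet(src.coords, fx.data), KeypointSet(tgt.coords, fy.data))


def match(src: KeypointSet, tgt: KeypointSet, temperature: float,
          normalize: bool = False) -> MatchMatrix:
    """Row-softmax of descriptor similarities at the given temperature.

    ``normalize=True`` uses cosine similarity (the model's convention);
    ``False`` uses the raw dot product.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    fx, fy = src.features, tgt.features
    if fx.shape[1] != fy.shape[1]:
        raise ValueError("descriptor dimensions differ between src and tgt")
    if normalize:
        fx = fx / np.linalg.norm(fx, axis=1, keepdims=True)
        fy = fy / np.linalg.norm(fy, axis=1, keepdims=True)
    logits = (fx @ fy.T) / temperature
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return MatchMatrix(e / e.sum(axis=1, keepdims=True), temperature)


def extract_correspondences(phi: MatchMatrix, src: KeypointSet, tgt: KeypointSet,
                            min_prob: float = 0.0) -> np.ndarray:
    """Mutual-argmax correspondences (i, j) with phi_ij >= min_prob.

    Ties inside a row/column resolve to the lowest index (argmax convention).
    Returns an (m, 2) integer array; may be empty.
    """
    p = phi.probabilities
    best_j = p.argmax(axis=1)
    best_i = p.argmax(axis=0)
    i = np.arange(p.shape[0])
    mutual = best_i[best_j] == i
    keep = mutual & (p[i, best_j] >= min_prob)
    return np.column_stack([i[keep], best_j[keep]]).astype(np.intp)


def match_pair(model: CurvatureMatcher, src: PointCloud, tgt: PointCloud,
               n_keypoints: int | None = None, min_prob: float = 0.0,
               src_plan: dict | None = None
               ) -> tuple[KeypointSet, KeypointSet, MatchMatrix, np.ndarray]:
    """Full CFL-PM inference: encode both clouds, attend, match, extract.

    ``src_plan`` lets callers reuse a cached encoding plan for ``src``.
    """
    src = ensure_curvature(src)
    tgt = ensure_curvature(tgt)
    plan_s = src_plan if src_plan is not None \
        else model.encode_plan(src.points, src.features, n_keypoints)
    plan_t = model.encode_plan(tgt.points, tgt.features, n_keypoints)
    fs = model.encode_from_plan(plan_s)
    ft = model.encode_from_plan(plan_t)
    fs, ft = model.attend_t(fs, ft)
    logits = model.similarity_t(fs, ft)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    phi = MatchMatrix(e / e.sum(axis=1, keepdims=True), model.temperature)
    kp_src = KeypointSet(plan_s["keypoints"], fs.data)
    kp_tgt = KeypointSet(plan_t["keypoints"], ft.data)
    corr = extract_correspondences(phi, kp_src, kp_tgt, min_prob)
    return kp_src, kp_tgt, phi, corr


# ---------------------------------------------------------------- training

def _prepare_pair(model: CurvatureMatcher, src: PointCloud, tgt: PointCloud,
                  t_gt: RigidTransform, tr_cfg: TrainingConfig,
                  curvature_cfg: CurvatureConfig | None) -> dict | None:
    """Fixed per-pair training structures: resampled clouds, curvature,
    encode plans and flat indices of ground-truth correspondences."""
    cap = model.cfg.points_per_cloud

    def resample(cloud: PointCloud) -> PointCloud:
        if len(cloud) <= cap:
            return cloud
        return cloud.subset(farthest_point_sample(cloud, cap))

    src, tgt = resample(src), resample(tgt)
    src = ensure_curvature(src, curvature_cfg)
    tgt = ensure_curvature(tgt, curvature_cfg)
    n_kp = min(model.cfg.sa_layers[0].n_out, len(src), len(tgt))
    plan_s = model.encode_plan(src.points, src.features, n_kp)
    plan_t = model.encode_plan(tgt.points, tgt.features, n_kp)
    x = t_gt.apply(plan_s["keypoints"])
    y = plan_t["keypoints"]
    d = np.linalg.norm(x[:, None, :] - y[None, :, :], axis=-1)
    ii, jj = np.nonzero(d <= tr_cfg.correspondence_radius)
    if len(ii) == 0:
        return None
    return {
        "plan_src": plan_s, "plan_tgt": plan_t,
        "flat": ii * len(y) + jj, "shape": (len(x), len(y)),
    }


def _pair_loss(model: CurvatureMatcher, prep: dict) -> Tensor:
    fs = model.encode_from_plan(prep["plan_src"])
    ft = model.encode_from_plan(prep["plan_tgt"])
    fs, ft = model.attend_t(fs, ft)
    logits = model.similarity_t(fs, ft)
    nll_rows = -logits.log_softmax(axis=1).take(prep["flat"]).mean()
    nll_cols = -logits.log_softmax(axis=0).take(prep["flat"]).mean()
    return (nll_rows + nll_cols) * 0.5


def train(dataset: list[tuple[PointCloud, PointCloud, RigidTransform]],
          enc_cfg: EncoderConfig | None = None,
          tr_cfg: TrainingConfig | None = None,
          curvature_cfg: CurvatureConfig | None = None) -> CurvatureMatcher:
    """Train a CurvatureMatcher on (source, target, ground-truth) triples.

    The ground-truth transform of each triple maps source coordinates into the
    target frame. Returns the trained model; ``model.history`` holds one
    ``(epoch, lr, mean_loss)`` row per epoch.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    tr_cfg = tr_cfg or TrainingConfig()
    model = CurvatureMatcher(enc_cfg, seed=tr_cfg.seed)
    model.log_temperature.data = np.array(np.log(tr_cfg.temperature_init))
    preps = []
    for src, tgt, t_gt in dataset:
        prep = _prepare_pair(model, src, tgt, t_gt, tr_cfg, curvature_cfg)
        if prep is not None:
            preps.append(prep)
    if not preps:
        raise ValueError(
            "no training pair has any ground-truth correspondence within "
            f"{tr_cfg.correspondence_radius} mm; check transforms and overlap"
        )
    params = model.parameters()
    opt = nn.Adam(params, lr=tr_cfg.learning_rate)
    rng = np.random.default_rng(tr_cfg.seed)
    model.history = []
    for epoch in range(tr_cfg.epochs):
        opt.lr = tr_cfg.learning_rate * 0.5 ** (epoch // tr_cfg.lr_halving_epochs)
        order = rng.permutation(len(preps))
        losses = []
        for start in range(0, len(order), tr_cfg.batch_size):
            batch = order[start:start + tr_cfg.batch_size]
            opt.zero_grad()
            total = None
            for bi in batch:
                loss = _pair_loss(model, preps[bi]) * (1.0 / len(batch))
                total = loss if total is None else total + loss
            total.backward()
            opt.step()
            losses.append(float(total.data))
        mean_loss = float(np.mean(losses))
        model.history.append((epoch, opt.lr, mean_loss))
        logger.info("epoch %d lr %.2e loss %.4f", epoch, opt.lr, mean_loss)
    return model


# ---------------------------------------------------------------- persistence

def save_model(model: CurvatureMatcher, path: str) -> None:
    """Serialize weights + config with a schema-versioned header (.npz)."""
    meta = {
        "schema": MODEL_SCHEMA,
        "config": asdict(model.cfg),
    }
    arrays = {f"param:{k}": p.data for k, p in model.parameters().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path: str) -> CurvatureMatcher:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("schema") != MODEL_SCHEMA:
            raise ValueError(f"unknown model schema {meta.get('schema')!r}")
        cfg_dict = meta["config"]
        cfg_dict["sa_layers"] = tuple(
            SALayerConfig(sa["n_out"], sa["radius"], tuple(sa["mlp_widths"]))
            for sa in cfg_dict["sa_layers"]
        )
        cfg_dict["fp_mlp_widths"] = tuple(cfg_dict["fp_mlp_widths"])
        cfg = EncoderConfig(**cfg_dict)
        model = CurvatureMatcher(cfg)
        params = model.parameters()
        for key in data.files:
            if key.startswith("param:"):
                name = key[len("param:"):]
                if name not in params:
                    raise ValueError(f"unexpected parameter {name!r} in model file")
                params[name].data = data[key].astype(np.float64)
    return model
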