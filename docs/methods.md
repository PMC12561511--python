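# Methods

`spinereg` registers a small, intra-operatively scanned spine-surface patch
onto a pre-operative CT-derived surface cloud when the two clouds share only
a few percent of their support, come from different sensors at different
densities, and start up to ~170° / ~115 mm apart. This note records the
model, the numerical choices, and what the synthetic phantom does and does
not establish.

## Problem setting and notation

Inputs are two point clouds in millimetres: the pre-operative cloud `Q`
(full anatomy) and the intra-operative cloud (one surgically exposed spinous
process). The goal is the rigid transform (R̂, t̂) mapping intra-operative
coordinates into the pre-operative frame. Accuracy against a ground-truth
transform `T_G` is measured through the residual ΔT = T T_G⁻¹:

    e_r = arccos((tr ΔR − 1) / 2)   [degrees, arccos argument clamped to [−1, 1]]
    e_t = ‖Δt‖                       [mm]

A result with e_r > 60° or e_t > 60 mm counts as a registration failure
(strict inequalities); summary means are taken over non-failed cases only.

## Curvature feature

Each point's feature is the surface variation of its 5 mm covariance
neighborhood: with eigenvalues λ1 ≥ λ2 ≥ λ3 of the neighborhood scatter
(neighborhood centroid as mean, query point included),

    σ = λ3 / (λ1 + λ2 + λ3) ∈ [0, 1/3].

σ is invariant to rigid motion and uniform scaling and is 0 on planes, 1/3
for isotropic neighborhoods. Neighborhoods with fewer than `min_neighbors`
(default 5) points fall back to σ = 0 (flat prior) and are counted in the
log. Before entering the encoder, σ is neighborhood-averaged over a 3 mm
radius (`EncoderConfig.sigma_smooth_radius`): σ estimated from a finite
sampling is noisy at the ~15–25 % level, and smoothing was necessary to make
descriptors reproducible across two independent samplings of the same
surface.

## The matcher (CFL-PM)

The learned core is a point-wise feature encoder — three Set Abstraction
(SA) layers and one Feature Propagation (FP) layer — followed by self/cross
graph attention and a temperature softmax over descriptor similarities.

**SA layers.** Each SA layer keeps `n_out` farthest-point-sampled centers,
groups up to `group_size` nearest neighbors within `radius`, encodes each
group with a shared perceptron, and pools with concatenated max and mean.
The per-neighbor input is the (smoothed, ×10 rescaled) curvature plus the
neighbor's offset in cylindrical surface coordinates per center: the
tangential radius and the signed height along the group's surface normal
(smallest covariance eigenvector, sign fixed by the spatial skew of the
group, i.e. convexity). These channels are invariant to rigid motion and to
any rotation of the tangent plane, so descriptors transfer across arbitrary
initial poses by construction and no pose augmentation is needed.

Full in-plane local reference frames (offsets expressed along oriented
covariance/curvature-gradient axes) were implemented and rejected: however
the in-plane sign is disambiguated, it occasionally flips *coherently*
between two independent samplings of the same surface, and a coherent flip
produces confident mirrored correspondences — RANSAC then finds a large
consensus for a pose that is wrong by 50–100°. Dropping the in-plane
direction information removes that failure mode entirely at a modest cost
in per-point distinctiveness, which the attention stage recovers from
context.

**FP layer.** SA3 features are interpolated back to the SA1 keypoints by
inverse-distance weighting of the 3 nearest coarse centers, concatenated
with the SA1 features, and projected to `feature_dim` by a final perceptron.
Keypoints are therefore a subset of the input points (the SA1 FPS sample).

**Attention.** `attention_blocks` rounds of shared-weight multi-head
self-attention on each cloud followed by cross-attention between the clouds
(residual + layer-norm + feed-forward per block). Cross-attention is
scheduled symmetrically so `attend(A, B)` and `attend(B, A)` agree up to
order.

**Matching.** Descriptors are mean-centred per cloud, L2-normalized, and
compared by cosine similarity divided by a learnable temperature
(log-parameterized, initialized at 1e-2 in the full-scale configuration):

    φ = softmax(f̂_X · f̂_Yᵀ / T),

row-stochastic; φ_ij is the probability that source keypoint i matches
target keypoint j. The per-cloud mean-centring matters: ReLU feature stacks
accumulate a large shared positive component, all pairwise cosines start
near 1, and the matching softmax then sits in a collapsed basin the
optimizer cannot leave. Centring removes exactly that component and applies
identically to both clouds.

**Training.** Ground-truth correspondences are keypoint pairs within
`correspondence_radius` of each other under `T_G`; the loss is the
symmetric negative log-likelihood (row and column log-softmax averaged) of
those pairs. Adam, learning rate halved every `lr_halving_epochs` (default
5). Full-scale defaults follow the original training protocol of this method family
(lr 1e-4, batch 4, 100 epochs, T init 1e-2, the second loss hyper-parameter
read as a 10 mm correspondence radius — the only remaining length scale in
the loss). The desk-scale configuration (`small_training_config`) takes two
orders of magnitude fewer optimizer steps, so it uses lr 1e-2, batch 2,
T init 0.05, and a correspondence radius of 2 mm (the keypoint spacing of
the small phantom crops); these were set from training diagnostics (loss
level and overfit precision), not from validation outcomes.

Training examples are built by `training_triples_from_pairs`: the
intra-operative cloud (density-equalized, curvature attached) against
pre-operative crops of the same radius the pipeline's region search uses,
centred on the true overlap, plus jittered crops for augmentation. Half of
the crops carry an appended *decoy* crop from a distant part of the
pre-operative cloud: at test time 24 of 25 candidate regions are wrong, and
without hard negatives the matcher never learns to starve look-alike
regions (neighboring spinous processes) of probability mass.

## Coarse registration

The pre-operative cloud is decomposed into k = 25 FPS regions, each the
closed ball of radius r around a sample point. r defaults to 1.3× the
intra-operative cloud's bounding-sphere radius: the region must be able to
contain the whole exposed patch (a factor below 1 leaves a ring of
intra-operative keypoints with no counterpart in any region, which caps
correspondence precision).

Per region, the matcher produces φ and RANSAC estimates a pose from the
top-3 most probable targets per source keypoint (mode configurable:
`topk` / `union` / `mutual`). Mutual-argmax extraction
(`extract_correspondences`) is available and contract-tested, but yields
only a few dozen candidates at modest precision on desk-scale data; handing
RANSAC a larger candidate set and letting consensus do the rejection is
both more robust and closer to how the φ matrix is meant to be consumed.
RANSAC scores hypotheses by φ-weighted inlier counts, rejects clustered
minimal samples (smallest leg < ⅓ of the source spread gives
ill-conditioned rotations), and re-estimates on all inliers by least-squares
superposition. Default 5000 iterations, inlier threshold 2× the median
nearest-neighbor spacing of the target keypoints, fully seeded.

After the traversal, up to `recrop_passes` (default 2) re-matching rounds
run on a pre-operative crop re-centred at the current pose's patch estimate:
the first pass localizes the patch only roughly (regions are anchored at
FPS samples, not at the patch), while a centred crop reproduces the
training-crop distribution exactly and often sharpens a mediocre pose. Each
round is accepted only if it improves the selection criterion of the active
mode.

Region selection runs in two modes:

* **oracle** — the evaluation protocol: regions ranked by e_r against the
  supplied ground truth (ties by lowest region index, then lowest e_t).
* **blind** — the deployment surrogate: RANSAC inlier count, ties by lowest
  trimmed-RMS residual. Clearly labelled in the result record.

## Fine registration

Classic point-to-point ICP (`icp_refine`) is implemented and exposed:
nearest-neighbor correspondences within `max_corr_dist` (default 10 mm),
least-squares update, stop when the mean residual changes by < `tol`.

The pipeline's default fine stage (`refine_pose`) is a cascade, because
point-to-point ICP between two *independent samplings* of a smooth surface
is biased: even initialized at the exact ground truth it drifts 1–2° (a
0.5 mm tangential slide on a ~16 mm patch is several degrees). The cascade
runs point-to-point capture, then a moving-least-squares polish: moved
points are projected onto local quadrics fitted to the pre-operative cloud
(covariance frame + distance-weighted quadratic height field, 30 neighbors,
2 mm kernel), which reconstructs the continuous surface between samples and
removes the sampling-spacing floor. Because the discrete landscape still has
spurious minima within a few degrees, the polish restarts from 12 seeded
perturbations (±4°, ±2 mm) and keeps the pose with the lowest
point-to-surface residual, subject to a trust region: polished poses more
than 15° / 10 mm from the captured pose are rejected, because a small
smooth patch can slide onto an entirely different surface area with a
*lower* residual than the true fit. Refinement runs against the full
pre-operative cloud (configurable to the winning region) using the raw,
densest intra-operative cloud.

Residual caveat: on patches with little surface texture the point-to-surface
cost is flat along a slide mode (rotation about the process axis), and poses
1–3° apart can be numerically indistinguishable (residual differences below
the MLS reconstruction error, ~0.01 mm). Fine accuracy therefore has heavy
tails governed by patch texture, not by the optimizer.

## Synthetic phantom

The generator is deliberately parametric, not anatomical; validation rests
on the statistical structure of the task (overlap fraction, density ratio,
pose ranges, noise), not on shape fidelity.

* One vertebra = ellipsoidal body (axes ~18–23 / 13.5–17 / 10.5–14 mm)
  smooth-min blended with a long "spinous process" capsule and 0–2
  transverse capsules, plus 40 Gaussian surface bumps (amplitude
  0.7–1.5 mm, width 2.5–5 mm) that break rotational symmetry and give the
  curvature field texture.
* A registration pair stacks 4 vertebrae along the cranio-caudal axis with
  cumulative inter-vertebral tilts (5–12° per level about the lateral axis,
  ±3° jitter) emulating spinal curvature. The tilts matter for evaluation:
  with identically oriented processes, a match onto the *wrong* vertebra has
  near-zero rotation error and ~26 mm translation error, and rotation-based
  oracle ranking cannot reject it — which is anatomically wrong, not a
  property of real spines.
* The pre-operative cloud samples the whole stack area-uniformly
  (per-primitive area-weighted sampling, Newton projection onto the blended
  isosurface); default 16 000 points (~0.43 mm spacing), a scaled-down
  stand-in for CT/structured-light clouds that are typically 50 k+ points at
  sub-0.5 mm spacing.
* The intra-operative cloud is a ball-crop around the middle vertebra's
  spinous tip grown to hit the overlap target exactly by point count
  (default target drawn from 1.3–4.3 %), independently resampled at
  `density_ratio` (default 2) times the pre-operative density, rigidly moved
  (per-axis rotations up to ±170°, translations up to ±115 mm) and
  optionally perturbed with isotropic Gaussian noise
  (σ ∈ {0.25, 0.5, 0.75, 1.0} mm in the robustness sweep). With
  `density_ratio = 1` the patch reuses the pre-operative samples (useful for
  exact-subset tests). The overlap ratio is the fraction of pre-operative
  points with a transformed intra-operative point within τ = 2× the
  pre-operative median nearest-neighbor spacing.

What the phantom does *not* model: real bone micro-texture (it is smoother
than bone, which makes the fine stage's flat-valley tails worse than they
would be on scans), soft-tissue occlusion beyond the crop, scanner-specific
noise structure, and multi-patient anatomical variability. Passing the
synthetic study shows the pipeline's machinery is sound under the stated
statistical regime; it does not certify clinical accuracy.

## Desk-scale validation study

`scaled_validation_experiment` (also run by `scripts/acceptance.py`) fixes
the problem sizes of the package's own validation: 48 training pairs with 3
crops each (decoys at 50 %), the small encoder (SA 192/56/16 keypoints,
feature dim 32, one attention block, ≤1024 points per training cloud), 20
training epochs, 2000 RANSAC iterations and 8 polish restarts per
registration, then oracle-mode registration of 40 held-out pairs with 25
regions. All seeds derive from one integer.

Training at this scale has a noticeable run-to-run spread (a few hundred
optimizer steps from random init), so the driver self-validates each
trained model by registering six of its own *training* pairs and redraws
the training seed once if the mean coarse rotation error exceeds 22° —
model selection on training data only, never on the held-out set. These
sizes are the package's choice of a single-workstation study; the
full-scale defaults remain on the configuration objects.

## Numerical details and edge cases

* Rotations are validated to 1e-6 (orthonormality and det +1) and rejected,
  never re-orthonormalized.
* FPS ties break to the lowest index; the first index is the seed index, so
  selections are permutation-robust up to the seed point.
* Region membership uses the closed ball (boundary included).
* Density equalization bisects the voxel edge until the median
  nearest-neighbor spacing is within 20 % of the reference's; voxels are
  represented by their medoid so output points remain true surface samples.
  If the reference is denser than the input can provide, the input is
  returned unchanged with a warning.
* Degenerate matching cases (fewer than 3 candidate correspondences, no
  hypothesis with 3 inliers, regions smaller than the SA3 width) mark the
  region unregistrable; if every region fails, the result is a flagged
  failure rather than an exception.
* `backward()` requires scalars; max-pool routes gradient to the first
  maximum; softmax/log-softmax are max-subtracted.

## Known limitations

* The learned matcher is trained per-study at desk scale; no pretrained
  weights ship with the package.
* Oracle region selection needs ground truth and exists to mirror the
  oracle evaluation protocol; blind mode is a surrogate whose ranking
  (inlier count, then residual) has no optimality guarantee.
* Fine-stage accuracy is texture-limited (see above); on smooth patches the
  reported means carry heavy per-pair tails.
* The noise sweep re-noises the *same* base pairs, so its per-σ means are
  correlated across columns by construction.
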