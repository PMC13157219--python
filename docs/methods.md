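# Methods

`plantfill` completes occlusion-incomplete 3-D plant point clouds with a
multi-scale dual-discriminator generative adversarial network, and ships
the full surrounding pipeline: synthetic plant generation, hierarchical
clustering with thin-plate-spline (TPS) non-rigid augmentation, a virtual
camera that manufactures training pairs by simulating single-view optical
occlusion, completion metrics with brute-force-verified implementations,
and the 2D–3D alignment math used to turn completed clouds into leaf-level
phenotypes. This note records the model, its assumptions, the tunable
parameters, and the design choices made where the design was genuinely
open.

## Problem setting and data model

A plant is an unordered set of N 3-D points with optional per-point organ
labels (0 = stem, i = i-th leaf). Single-view optical acquisition hides
interior and far-side structure; the completion task is: given the
visible subset of a plant's cloud, predict a fixed-size set of M points
covering the occluded region. All network computation happens in
per-axis-normalized coordinates: p̂ = 2(p − m_min)/(m_max − m_min) − 1,
inverted after prediction (Hadamard product with the stored extents).
The normalization is anisotropic by default because the downstream
network only ever sees the normalized frame; an isotropic variant
(single scale = largest axis extent) is available behind a flag for
users who need preserved aspect ratios.

## Synthetic plants

No plant scans ship with the package; a seedable generator emulates the
relevant geometry instead. Each plant is a bent-cylinder stem plus
`n_leaves` curved blades; a leaf is a quadratic-profile parametric patch
S(u, v) — midrib rising with a template slope and drooping quadratically
with the `curvature` parameter, an elliptical width profile (heart,
oval, or lobed per species template), and a shallow cross-blade arch so
blades are curved sheets rather than planes. Four species-like templates
(sunflower-, pumpkin-, eggplant-, luffa-like) differ in blade shape,
aspect and droop. Defaults: `points_total` 6000 (≥ 5000 enforced — the
pipeline assumes dense complete clouds), stem height 1.0, leaf scale
0.45, noise_sd 0 (additive Gaussian coordinate noise available).
Roughly 30% of the point budget goes to the stem, the remainder evenly
across leaves, integer remainders to the stem.

What the generator does *not* emulate: sensor noise models, leaf
texture/thickness, petioles, self-intersection, growth stages, or real
interspecies variation. Tests passing on these clouds therefore
demonstrate the pipeline's mechanics and learnability of far-side
structure under controlled conditions, not field-ready accuracy on
scanner data.

Datasets are stratified by species: each species' samples are split
7:2:1 (floor-based, remainders to training) and then jointly shuffled,
so every split keeps the global species proportions and later
mini-batches mix species. With the reference per-species counts
(560/410/540/390) the split sizes are exactly 1330/380/190.

## Clustering and TPS augmentation

Organ-scale regions are found by greedy agglomeration from singletons:
merge the pair of clusters with the smallest center-to-center distance,
where a merged center is the size-weighted mean of its parts (for the
initial singleton rounds this coincides with average linkage). Ties
break on the lowest (id, id) pair. This is operationally greedy centroid
linkage; the package cross-checks it against an exhaustive oracle and
`scipy.cluster.hierarchy` in tests, and offers exact average linkage
(Lance–Williams) behind `method="average"`. k is user-chosen, default 8;
clouds beyond 600 points are clustered on an IFPS subsample with
nearest-centroid assignment of the rest (exact clustering is O(N²) per
merge).

Non-rigid augmentation deforms one non-stem cluster per variant with a
radial–tangential TPS:

    y = Σᵢ Wᵢ [α ψ_r(x, xᵢ) + β ψ_t(x, xᵢ, nᵢ)] + A x + b

with ψ_r(r) = r² log r (0 at r = 0) and ψ_t = cosine between x − xᵢ and
the control normal nᵢ (from 16-neighbor PCA). Fitting solves the
interpolation system with the standard side conditions (Σ Wᵢ = 0,
Σ Wᵢ xᵢᵀ = 0) and a 1e-8 ridge on the basis block. Defaults α = 0.7,
β = 0.3, 12 control points per cluster. Control targets are random
displacements bounded by `max_displacement` × bounding-box diagonal;
the stem cluster (lowest mean height) is never deformed, and points
outside the selected cluster are bit-identical to the input. A zero
displacement bound short-circuits to an exact copy.

## Virtual camera and silhouettes

Viewpoints are sampled uniformly on a sphere centered at the cloud
centroid with radius `radius_factor` (default 2.4) × the largest axis
extent; each viewpoint defines an orthographic projection plane through
the centroid with normal n = p_cen − p_view and a deterministic in-plane
basis (u = up × n̂ with up = ẑ, falling back to ŷ near the poles).

Silhouettes are rendered in two passes: a probe pass with radius 3 px
estimates the visible-pixel count A, then each projected point stamps a
disc of the density-aware radius r = ceil(η·A/M) (η default 1.0), which
closes the inter-point holes that a fixed radius would leave in sparse
views. Default raster 256×256 at full scale, 64×64 in the desk preset;
the world-units-per-pixel scale auto-fits the cloud into 80% of the
frame unless given.

Visible/missing partitioning uses a per-pixel z-buffer: the point
nearest the camera in each pixel is visible; points more than
`depth_tol` (default 1% of the bounding-box diagonal) behind it are
occluded. The occluded set is resized to exactly `missing_size`
(default 512; 2048-point inputs then leave 1536 visible): IFPS-reduced
when too large, topped up with the *deepest* remaining points — the
cloud's far side along the viewing direction — when too small. The
far-side rule matters: an earlier margin-based variant degenerated to an
index-ordered, unlearnable point set on sparse clouds.

The silhouette-consistency mask keeps a predicted point only if its
projection lands on an on-pixel of the ground-truth silhouette in every
view. Masked-out points are zeroed (coordinates multiplied by 0) before
both discriminators — the discriminators take fixed-size inputs, so
removal is implemented as zeroing; the supervised completion loss stays
unmasked because it already anchors geometry to the ground truth.

## Networks

All networks run on a small reverse-mode autodiff engine written on
NumPy inside the package (`plantfill.nn`): broadcasted arithmetic,
matmul, ReLU/tanh/sigmoid, single-axis reductions with argmax-routed
gradients, concatenation/indexing/repeat, an im2col 2-D convolution, and
AdamW with StepLR. Gradients are verified against central differences in
the test suite.

* **CMLP** — shared per-point layers of widths [64, 128, 256, 512, 1024]
  (linear → batch norm → ReLU); the last four layer outputs are globally
  max-pooled over points and concatenated to a 1920-dim feature.
* **Encoder (MRE)** — three parallel CMLPs fed with IFPS resamplings of
  the input at N, N/2 and N/4 points (the farthest-point sampler starts
  at the point farthest from the centroid, making the encoder
  permutation-invariant), concatenated and fused by a two-layer MLP back
  to 1920 dimensions.
* **Generator (MSPG)** — four chained FC blocks (1024/512/256/128 wide).
  The two coarsest features emit a primary set of M/4 points; the middle
  layer emits per-point offsets added to a 2× repeat of the primary set
  (secondary, M/2); the widest layer refines to the detail set of M
  points the same way. Every scale is tanh-squashed into [−1, 1]. The
  2×-repeat-plus-offset realizes the skip-connected coarse-to-fine
  expansion; the exact expansion scheme is this package's reading of an
  under-specified design.
* **Discriminators** — both use the [1→64, 64→128, 128→256] channel
  progression. The spatial discriminator applies per-point blocks (the
  initial layer spans the 3 coordinates), max-pools each layer's output
  over points, and scores the concatenation through an FC head +
  sigmoid. The silhouette discriminator is three stride-2 3×3 conv
  blocks with a global spatial max pool and the same FC head.

Weight init is fan-in-scaled Gaussian from a seeded generator; batch
norm keeps running statistics (momentum 0.9) for evaluation mode. Batch
normalization over a batch of one in training mode degenerates (the
sample is its own statistics); single-sample inference must use
evaluation mode, which the library entry points do.

## Losses and training

Total objective L = λ_com·L_com + λ_dis·L_dis + λ_sil·L_sil. L_com is a
three-scale Chamfer loss: detail vs. ground truth, secondary and primary
vs. one and two farthest-point-sampling halvings of the ground truth,
weighted 1 / α (0.5) / β (0.25). Adversarial terms are standard
non-saturating GAN binary cross-entropies (scores clipped at 1e-7); the
silhouette term averages per-view cross-entropies over the projection
views. Defaults λ_com = 1.0, λ_dis = λ_sil = 0.05.

Hard rasterization carries no gradient, so the generator's silhouette
feedback flows through a *soft* renderer: each projected point splats an
isotropic Gaussian (σ = 1.5 px) and the accumulated intensity is
tanh-squashed; the discriminator's "real" images are soft renders of the
complete cloud so that it discriminates content rather than rendering
style. The hard DARE renderer remains the path for consistency masks and
any exported silhouettes.

Per iteration the two discriminators are updated first (real = ground
truth missing region / soft silhouettes of the complete cloud; fake =
masked generator output, detached), then encoder + generator with the
combined objective. The optimizer is AdamW (decoupled weight decay
1e-4; plain Adam behind a flag), base learning rate 5e-4, batch 16,
StepLR (step 50, decay 0.5) at full scale. Loss curves are tracked raw
and EMA-smoothed with EMA_t = α·EMA_{t−1} + (1−α)·x_t, α = 0.2.

### Desk-scale preset

The package ships a CPU-scale preset used by the tests and the
acceptance script: 40 synthetic plants (10 per species, 32 train / 8
validation), clouds IFPS-downsampled to 384 points, M = 128 (visible
256), all channel widths quartered (latent 480), 5 partition views and
3 silhouette views per plant at 64×64, batch 16, 200 iterations,
learning rate 2e-3 with one 0.5 decay at iteration 100, and loss
weights 1 / 0.01 / 0.01. The chamfer-dominant weighting keeps the short
run in the supervised-convergence regime while still exercising both
discriminators, the consistency mask and the soft renderer end to end;
at full scale the adversarial weights default higher. These sizes were
chosen so the whole demonstration (data synthesis, training, evaluation,
rotation sweep) completes in minutes on a single CPU.

Evaluation predicts the missing region for each held-out (plant, view)
pair and reports dCD (squared-distance Chamfer), dUCD, dHD and F1(τ),
τ = 0.03 in normalized units, per species and overall. Because one
reported table header is ambiguous between UCD and HD, reports always
carry both, labeled. The reference predictor for the training
demonstration is "visible-IFPS": M farthest-point-sampled points of the
visible cloud — a strong baseline whenever missing points interleave
with visible structure, beaten only when the model actually learns
far-side occlusion statistics. Rotation robustness rotates the visible
input about z (30°/60°/90°), predicts, rotates back, and compares
Chamfer distance against the unrotated prediction.

## Phenotype alignment

Completed clouds are restored to metric world coordinates (inverse
normalization, camera-to-world rigid map) and projected into a
calibrated RGB view with the pinhole model u,v ~ K[R|t]X. Each leaf
instance mask is matched to the projected cloud by intersection-over-
union; masks with IOU ≥ τ (default 0.87) claim the points whose valid
projections land on their on-pixels, contested points going to the
highest-IOU mask. Per-leaf area projects the points onto their best-fit
plane, Delaunay-triangulates there, lifts the triangles back to 3-D and
sums their areas, dropping triangles whose longest edge exceeds 5× the
median triangulation edge (guards against bridging separate lobes).
Inclination is the angle between the best-fit-plane normal (smallest
principal component) and the vertical, folded to [0°, 90°].

## Numerical choices and edge cases

* IFPS: seeded uniform start by default (an explicit `start` overrides);
  ties in the farthest-point argmax go to the lowest index.
* PCA normals: sign fixed to positive z, tie-broken by positive x.
* ψ_r and ψ_t are defined as 0 at r = 0 (continuous limits).
* Degenerate normalization axes raise, naming the axis.
* Discriminator scores are clipped to [1e-7, 1−1e-7] with a warning
  before logs.
* Non-finite training losses abort with the iteration index.
* Checkpoints are single NPZ archives carrying every module's weights,
  running statistics and the architecture config as JSON.

## Known limitations

* The fixed output size M cannot spread points over many disconnected
  missing regions; dispersed occlusion degrades completion.
* The desk-scale demonstration shows learnability and pipeline
  correctness, not the accuracy attainable with real scans and
  full-scale training.
* The soft silhouette renderer is a smooth surrogate; its gradients
  vanish for points far outside every splat window.
* Exact hierarchical clustering is quadratic; very large clouds rely on
  the subsample-and-assign path.
* The phenotype module consumes externally produced instance masks; no
  segmentation model is bundled.
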