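# Methods

This note documents the models, simulators and estimators in `skulladapt`,
the defaults they ship with, and what the desk-scale experiments do and do
not demonstrate.

## The problem being modelled

A classifier is trained mostly (or entirely) on *synthetic* images —
renders of 3D specimen assets — and deployed on *photographs*. The two
image distributions differ in background, lighting, colour and noise, so a
source-only model can lose a large fraction of its accuracy on the target
domain even when the morphology it needs is identical in both. The package
reproduces this failure and three mitigations (MMD feature alignment,
fine-tuning, supplementation) in a closed world where every stage is
seedable and cheap.

## Specimen forge

Each species is a vector of seven morphology parameters with fixed ranges:
mediolateral and dorsoventral extent relative to anterior-posterior length
(0.35–0.80, 0.30–0.70), superellipsoid cross-section exponent (1.6–4.0),
rostrum taper (residual cross-section at the anterior tip, 0.20–0.80),
dorsal sagittal-crest amplitude (0–0.22 of length), ventral bump-arc
amplitude (0–0.10) and bump count (3–9) — the last two a tooth-row
analogue. A specimen applies these deformations to a subdivided icosphere
(trimesh primitive); within-species variation is an independent Gaussian
perturbation per parameter with standard deviation 3% of each range.

Default species placement is rejection sampling in range-normalized
parameter space with a minimum pairwise distance of 6 within-species
standard deviations. That margin makes the classification task learnable
by construction (a nearest-centroid classifier on the true parameters is
perfect), which is deliberate: the experiments probe *domain transfer*, not
task difficulty.

Anterior-posterior is the local +x axis. Standardization scales the
bounding box to a target length (default 1 scene unit) and centres the
vertex centroid; it is idempotent and invariant to uniform pre-scaling.
Decimation uses vertex clustering on a uniform grid, binary-searching the
finest resolution that meets the face budget — crude relative to quadric
collapse but irrelevant at render scale, and free of dependencies. OBJ I/O
reads only v/f records (1-based, negative indices resolved per the
standard, polygons fan-triangulated) and writes coordinates with 17
significant digits so a write/read round-trip is lossless.

## Renderer and photo-domain simulator

The camera sits on a sphere around the mesh centroid (yaw/pitch; distance
in units of bounding radius, default 2.5, field of view 35°), up-vector
world-z except at the poles where world-x breaks the singularity; a pole
admits exactly one pose. The default lattice is yaw rings at chosen pitches
plus the two poles; 20° steps at pitches 0, ±30, ±60 with poles give the
classic 92-view protocol.

Rasterization is perspective projection with a z-buffer and flat (per
triangle) Lambertian shading, `ambient + diffuse·|n·l|`, two-sided so thin
features never vanish, over a uniform grey background. There are no
shadows, textures or interpolated normals: the domain gap in these
experiments is *injected by the photo simulator*, not left to renderer
fidelity.

The photo domain composites the render over a turntable-like background
(radial tick marks and a rim at seeded phase/width), then applies
log-normal brightness jitter, per-channel colour cast, Gaussian blur and
pixel noise, with optional log-normal camera-distance jitter. Every
magnitude at zero reproduces the clean render bit for bit — the null-shift
identity the tests pin down. With `session_confound` enabled the background
pattern is keyed by the specimen's species, emulating one photography
session per species on one turntable region: the background becomes a
stable contextual cue that predicts the label at train *and* test time, the
shortcut a morphology-blind model will happily learn.

## Splits, subset, augmentation

Splits are at specimen level within species: `floor(n·test_fraction)` test
specimens, clamped to `[1, n-1]`, membership seeded. With 30 specimens at
0.2 that is 24:6; with 29, 24:5; with 10, 8:2. The subset operation keeps
`floor(keep·n_train)` (minimum 1) training specimens per species — 25% of
an 8:2 split leaves 2:2:6 train:test:unused. Augmentation (supervised
streams only) draws a per-image translation (default ±5% of side),
horizontal flip (p=0.5) and brightness/contrast/saturation/hue jitter
(±10%/±10%/±10%/±2%); the all-zero config is the identity. Images are
resized bilinearly (masks nearest-neighbour).

## Classifier and training regimes

The network engine is a compact numpy implementation (im2col convolutions,
ReLU, 2×2 max-pool, dense layers, softmax cross-entropy, Adam) with
explicit backward passes; its two gradient taps — the flattened
post-convolution feature vector and the final convolutional activations —
feed the MMD loss/t-SNE and Grad-CAM respectively. Backbones: `tiny`
(3 conv blocks, 8/16/32 channels, for 48–64 px inputs) and `vgg19_like`
(the 16-convolution VGG19 layout for 224 px). The head is fixed: max-pool →
flatten → dense (ReLU) → dense → softmax. Pretrained weights can be loaded
from a local `.npz`; nothing is ever downloaded, and all tests use randomly
initialized tiny backbones.

Regimes: `baseline` (labelled synthetic), `photo_baseline`/`photo_subset`
(labelled photos), `mmd` (labelled synthetic + unlabelled photos),
`supplemented` (synthetic + labelled photo subset), `finetune` (from the
MMD model's final weights, cross-entropy on the photo subset, provenance
recorded so epochs report as "N + M"). The MMD term uses the biased
estimator on the flattened features of each joint batch, Gaussian kernel
with median-heuristic bandwidths times {0.5, 1, 2}, weight λ = 1; λ = 0
disables the pathway entirely, making the run identical to the baseline at
the same seed. Optimization is Adam (desk default 2·10⁻³), batch 32, early
stopping on the training-domain test loss with patience counted in
consecutive non-improving epochs; the supplemented and fine-tuned models
instead keep the epoch maximizing the mean of the two domains' test
accuracies (`select_best_epoch` makes that choice explicit and
reproducible). The best monitored weights are restored at the end.

Training is deterministic given the seed at a fixed BLAS thread count;
stochastic claims in the tests are therefore made on seed batteries
(3-seed medians), not bit-exactness.

## Evaluation

Accuracy is the argmax match rate (ties to the lowest class index);
confusion matrices are row-normalized over true labels. Domain confusion is
read from one *joint* t-SNE embedding (scikit-learn, PCA init, perplexity
min(30, (N−1)/3), seeded) of both test sets' features; silhouette scores of
the ground-truth species clusters are reported for the synthetic subset,
the photo subset and the pooled embedding. When a feature extractor maps
the domains onto each other the combined score stays near the per-domain
scores; domain-specific features split each species into two blobs and drag
the combined score down.

Grad-CAM follows the standard recipe: spatially averaged gradients of the
target-class logit w.r.t. the final conv activations weight a rectified
channel sum, upsampled bilinearly and max-normalized. The manual 0–3
"specimen focus" rubric is automated as mask overlap: f = fraction of hot
mass (≥50% of map max) inside the foreground mask; score 3/2/1/0 at
f ≥ 0.9/0.6/0.3. Because the activation grid is 8–12 cells wide, evidence
on the specimen outline blurs a few pixels past the silhouette; the
evaluation pipeline therefore dilates the mask by the upsampling factor
(image side / grid side, ≈4 px) before the overlap is measured. The raw
rubric (no dilation) remains available and is what the unit tests pin down.
This proxy scores *where* the evidence lies, not whether a human would call
it diagnostic; it is a stand-in for manual annotation, not a replica of it.

## Desk-scale study conditions

The shipped desk profile uses 4 species, 6 synthetic and 10 photo
specimens per species (photo split 8:2, 25% subset → 2:2:6 as in a
replication-scale photo bank), 12 views (90° yaw steps at pitches 0, ±30),
64 px renders scaled to 48 px, the tiny backbone, 35 epochs maximum with
patience 10. Sizes were chosen so the full six-regime comparison runs in
minutes on one CPU while test sets stay large enough (48 synthetic / 96
photo images) for stable accuracy estimates.

What passing desk-scale tests shows: the *mechanisms* — a measurable
synthetic→photo accuracy drop produced purely by nuisance factors, its
absence when the nuisances are off, partial recovery by unsupervised MMD
alignment, full recovery by supplementation, the collapse of photo-only
models on the synthetic domain, and background-reliance under a session
confound visible in Grad-CAM focus scores. What it does not show: the
absolute accuracy levels of any real study (real scans have texture,
within-species allometry and scanning artifacts the forge does not model;
real photographs have depth of field, specularities and clutter the
simulator does not model), nor ImageNet-transfer effects, since the desk
backbone is trained from scratch.

## Numerical choices and degenerate inputs

Kernel matrices are computed in float64 from clamped squared distances;
the biased MMD² is nonnegative up to 10⁻¹² rounding. Median-heuristic
bandwidth falls back to 1 when all pairwise distances are zero. The
rasterizer drops triangles crossing the camera plane and raises a
degenerate-view error if nothing projects into the frame. Decimation
refuses budgets that would degenerate a mesh below 4 faces. Splits refuse
species with a single specimen. Silhouettes are undefined (error) when a
subset has fewer than two labels. An all-zero Grad-CAM stays all-zero and
scores 0.
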