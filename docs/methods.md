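# Methods

## Problem and representation

The package estimates a tree skeleton — node positions c_i (meters), branch
radii r_i, and connectivity — from per-view binary silhouettes M_v and
calibrated pinhole cameras. Connectivity is kept *soft* during optimization:
a symmetric logit matrix Ã parameterizes edge probabilities A = σ(Ã), so
topology is refined by the same gradient flow as geometry. All coordinates
are world meters; cameras look down +z in their own frame; pixels are
0-based with centers at (i + 0.5, j + 0.5); extrinsics map world to camera
as x_cam = R x + t.

## Mask fusion

Real deployments produce two mask channels per view: a high-resolution
foreground mask (spatially accurate, semantically promiscuous) and a
language-grounded object mask (semantically targeted, coarse). They are
fused as

    M_final = LargestCC( M_fg ∧ Close(M_lang, s) ),    s = 7 px.

The structuring element is a square (simplest separable choice; the shape is
configurable), components are 8-connected so thin diagonal branches survive,
and morphology uses the standard border convention — dilation pads with
background, erosion with foreground — which makes closing extensive
(output ⊇ input) and leaves an all-foreground mask unchanged.

## Initialization

1. **Mask-consistency filtering.** A 3D point is kept iff its projection
   lands on a foreground pixel in at least N_min views (default 3, or the
   view count if smaller); points behind a camera (z ≤ 1 cm) do not count
   for that view. The default tolerates a few failed segmentations per
   scene.
2. **Outlier removal.** Radius filter (≥ 5 neighbors within twice the
   median nearest-neighbor distance) then a statistical filter (mean
   distance to 20 nearest neighbors within 2 global standard deviations).
   Note that for any bounded homogeneous cloud the statistical stage may
   clip a few surface points whose neighborhoods are half-empty; interior
   points are never affected.
3. **Clustering.** K-means (k-means++ init, fixed seed) with
   K = clamp(round(#points/200), 16, 256) by default, tying the node budget
   to cloud density while bounding optimization cost. The node radius is
   the **median distance of cluster members to the cluster's first
   principal axis** through the centroid — the local cylinder radius —
   floored at 5 mm. The more obvious median distance-to-centroid
   overestimates branch radius by 2–3× for clusters elongated along a
   branch, which later biases the silhouette loss toward making splats
   transparent; the axis variant removes that bias. Clusters with fewer
   than three members fall back to distance-to-centroid.
4. **Topology.** Euclidean MST over centroids (Kruskal; ties broken by
   weight, then lexicographic (i, j)); edge probabilities initialized to
   1 − ε on MST edges and ε elsewhere with ε = 10⁻⁶, stored as logits
   (±13.8155).

## Differentiable silhouette rendering

Each sampled edge contributes N + 1 splats (N = 64 by default) at linear
interpolations of positions and radii; all splats of an edge share the
edge's opacity. Projection is first-order pinhole: image mean
(f_x X/Z + c_x, f_y Y/Z + c_y), isotropic image std
σ = max(f_x, f_y)·s/Z + 0.3 px, clamped at 32 px. The blur floor keeps
sub-pixel splats from vanishing (and from producing needle-sharp gradient
basins); splats behind z_near = 1 cm are culled. A full EWA Jacobian is
unnecessary because the 3D Gaussians are isotropic with fixed rotation.

Per pixel, α = 1 − ∏(1 − o_g G_g) over splats whose footprint covers the
pixel — an order-independent compositing rule (no depth sorting), verified
bit-exact under splat permutation by processing splats in a canonical
sorted order. An alternative per-splat response α = 1 − exp(−Σ o_g G_g) is
available (`alpha_variant="exponential"`).

Two numerical choices matter:

* **Continuous footprints.** Each splat rasterizes a square patch of
  half-width 3σ, and the Gaussian is multiplied by a C¹ smoothstep window
  in u = d²/σ² that is exactly 1 inside (3−1)σ and exactly 0 at 3σ. Without
  the window, the patch boundary jumps across pixel columns as the mean
  moves, and analytic gradients disagree with finite differences at the
  1e-1 level; with it the relative error is ~1e-5. At the splat center the
  window is 1, so compositing closed forms are exact.
* **Analytic gradients.** Forward and backward are hand-derived and
  implemented as numba kernels; `gradient_check` compares every parameter
  group (centers, scales, opacity logits) against central finite
  differences and is part of the test suite (tolerance 1e-3; observed
  ~1e-5).

## Tree projection

`sfs_project` maps the soft adjacency to its maximum-probability spanning
tree: Kruskal MST under weights −log A_ij, retained entries keep their
probability, suppressed entries are zeroed and receive no gradient from
this path (straight-through masking). Because the mask is an MST, the
projected graph is *always* connected and acyclic — the 100% tree rate of
the finalized output is structural, not statistical. When node positions
are available, an infinitesimal distance term (1e-4·d_ij/diag) orders
exact probability ties (edges pinned at either logit clamp) by the
geometric prior rather than by node index; it can never override a real
probability difference. A pure Euclidean weight mode is also available.

## Losses

With Ω_v = dilate(M_v, ρ) ∪ {α > 0.01} (ρ = 5% of image width; recomputed
each iteration, treated as a non-differentiable pixel selection so that
false-positive renderings outside the mask remain penalized):

* L_GS = mean over Ω of |α − M| for the soft rendering, weight λ_GS = 0.1;
* L_MST likewise for the MST-projected rendering, weight λ_MST = 1.0;
* L_rep = Σ_{i<j} exp(−‖c_i−c_j‖²/σ_rep²), σ_rep = 2 cm;
* L_edge-short = Σ_E exp(−‖c_i−c_j‖²/σ_edge²), σ_edge = 2 cm;
* L_angle = Σ softplus(cos θ_ijk − cos 20°) over consecutive-edge triples;
* L_mid = Σ softplus(d_max − ‖m_ij − m_jk‖) over near-collinear pairs
  (direction cosine > 0.90), d_max = 2 cm — the "penalize crowding"
  semantics; the opposite sign is available as `midpoint_variant="printed"`;
* L_radius = Σ_i softplus(r_min − r_i) over nodes, r_min = 1 cm.

Geometry weights default to 0.05 each. Geometry terms are evaluated on the
current hard-MST edge set (stable triples); kernel exponents are ‖·‖²/σ².
All gradients are analytic and validated against finite differences in the
tests.

## Optimization loop

Per iteration: project to the MST; sample splats on the soft support
(probability > 0.01, union the MST edges) and on the MST edges; render both
silhouettes for a deterministic cyclic batch of min(4, #views) views; take
an Adam step on positions and log-radii and a straight-through SGD step on
logits; clamp. The best-total-loss state is returned (view batching makes
the per-iteration loss mildly non-monotone). Radii are optimized as
log-radii so they stay positive. The position step is scaled by the scene
bounding-box diagonal (2e-3·diag), which plays the role of scene
normalization without touching camera extrinsics. Positions are clamped to
the initialization cloud's bounding box padded by 10% of the diagonal: the
skeleton cannot leave the observed volume, and without the clamp nodes
whose branches are sub-pixel receive almost no silhouette gradient and
drift on the never-vanishing geometry-regularizer gradients that Adam
renormalizes to full-size steps.

Two asymmetries in how the two renderings are used proved essential at
working resolutions where branches are 1–3 px wide:

* **Geometry/evidence split.** The MST rendering is drawn with fully opaque
  retained edges and supervises geometry only; the soft rendering (opacity
  = A_ij) carries all adjacency evidence. If the MST rendering instead used
  the soft opacities, partially suppressed edges would render dim,
  under-cover the mask, and drag their endpoint nodes toward unrelated
  silhouette regions.
* **Straight-through, median-centered logit updates.** At the saturated
  initialization the sigmoid derivative is ~ε, so chain-rule gradients
  vanish below Adam's numerical floor and the topology freezes; per-
  parameter normalized updates, conversely, are magnitude-blind and
  suppress weakly and strongly contradicted edges at the same speed. The
  logit update therefore applies the opacity gradient directly (straight-
  through) with plain SGD (lr 200 in opacity-gradient units — sized so an
  edge whose splats consistently overpaint background, gradient ~1e-3 per
  iteration, is suppressed within a few hundred iterations), after
  subtracting the median over sampled edges: rendering sub-pixel branches
  spills a Gaussian skirt over background for *every* edge alike, and this
  common-mode push is a renderer artifact, not evidence against any
  particular edge.

`finalize_tree` recomputes the MST and binarizes the logits to
±logit(1 − ε); its output passes the connected-acyclic check
unconditionally. Divergence (non-finite loss) aborts with a state summary.

## Evaluation

Skeletons are compared as point clouds sampled along every edge at a fixed
spacing (1 mm for meter-scale scenes, 1 cm for the large curved scenes),
endpoints included, shared nodes deduplicated. The Chamfer distance is the
sum of the two directional means of squared nearest-neighbor distances
(KD-tree; the O(n²) brute force serves as the test oracle); a linear
variant is reported alongside since the squared form has units m². Node and
edge deltas are computed after contracting all degree-2 nodes; the tree
rate is the fraction of outputs with |E| = |V| − 1 and a single connected
component.

## Synthetic scenes

One parametric turtle generator spans both study regimes. Each generation
grows a segment then bifurcates with probability 0.85 (children pitched
~branch-angle away at opposed azimuths) or continues with a jittered child;
lengths and radii decay per generation. `curvature > 0` splits segments
into three sub-segments bent by Gaussian angles, yielding organic curved
branches. Presets: **straight** (depth 4, angle 30°, decay 0.75/0.7, trunk
1.4 m × 5 cm — a 2–4 m tree) and **curved** (depth 4, angle 35°, decay
0.8/0.55, curvature 0.18 rad, trunk 5 m × 30 cm — up to ~18 m with strong
taper). Cameras sit on a ring of radius 1.2× the bounding-box diagonal at
mid-height (a partial-arc mode emulates sidewalk-only capture), with focal
length chosen so the tree fills most of the frame.

Ground-truth masks are rendered by the package's own renderer (dense
sampling, opacity 1 − ε, threshold 0.5), keeping supervision and model
consistent; realism stressors are injected separately by the corruption
operators: branch-surface sampling with isotropic Gaussian noise (1 cm
straight / 4 cm curved), deletion of whole contiguous spans totaling a
fraction of skeleton length (fragmentation), uniform outliers in a 1.5×
bounding box, and per-view mask erosion. What passing tests on these scenes
do **not** show: robustness to foliage occlusion, segmentation bias that is
correlated across views, camera-pose error, or radiometric effects — the
masks here are geometrically exact where not explicitly corrupted.

## Problem sizes and reproducibility

The benchmark protocol runs 5 straight and 5 curved scenes (12 views,
128×128, K = 32 nodes, 24 splats per edge, 300 iterations) — a scale chosen
so the whole benchmark reruns from scratch in a few minutes on one CPU
core; the defaults for real use (N = 64, 2000 iterations, native working
resolution 256 px) are correspondingly larger. Everything is deterministic
given the seed: scene generation and corruption use a seeded generator,
K-means has a fixed random state, view batching is cyclic, and rendering is
order-canonical.

At this benchmark scale the acceptance tests observe: 10/10 finalized
outputs are valid trees (structural); Chamfer to ground truth improves over
the initialization in 9/10 scenes (the one regression is a curved scene
whose corrupted-cloud initialization is already unusually good); starting
from the ground truth perturbed by 2% of the bounding-box diagonal,
optimization reduces Chamfer to well under half the perturbed value; and
with the tree projection disabled, the thresholded soft graph fails the
tree check in 5/5 scenes while the projected pipeline never does.

## Known limitations

* Silhouettes cannot pin nodes sliding along a branch axis; node-identity
  errors can grow while skeleton distance shrinks. Metrics are therefore
  skeleton-based, not node-based.
* K is fixed after initialization — no node birth/death — so missing whole
  subtrees can only be covered by stretching existing edges.
* The product compositing saturates inside thick silhouettes, so interior
  pixels stop providing "stay opaque" gradients; the median-centering of
  logit updates compensates for the resulting bias but is a heuristic.
* Depth ordering is ignored (silhouettes only); occlusion-dependent
  appearance is out of scope.
* CPU rasterization is minutes per tree at benchmark scale; it is not
  real-time.
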