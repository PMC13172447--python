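# Methods

## Model

A 3D cellular microstructure is represented by a periodic Voronoi
tessellation inside a cubic window W = [0, L)³: a seed-point pattern
S = {s₁, …, sₙ} ⊂ W, three real parameters per cell. Cell i contains every
point x with d̃(x, sᵢ) ≤ d̃(x, sⱼ) for all j, where

    d̃(x, y) = min over v ∈ {−L, 0, L}³ of ‖x − (y + v)‖

is the Euclidean metric on the 3-torus. Periodic boundary conditions remove
window-edge artifacts: cells continue across the faces, and all descriptors
and adjacency computations wrap accordingly.

The hard membership indicator is relaxed to a softmax over negative
distances,

    Cᵢ(x) = exp(−β d̃(x, sᵢ)) / Σⱼ exp(−β d̃(x, sⱼ)),

which is differentiable in every seed coordinate and recovers the hard
tessellation as β → ∞ (argmax of the soft membership equals the nearest-seed
assignment for every β > 0, since softmax is monotone). Assigning each cell
a random RGB color cᵢ ∈ [0,1]³ and summing color-weighted memberships,
I(x) = Σᵢ cᵢ Cᵢ(x), turns a structure into an image a convolutional network
can score, and compresses the |G| × n membership tensor by a factor ≈ n/3.

## Adversarial fitting

Axis-aligned integer planar grids G_{d,k} (d ∈ {1,2,3}, k ∈ {0,…,L−1}) of
the window are rendered through the soft tessellation into L×L RGB sections.
A fully convolutional patch discriminator D scores the realism of local
24×24 patches of such sections. Two losses drive alternating Adam updates:

    L_T = mean over sampled sections of ‖D(rendered section)‖₁   (seeds)
    L_D = ‖D(measured section)‖₁ − L_T                           (D weights)

Minimizing L_T in the seed coordinates moves cell boundaries so that
generated sections score like measured ones; minimizing L_D in the network
weights sharpens the discrimination. Fresh uniform colors are drawn for
every cell of both measured and generated structures at every iteration
(implicit augmentation; prevents the discriminator from keying on colors).
The ‖·‖₁ of a patch-score map is mean-normalized by default because the
measured (no padding) and generated (cyclic padding) maps have different
sizes; a raw-sum mode is available.

Both losses are minimized exactly as written; the discriminator therefore
learns to score generated sections high and measured ones low, an
equivalent relabeling of the usual convention.

## Discriminator

The first 11 feature modules of a VGG19 network (conv3×3 64, 64, pool,
128, 128, pool, 256 — counting convolutions, activations and pools
individually, ending at the first block-3 convolution), followed by a
spectrally normalized 1×1 convolution to one channel and a sigmoid. Layer
arithmetic gives a 24×24-pixel receptive field; output maps are
(h−4)/…-sized with no padding and h/4 × w/4 with cyclic padding.
Modifications to plain VGG19: LeakyReLU (slope α = 0.2) for gradient flow,
spectral normalization on every convolution (largest singular value
estimated by one power-iteration step per training forward pass, warm-started
at initialization), cyclic padding for periodic inputs and no padding for
measured ones. No pretrained weights; initialization is He-scaled Gaussian
from the run seed.

The network, its backward pass, spectral normalization and Adam are
implemented directly on NumPy arrays (im2col convolutions, explicit layer
caches), so gradients flow both to the weights and to the input image; the
image gradient is chained analytically through the RGB embedding, the
softmax and the periodic distance to the seed coordinates. All gradient
paths are verified against central finite differences in the test suite.

## Parameters

| parameter | default | unit | notes |
| --- | --- | --- | --- |
| β (temperature) | 10 | 1/voxel | sharp transitions ≈ 0.1 voxel wide; rescale if spacing ≠ 1 |
| lr seeds | 3e−1 | voxel | Adam, ~3% of a typical cell diameter per step |
| lr discriminator | 1e−5 | — | Adam |
| iterations | 10,000 | — | canonical; scaled runs use fewer |
| initial seed count | 300 | — | canonical window; scale by window volume otherwise |
| adapt_every | 100 | iterations | seed-count adaptation cadence |
| slices_per_direction | 1 | — | unbiased subsample of the 3L-section loss per step |
| ISO_SMOOTH_SIGMA | 0.6 | pixel | mask smoothing before iso-surface extraction |

## Seed-count adaptation

The number of cells is unknown a priori. Every `adapt_every` iterations the
mean number of cell profiles per unit area is measured on freshly sampled
generated hard sections (n₂D) and on all training images (n′₂D), and
⌊scale·(n′₂D−n₂D)/2⌋ seeds are added (or removed at random, never below one
seed). With scale = L² the step is half the deficit in mean profiles per
section; since the profile intensity of a Voronoi structure grows like
n^(2/3), the update map has slope 1 − 0.486·n^(−1/3) ∈ (0,1) — a contraction
that converges without overshooting. With scale = L³ (profiles per unit
voxel area, selectable via `adapt_scale="volume"`) the same map has slope
1 − 0.486·L·n^(−1/3), which is expansive at practical scales and oscillates;
the package therefore defaults to the area scaling, which realizes the
intended behavior (half the estimated missing-cell count per adjustment).
Floors are taken with a 1e−9 guard against binary representation error.
The floor makes the final approach one-sided: from below, adaptation stalls
once the profile deficit drops under 2, so short runs settle slightly below
the true count (measurement noise across sampled sections keeps nudging the
count upward).

## Synthetic generators

Three point processes emulate the validation structures, canonically 666
seeds in a 100³ window: uniform (binomial process), hardcore (dart throwing
with minimum pairwise periodic distance 10; rejection sampling with a
saturation error when the packing is infeasible), and twinning (222 uniform
initial points, each completed to a collinear triple with companions at
periodic distance 10 along a direction uniform on the sphere via normalized
Gaussians; companions wrap modulo L). These generators emulate cell-count,
spacing and anisotropy statistics of real cellular materials but not
curved boundaries, multimodal size distributions, or segmentation noise —
passing the synthetic recovery therefore demonstrates that the optimization
machinery works, not that Voronoi geometry suffices for every material.

## Descriptors

Per cell of a 2D/3D label image: volume V (grid-point count), equivalent
diameter d_V = 2(V/π)^1/2 in 2D and 2(3V/4π)^1/3 in 3D, boundary measure
S_A (length of the 0.5 iso-contour / area of the marching-cubes iso-surface
of the lightly smoothed binary mask; Gaussian σ = 0.6 keeps digitized
disk/sphere errors under ~3–5% at radii ≥ 5 and the bias falls with radius),
elongation E = λ_min/λ_max of the coordinate covariance (periodic cells are
unwrapped to the image nearest a per-cell anchor — the seed when known, else
the first grid point in scan order; single-point cells are defined as E = 1,
collinear cells give 0), and neighbor count γ under 8-/26-connectivity with
wrap-around adjacency when periodic. For periodic S_A the mask is cyclically
rolled until the cell clears the window boundary (an empty slab per axis is
rolled to the edge) and then zero-padded so the iso-surface closes; this
counts each wrap-around interface exactly once (cyclic padding is the
fallback when a cell spans a full axis, and a cell with no boundary returns
0). Distributions are compared by the exact 1-D Wasserstein distance
∫|F_x − F_y| dt, which carries the descriptor's physical unit.

## Numerical choices

- Distance ties in hard assignment and voxelization break to the smallest
  seed index (deterministic, permutation-auditable).
- Voxel sample points are the integer corners {0,…,L−1}³, matching the
  planar grids; results are translation-equivalent under the corner/center
  choice.
- Softmax logits are max-shifted before exponentiation; at β = 10 in voxel
  units most pixels are saturated and seed gradients flow from the ~1-voxel
  boundary bands, which is exactly where boundary motion is informative.
- Voxelization decomposes squared distances per axis and evaluates in
  x-slabs; results are independent of the chunk size.
- The renderer's gradient guards against a zero distance (pixel exactly on
  a seed) with a 1e−12 floor.
- Seeds are wrapped modulo L after every update; geometry never leaves the
  torus.

## Scaled validation conditions

The recovery experiment sizes the canonical study for one CPU: a hardcore
structure with 40 cells in a 32³ window (minimum distance 6 ≈ 0.64 cell
diameters, the same ratio as 10 voxels at canonical scale), all 96 sections
as training input, 1,500 iterations with 6 sampled sections (2 per
direction) and 4 recolored measured sections per step, initial seed count
10 (300 scaled by window volume), and seed-count adaptation every 15
iterations — the canonical every-100 cadence scaled so the run contains the
same 100 adaptation events as the 10,000-iteration study (with only 15
events the floor-damped adaptation does not finish its one-sided approach).
Success is measured as the final seed count vs the true cell count
and the factor by which training shrinks the 1-D Wasserstein distance of
the pooled 2D descriptor distributions (d_V, E, γ) relative to an untrained
random tessellation with the same initial seed count.

## Known limitations

- Isotropic structures only (one discriminator for all three directions);
  anisotropic extensions need direction-specific discriminators.
- Voronoi cells are convex with planar facets: curved boundaries and
  multimodal size distributions are out of reach of the unweighted model.
- The iso-surface S_A estimator differs from exact-surface estimators by a
  small systematic factor; absolute S_A values carry a few percent bias.
- The NumPy network is single-threaded BLAS-bound; canonical-scale runs
  (100³, 10,000 iterations) are possible but slow, and the renderer's
  gradient tape holds an L²×n×3 array per section.
- Training histories are bit-reproducible for a fixed seed on a given
  BLAS/CPU combination; across different BLAS builds the trajectories can
  diverge while remaining statistically equivalent.
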