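# Methods

This note records the models, conventions and deliberate choices behind
`occlugen`, and what the synthetic test bed does and does not establish.

## Geometry model and conventions

Crown geometry is a triangle mesh in millimetres, right-handed, Z up, with
the occlusal (chewing) surface facing +Z. Meshes are carried as
`trimesh.Trimesh`; OBJ/PLY/STL I/O goes through trimesh, with STL triangle
soups welded at 1e-6 mm so vertex adjacency is well defined, and degenerate
faces dropped on load.

**Curvature.** Per-vertex curvature is the unsigned discrete mean curvature
from the cotangent Laplace–Beltrami operator with *mixed Voronoi* vertex
areas (exact Voronoi cells on non-obtuse triangles, half/quarter triangle
area at/opposite an obtuse corner). Barycentric areas were measurably biased
(+15 % at the valence-5 vertices of an icosphere); the mixed areas recover
the unit sphere to ~1e-5 relative. The estimator is undefined on open
boundaries; boundary vertices copy their nearest interior neighbour's value
(breadth-first). Magnitude-only curvature follows the usage of the cost term
below, which only ever takes differences between neighbouring vertices; a
signed variant was evaluated and did not change fissure-path behaviour on
the synthetic crowns.

## Fissure-line search

The fissure curve between two seed vertices is the edge path minimizing the
accumulated step cost

    λa·f_dir1 + λb·f_dir2 + λc·f_D + λd·f_C ,
    (λa, λb, λc, λd) = (0.75, 0.85, 0.85, 0.55)

Because `f_dir1` depends on the incoming direction, plain vertex-Dijkstra is
incorrect; the search runs over *(vertex, predecessor)* states, which makes
the per-state cost well defined and keeps the optimality argument intact.
Ties break toward the lowest vertex index, so runs are reproducible.

Term scales (the four raw terms have incompatible units): the two angles are
radians in [0, π]; `f_D` is divided by the mesh bounding-box diagonal;
`f_C` by the 95th percentile of |Δcurvature| over all mesh edges. This makes
the weights meaningful as relative priorities. The first step has no
direction history, so `f_dir1 = 0` there; `f_dir2` uses the unit vector from
the candidate toward the leg's goal (zero at the goal itself), the reading
under which the term pulls the line closed.

Closed loops concatenate per-leg optimal paths through an ordered seed list
(≥ 3), joining the last seed back to the first; junction duplicates are
removed and the first vertex is repeated at the end.

**Known limitation.** The optimum of this cost is not always the valley
floor. Two effects matter on the synthetic crowns: (i) on structured-grid
triangulations the per-step turning term makes lattice-aligned "elbow" paths
cheaper than staircases, so paths can cut chords up to ~0.5 mm off a fissure
that runs obliquely to the lattice; (ii) on three-cusp crowns the fissure
ring is small and merges with the central pit into a flat basin where
"below the neighbouring surface" is decided by millimetre-thousandths. The
valley-tracking test therefore uses a four-cusp crown with a well-separated
fissure ring and seeds placed along the groove (saddles and chord
midpoints), where the extracted loop lies below its off-path neighbourhood
at ~99 % of vertices. Denser seeding always tightens adherence; this mirrors
the interactive seeding the workflow assumes.

## Depth images

A depth image is one orthographic −Z ray per pixel centre; the kept hit is
the intersection nearest the projection plane, found with a z-max rasterizer
(numba-jitted, pure-python fallback) rather than generic ray casting — the
two are equivalent for this geometry and the rasterizer is several orders of
magnitude faster at 65k rays × 32k triangles.

Grid: square pixels sized so the XY bounding box fits with a 5 % margin;
pixel (0,0) at the min-x/max-y corner (top-left raster convention); the
projection plane sits γ = 1.0 mm above the model's top (γ is a free
clearance parameter; 1 mm keeps every surface point strictly in front of the
plane). Encoding: `Pixel = round(255 − 255·(d/h)^n)`, round-half-up, clamped
to [0, 255]; points beyond the limit plane (`d > h`, default h = 6.5 mm) and
ray misses are 0. The inverse `d = h·(1 − p/255)^(1/n)` makes
encode∘decode the identity on all 256 integer levels for any valid (h, n).

The enhancement exponent `n` redistributes grey levels; it is selected by
maximizing the mean Shannon entropy of the projected image set over a
candidate grid (ties to the smallest n). On the synthetic crowns the
entropy-vs-n curve is unimodal, as expected from a histogram-spreading
parameter; the selected value depends on the height distribution of the
input set, so the canonical n = 1.4 is kept as the default rather than
re-derived per dataset.

Back-projection emits one point per nonzero pixel at the pixel centre with
`z = plane_z − d(p)`. Its accuracy is limited by 8-bit quantization: the
per-pixel bound `h·(1/(255 n))·(1 − p/255)^(1/n − 1)` (the inverse mapping's
derivative over one grey step) is verified to hold everywhere on a finely
tessellated crown (grid 257, so surface-interpolation error is sub-dominant
to quantization).

## Synthetic crowns and datasets

The generator emulates the *shape grammar* of posterior teeth, not their
statistics: a closed-form height field over an 8×8 mm footprint — Gaussian
dome + 3–5 Gaussian cusps on a ring + a fissure trench of set depth
(0.6–1.0 mm) and width (0.7–1.1 mm) carved along a skeleton polyline —
triangulated on a 129×129 grid (the 257 grid is used where tessellation
error must be negligible). The skeleton is a closed ring through the
inter-cusp saddles plus spokes to the central pit, so the valley network is
connected and a closed fissure loop exists, as on real molars. The opposing
surface is the z-mirrored complement offset so the minimum vertical gap
equals the occlusal clearance (default 0.5 mm); this realizes the jaw-space
constraint exactly and makes "opposing of opposing" the original shape up to
a vertical shift.

Training triplets: `x` is the crown depth image with a disk (default radius
2.5 mm) around the footprint centroid zeroed — the missing occlusal region;
`op` is the opposing tooth viewed from its own occlusal side (rotated π
about x before projection); `y` keeps the depth values within one groove
width of the skeleton and is 0 elsewhere (depth-valued fissure crop rather
than a binary mask — the encoding that preserves the information needed for
back-projection). Datasets are split 75/25 train/test in generation order
(400 samples → 300/100) and are byte-reproducible under a seed.

What passing tests on these fixtures do **not** show: robustness to scan
noise, real anatomical variability, wear facets, or neighbouring-tooth
context — none of which the generator models.

## Adversarial network

Architecture (chosen where the source figures fix only kernel 4×4 and
stride 2): the generator is a U-Net with encoder channels
64-128-256-512-…-512 down to a 1×1 bottleneck (depth log2 R, so 8 stages at
256², 6 at 64²), batch-norm on all but the first and bottleneck stages,
leaky rectifiers (slope 0.2) down and plain rectifiers up, skip
concatenations pairing stage i with stage n−i, tanh output; input is the
2-channel (x, op) stack. The discriminator sees (x, op, candidate) — both
terms of the adversarial objective are conditioned, for symmetry — through
stages 64-128-256 (stride 2) and 512 (stride 1), then a 1-channel stride-1
sigmoid conv: a 30×30 patch-probability matrix at 256². "Layers 2–4" for
the perceptual loss are the post-activation outputs of discriminator conv
stages 2–4.

Objective: patch probabilities are averaged *before* the log; probabilities
are clamped 1e-7 from {0, 1}. The generator minimizes the non-saturating
adversarial term −log D(fake) (the standard stability replacement for
minimizing log(1−D)) plus 100·L1 plus 50·Σλᵢ·Sᵢ; the discriminator
minimizes −(log D(real) + log(1−D(fake))) plus 20·max{0, 0.35 − Σλᵢ·Sᵢ}.
Sᵢ is the size-normalized element-wise absolute deviation of layer-i
activations; the unannotated norms of the L1 and perceptual definitions are
both taken element-wise absolute ("least absolute error"). Ablation groups:
1 = adversarial only, 2 = +L1, 3 = +perceptual; a richer group with its
extra weights set to 0 reproduces the poorer group's losses bit-exactly.

The stochastic input z is realized as generator dropout (p = 0.5 on the
three innermost decoder stages), the standard practice for conditional
translation; noise mode defaults to off, making training and inference
fully deterministic under the configured seed. Images map to [−1, 1] for the
networks; losses are reported on that scale; outputs quantize back to 8 bits
with round-half-up.

Implementation: the layers (im2col convolutions and transposed convolutions
with cached scatter indices, spatial batch normalization for batch size 1,
rectifiers, sigmoid/tanh, inverted dropout) and the Adam optimizer
(β = 0.5/0.999, bias correction folded into the step size — algebraically
the textbook update) are written directly on numpy in float32, with every
backward pass hand-derived and verified against finite differences in
float64 (parameter gradients agree to ~1e-8 relative). One generator
forward per iteration serves both the discriminator and generator updates,
which is valid because the generator's weights change only in its own step.

Training runs one triplet per iteration (batch size 1), discriminator step
then generator step, 200 epochs by default (Table-scale settings); the desk
scale used in tests and the acceptance script is 8 triplets at 64×64 for
200 iterations, which reduces the training-set L1 to ~0.1 of its initial
value in a few minutes on one CPU — a learning-dynamics check, not a claim
about full-scale image quality.

## Evaluation dialects

PSNR uses MAX = 255 and an infinity sentinel at MSE = 0 (serialized "inf"),
keeping monotonicity exact. SSIM is computed from *global* image statistics
— one value per pair, constants C1 = 6.5, C2 = 58.5 on the 0–255 scale —
matching single-number-per-image reporting rather than the windowed variant;
the two dialects are not numerically comparable. Surface deviation is the
perpendicular distance to the nearest point of the reference surface,
*signed* by the side of the nearest face's normal; SD is taken over the
signed values and RMSE is √mean d². Signed deviations are the convention
under which SD ≈ RMSE for an unbiased deviation field and a pure offset
appears in RMSE but not SD; unsigned magnitudes would make the SD of
zero-mean noise ~0.6σ, which is not a useful spread estimate. The
nearest-surface query is a scipy KD-tree over triangle centroids with a
certified candidate radius plus an exact vectorized point-triangle distance.

## Experiment driver and reproducibility

`occlugen experiment` trains the requested ablation groups on a manifest's
train split, generates on the test split, and writes a sample×group
PSNR/SSIM CSV plus a JSON summary. One global seed fans out to per-stage
seeds via SHA-256 of "(seed):(stage name)" (kept below 2³¹), so any stage
can be re-run alone and reproduce exactly. All array computation is
single-threaded deterministic numpy; two runs with the same seed produce
identical loss histories, metrics and bytes on disk.

## Problem sizes

Defaults target desk-scale verification: 129² crown grids, 256² images
(64² for training exercises), 8-triplet training runs of 200 iterations,
400-sample datasets for split checks, and ≤ 12-vertex meshes for the
exhaustive path-search oracle (50 of them). Each was chosen as the smallest
size at which the property being checked is non-trivial.
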