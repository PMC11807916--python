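# Methods

`atriarecon` reconstructs the left-atrial (LA) endocardial surface from
the sparse point cloud traced by a mapping catheter during the initial
bearing manoeuvre — trans-septal entry, then the four pulmonary-vein
(PV) ostia in the order left-superior, left-inferior, right-inferior,
right-superior.  Because paired clinical path/anatomy data are scarce,
the system is trained entirely on synthetic data: a statistical shape
generator produces atrium-like chambers, a path simulator produces
catheter-like trajectories inside them, and a neural network learns the
map from voxelized path to full chamber occupancy.  This note records
the models, the parameters that matter, and the design decisions taken
where the problem was genuinely open.

## Occupancy representation

All volumes live on a cubic voxel grid, by default 45^3 voxels with a
2.666 mm edge length, i.e. a ~120 mm cube centred on the origin —
enough to contain an adult LA with margin.  The voxel figure is read as
an edge length, not a volume: a 2.666 mm^3 voxel volume (edge 1.39 mm)
would span only 62 mm at 45 voxels, too small for the anatomy.  An
occupancy volume marks interior/boundary voxels with 1.  Both the grid
dimensions and the spacing are configurable; the scaled-down benchmark
uses 24^3 voxels at 5 mm (same 120 mm physical extent).

## Synthetic atrium generator

Proper statistical shape models of the LA are learned from CT
segmentations and are proprietary; the generator here is a documented
parametric stand-in, not an estimate of any clinical population:

* **Geometry.** A superellipsoid chamber body (exponent 2.2, semi-axes
  ~32 x 27 x 23 mm), four capsule PV tubes anchored on the body surface
  (radius ~6-6.5 mm, protruding 16-18 mm), a spherical appendage bump
  (radius ~10 mm, anterior-left-superior), and a quadratic bend of the
  whole shape along z (amplitude ~3 mm).  Primitives are blended with a
  soft-min over signed-distance fields (blend width 4 mm), which
  guarantees a smooth, closed genus-0 surface.
* **Statistics.** The 35 shape parameters follow a multivariate normal
  whose covariance is low-rank: 8 frozen latent modes mixed into all
  parameters, with per-parameter standard deviations of ~2 mm on the
  body axes, ~0.06 on direction components, ~0.6 mm on PV radii and
  ~2.5 mm on PV lengths.  A low-rank covariance mimics a PCA-truncated
  shape model and makes the Mahalanobis distance of a typical draw
  ~ sqrt(8) = 2.8, so the plausibility filter (keep samples within
  Mahalanobis distance 3 of the mean) accepts roughly two thirds of
  draws.  With a full-rank 35-dimensional covariance the same filter
  would reject essentially everything (typical distance sqrt(35) = 5.9),
  which is why the rank, not the threshold, was chosen as the free knob.
* **Meshing and voxelization.** The surface mesh is marching cubes on
  the analytic field at 1 mm sampling by default (2.5 mm for the coarse
  benchmark), independent of any training grid.  Landmarks — septum,
  four PV ostia (on the tube/body junction ring) and appendage — are
  placed on the analytic zero level set by 1-D root finding, so they lie
  on the surface by construction.  Generated shapes are voxelized
  through their analytic field (voxel centre inside-or-on test);
  meshes loaded from disk use a generalized-winding-number inside test,
  which is robust to near-degenerate triangles.

What the generator does *not* emulate: real inter-patient topology
variants (common left trunk, five PVs), wall thickness, trabeculation,
the LAA ridge geometry, or any statistics actually learned from CT.
Passing benchmarks on these shapes therefore demonstrates the machinery
(path simulation, training, evaluation) and the relative ordering of
methods, not clinical-grade accuracy.

## Catheter-path simulator

Interior voxels form a 26-connected graph.  An edge of Euclidean length
`s` costs `s * (1 + w / (1 + d_wall))`, where `d_wall` is the mm
distance of the edge midpoint to the nearest non-interior voxel
(approximated by the endpoint average) and `w` (default 2) weights
navigability against pure length.  Least-cost routes between the septum
entry and the four ostium entries (each landmark snapped to its nearest
interior voxel) are computed with Dijkstra's algorithm; the path is
reconstructed by walking back through optimal predecessors, breaking
ties toward the lexicographically smallest voxel index so results are
byte-stable.  With `w = 0` paths hug walls (shortest chords); with the
default weight they bow toward the chamber centre, as clinical
catheters do between targets.

Augmentation models sensor scatter and wall pushing: around every path
point, `n = 5` isotropic Gaussian samples (sigma = 2 mm) are drawn,
kept independently with probability `s_f = 0.5`, filtered to the
chamber interior, and then jittered by `N(0, I) * mu_s` (mu_s = 1 mm).
The jitter is deliberately applied *after* the interior filter, so the
final cloud can slightly exit the chamber.  None of these four values
is dictated by physics; they were fixed once at catheter-plausible
magnitudes and are all configurable.

## Dense encoder-decoder (DED)

A multilayer perceptron over flattened volumes, N -> k -> k -> N with
k = 350.  The input and output layers share one weight matrix W (N x k);
the output map is its transpose, stored once so the tying invariant
survives every optimizer step.  Hidden layers use batch normalization
(momentum 0.1, eps 1e-5) and ReLU; the output layer a sigmoid.  During
training the input is multiplied by a Bernoulli keep mask (drop rate
0.3, no rescaling — the inputs are binary indicators, making this a
denoising-autoencoder corruption rather than standard dropout).

**Loss.** `L(x, z) = alpha * BCE(x, z) - (1 - alpha) * DICE(x, z)` with
alpha = 2/5.  The soft DICE uses linear (not squared) denominator terms
and 1e-7 stabilizers; a squared-denominator switch exists.  Probabilities
are clamped to [1e-7, 1 - 1e-7] inside the BCE.

**Boundary enhancement.** The DICE term is weighted per voxel by a mask
built from D(v), the unsigned Euclidean distance (voxel units) to the
occupancy boundary, and PN, the normal pdf with sigma = 1.5.  Two modes
ship because the printed formula and its stated intent disagree: the
formula `(1 + beta)/(1 + PN(D))` *grows* with distance from the
boundary, while the surrounding description (and the mask's purpose)
require the weight to be maximal on the boundary and decay outward.
The default mode, "peaked", implements the intent as
`1 + beta * PN(D)/PN(0)` — equal to 1 + beta = 15 on the boundary,
decaying to 1 — while "literal" implements the printed expression
(11.85 on the boundary, 15 far away, for beta = 14).  Both are tested.

**Spatial weight-smoothing regularization (SWR).** Each hidden unit's
column of W is a scalar field over the voxel grid; the penalty is the
sum of squared forward finite differences of that field along the three
axes, over all units, doubled because the tied matrix serves both the
input and output layers.  The training objective adds this penalty *as
a per-weight mean*: `L + lambda * penalty / (N k)`.  The named lambda
values (0 = "No SWR", 0.05 = "SWR005", 75 = "SWR75") are only
magnitude-consistent with such a normalization — the raw sum over
N x k ~ 5e6 weight gradients is ~8e3 at initialization on the 24^3
benchmark, so an unnormalized lambda = 0.05 would multiply the
reconstruction loss ~400-fold (empirically this collapses training to
a test DICE of ~0.55, versus ~0.93 without SWR).  With the per-weight
mean, lambda = 0.05 is a gentle prior and lambda = 75 trades a little
overlap for markedly smoother weight maps (roughness drops ~40-fold on
the toy problem), matching the intended behaviour of the variants.

**Training.** Adam (lr 1e-3, batch 20), 100 epochs at benchmark scale;
deterministic per seed; NaN losses abort with the offending batch.  A
"noaug" variant disables both the path augmentation and the boundary
mask.

## V-Net baseline

A volumetric convolutional encoder-decoder: four stages of
conv + batch-norm + ReLU + dropout (0.1) followed by 2x max pooling,
filter counts 16/32/64/128, a bottom block, then four learned 2x
upsamplings (transposed convolutions) with same-size skip
concatenations; 5^3 kernels in the first and last layers, 3^3
elsewhere; sigmoid output.  45^3 inputs are zero-padded to 48^3 and
cropped back.  It trains with the same BCE/DICE mix, uniform mask, no
SWR.  Both networks are implemented directly in NumPy with
hand-written backpropagation (validated against finite differences in
the test suite) and share a single Adam/layer toolkit.

## Mean-shape baseline and clinical-style preprocessing

The baseline reconstruction is the voxel-wise average of all training
occupancy volumes, binarized at 0.5, with landmarks averaged
arithmetically.  Clinical-style inputs are registered into this frame:
per-PV centroids of the tagged ostium points are aligned to the mean
shape's ostia by closed-form least-squares rigid registration
(SVD/Kabsch with reflection correction; collinear tag sets are
rejected), the transform is applied to the whole cloud, and the cloud
is binned into the network grid.  The septum tag is excluded from the
registration by default (four-point alignment).

## Evaluation

Reconstructions and ground truths become meshes by marching cubes at
the 0.5 level (largest component kept).  The symmetric surface
distance is the average of the two directed mean nearest-*vertex*
distances; with a radius restriction, only vertices within the given
radius of at least one PV interest point are counted (the union of
balls — an intersection would usually be empty at 10 mm).  Radii 10,
15, 20, 25 mm and unbounded are reported, plus the Hausdorff distance
(max over both directed maxima) and a paired one-tailed t-test of
improvement over the mean shape (exact Student-t tail on the paired
differences; zero-variance differences degenerate to p in {0, 0.5, 1}
by sign).  Nearest-vertex rather than point-to-triangle distance is
the reported metric because both meshes come from the same
marching-cubes resolution, making vertex densities comparable.

## Benchmark scale and what it shows

The shipped benchmark uses a 24^3 grid (5 mm voxels), 200 training and
50 test shapes, meshes sampled at 2.5 mm, and 100 training epochs —
sizes chosen so the whole study runs on a single desktop CPU core in
minutes.  At this scale the SWR005 network reaches a median held-out
DICE around 0.93 and beats the mean-shape baseline's surface distance
near the ostia with p well below 0.05.  Numbers at this scale are not
comparable to clinical-CT evaluations: the synthetic shapes are
smoother and less variable than real anatomy, the grid is coarser than
45^3, and the "clinical gap" (catheter-specific artefacts, registration
error, protocol deviations) is absent.

## Numerical choices and degenerate inputs

* Binarization uses `>= threshold`, so an all-0.5 volume is fully
  occupied; the map is idempotent and monotone in the threshold.
* Dijkstra tie-breaks are lexicographic; dataset generation, training
  shuffles, masking and augmentation all derive from explicit seeds, so
  identical configurations reproduce byte-identical artifacts.
* Degenerate parameter draws (self-intersecting or non-watertight
  surfaces, PV directions closer than 20 degrees) are rejected and
  resampled; a plausibility acceptance rate below 1% raises a
  configuration error instead of looping forever.
* Shapes that leave the voxel grid raise an error naming the
  overflowing axis; landmarks with no interior voxel within 3 spacings
  raise an error naming the landmark; unreachable path legs raise an
  error naming the leg.

## Known limitations

* The shape generator's statistics are fixed by design, not learned;
  absolute distances on this benchmark say nothing about clinical
  accuracy.
* The path simulator has no temporal/velocity component and no
  catheter-specific geometry (e.g. circular mapping catheters).
* The NumPy networks are CPU-bound; the 45^3 x 350 configuration
  trains, but large-scale sweeps are out of scope.
* Only four-PV anatomy is generated; other variants would need their
  own generator settings and retraining.
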