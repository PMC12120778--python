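# Methods

This note documents the models, estimators, parameter choices and known
limitations of the package, in the order data flows through the
pipeline.

## Coordinate and unit conventions

Label arrays are stored zyx (section axis first); voxel resolution is
given in nm per axis in (x, y, z) order and may be anisotropic (the
defaults emulate serial-section EM: finer in-plane than across
sections). Physical positions are voxel centers, `index * resolution +
offset`, in nm. Volumes are voxel count × voxel volume; all distances
are Euclidean between centroids in nm.

## Detector

The detector is a 2D symmetric U-Net: `depth` levels with feature widths
doubling per level (defaults 16, 32, 64, 128, 256), three 3×3
non-strided same convolutions per step, each followed by instance
normalization and ReLU; 2×2 max pooling between encoder levels; decoder
steps of nearest-neighbor ×2 upsampling followed by a 2×2 convolution,
concatenation with the same-level encoder output, and another
convolution step; a final 3×3 convolution with a logistic head yields
per-pixel foreground probability. Probability maps are binarized with a
closed threshold at 128/255 (a pixel exactly at 128/255 is foreground).

Training uses pixelwise binary cross-entropy on logits with Adam
(lr 1e-3 to 3e-3 at desk scale); neither loss nor optimizer is dictated
by the architecture, so both are package defaults exposed as arguments.
Inputs whose sides are not divisible by 2^(depth−1) are reflect-padded
and the output cropped back, so the spatial contract is exact for any
size. Weight initialization, epoch shuffling and therefore the full
training trajectory are deterministic given the seeds.

The implementation is plain NumPy with hand-written backpropagation (one
GEMM per kernel offset), single-image steps (instance normalization
makes batching unnecessary), float32 arithmetic. Desk-scale experiments
train a reduced configuration (depth 3, features 8/16/32) on 128×128
synthetic sections — about 20 s for 12 epochs × 16 pairs on one CPU —
while the full-width configuration is exercised for the 576×576 forward
contract. Fine-tuning chains are supported by
`UNet.state_dict`/`load_state`.

Evaluation: pixel precision/recall from the confusion matrix (an empty
prediction leaves precision undefined and flagged, not silently 0);
object-level evaluation counts a truth instance as detected when a
single predicted instance covers ≥ 50% of its voxels (the majority rule;
the fraction is an argument since no canonical criterion exists).

## Reconstruction

Instances are 26-connected components (face + edge + corner adjacency)
of the binarized stack, computed on the index grid — anisotropy is
deliberately ignored for connectivity and honored for all physical
measurements afterwards. Labels are renumbered by each component's
first-encountered voxel in a zyx raster scan, making labeling
deterministic. Each instance is assigned to the cell owning the majority
of its voxels; background counts in the denominator, and instances with
majority fraction < 0.5 (or majority background) are flagged ambiguous
and excluded from per-cell summaries.

Skeletonization is medial-axis thinning on the index grid followed by:
26-adjacency graph over skeleton voxels; BFS spanning forest (dropping
any thinning-induced cycle chords); pruning of leaf chains shorter than
1.2× the maximal-ball radius (from the anisotropic Euclidean distance
transform) at their junction — these are thinning artifacts of surface
bulges; chain lengths summed over chords through every 3rd voxel, which
suppresses digital-staircase inflation; and a per-leaf tip extension
obtained by marching the outward chain tangent until the ray exits the
instance. The tip extension matters: thinning retracts a tube's
centerline about one cap radius plus a few voxels short of the true tip,
and the ray restores tip-to-tip length. On axis-aligned capsules of
400–4000 nm the worst length error is ~5%; single-voxel instances are
defined to have length 0 (any nonzero value would be resolution
fiction). The algorithm is pluggable: the contract is the
length/topology property suite, not a particular trace.

Branch statistics for muscle cells: five sections are drawn uniformly
without replacement (seeded) among sections containing the cell; a
cross-section is an 8-connected 2D component of the cell's mitochondria
voxels in that section. Cells spanning fewer than five sections use all
their sections and are flagged. The per-cell value reported is the mean
of the per-section counts (individual counts are also emitted); the
reduction is a package default since only a single per-cell value is
standard in the field's figures.

## Morphometrics

Surface area is exposed-voxel-face counting with anisotropic face areas
(a face perpendicular to x has area dy·dz, etc.). Face counting
over-estimates smooth surfaces by a factor that converges to ~1.5 for
spheres and is stable across radii (tested as a regression property);
because every stage uses the same estimator, all comparative statements
(between cells, classes, stages) are unaffected. Meshing was rejected in
favor of exact testability against a brute-force face enumeration.

MCI = SA³/(16π²V²) is dimensionless and scale-invariant; with smooth
estimators a sphere scores 9/(4π) ≈ 0.716 and a cube 216/(16π²) ≈ 1.368.
Under voxel-face SA the absolute values are inflated by the estimator
bias cubed — only comparisons are meaningful, which is how the index is
used. Per cell, `mean_mci` averages instance MCIs (the neuronal
convention) and `pooled_mci` applies the index to the cell's pooled
ΣSA/ΣV — the muscle convention, where a reticulum is effectively one
instance and instance boundaries are not meaningful.

Volume fraction is ΣV_mito/V_cell and must lie in (0, 1]; a violation is
surfaced as a segmentation-mismatch error, never clamped. SAV is the
pooled ratio ΣSA/ΣV (not a mean of ratios; the pooled value always lies
between the instances' individual ratios). Cells with zero mitochondria
are excluded from summaries rather than given degenerate rows.

The per-cell feature sets are: 8 neuronal features (total and mean
volume, total and mean surface area, total and mean length, volume
fraction, mean MCI) and 5 muscle features (total volume, total surface
area, volume fraction, SAV, pooled MCI).

## Synapse proximity

One presynaptic site per active zone and one postsynaptic site per
(zone, partner) pair; both inherit the zone centroid as their position,
and the postsynaptic site is measured against the partner cell's
mitochondria — the reading required for pre/post comparisons to be
meaningful. Out-degree sums fan-outs over a cell's zones; in-degree
counts received incidences; cells with zero of the relevant degree are
absent from the corresponding analyses, and sites whose cell holds no
mitochondria are excluded with a reason code.

The randomization null assigns every site one uniformly drawn
mitochondrion from its own cell, independently per site and per
configuration; 1000 configurations yield a density histogram (area 1)
summarized by its mean and percentile 2.5–97.5 band. The null is
calibrated by construction against a held-out configuration (a
configuration drawn with an independent seed lies inside the band in
≈95% of bins). Note that the observed *nearest*-distance histogram is
not expected to lie inside this band even for uncoupled placement: the
observed statistic is a minimum over the cell's k mitochondria while the
null draws one uniformly, inflating observed density at small distances
by ~k. The two distributions coincide exactly only for cells with a
single mitochondrion, which is asserted as a separate property.

The near/far threshold operationalizes "the distance where the
cumulative distance distribution starts to saturate (<5% difference)"
as: histogram the distances in fixed 0.1 µm bins from 0 and take the
upper edge of the first bin at which the cumulative fraction reaches
≥ 95% (equivalently, where the remaining tail drops below 5%). The rule
is scale-equivariant; saturation already inside the first bin is flagged
degenerate (threshold = one bin width). Bin width is a configuration
knob; 0.1 µm reproduces the 1.1–1.3 µm granularity typical of these
analyses. "Near" is tie-inclusive (distance ≤ threshold).

## Statistics and embeddings

Pearson correlation with the two-sided t-transform p; constant inputs
are rejected. The Wilcoxon rank-sum test is exact by enumeration for
tie-free combined samples of ≤ 20 (scipy's exact method, cross-checked
in the test suite against a from-scratch enumeration of all rank
splits), otherwise a normal approximation with tie and continuity
corrections; the variant used is recorded in the result. P-values below
1e-20 are displayed as "P ≈ 0". No multiple-testing correction is
applied anywhere — raw rank-sum p-values are reported.

PCA standardizes each feature column (zero mean, unit variance),
projects onto the first two components, and fixes signs so each
component's largest-magnitude loading is positive (reproducible
embeddings). UMAP uses the same standardization with n_neighbors = 15,
min_dist = 0.1 and a fixed random_state, making coordinates
deterministic given the seed; hyperparameters are recorded in output
metadata. Zero-variance columns are an error naming the column.

## Synthetic worlds

The generator produces the statistical structure the analyses assume,
not anatomy:

* **Neurites** are straight tubes (default radius 160 nm) along the
  section axis on a lattice with ≥ 4 voxels between surfaces, so
  instances can never merge across cells. Default resolution
  (16, 16, 32) nm, tube length 800 sections (≈ 25.6 µm).
* **Neurite mitochondria** are capsules of radius 80 nm centered on the
  tube axis; tip-to-tip length is clipped-lognormal (median 800 nm,
  σ = 0.35, clipped to 400–2400 nm), matching the pill-shaped,
  rarely-branching morphology of neurite mitochondria. Capsules are
  rasterized by exact point-in-capsule tests at voxel centers, so true
  volume, surface area and length are analytic. Within a tube, capsules
  keep ≥ 2 empty sections between them; placement failure after 200
  retries raises a capacity error naming the cell.
* **Active zones**: per-neurite zone counts Poisson(12); fan-out over
  1–5 with pmf (0.14, 0.627, 0.19, 0.034, 0.009), the normalized adult
  per-fan-out site counts; physical size log-linear in fan-out
  (slope 0.5 per partner on log voxel count, base 30 voxels, lognormal
  noise 0.4). Zone centroids sit just inside the presynaptic tube
  surface, leaning toward the first partner. In a single-neurite world
  zones are self-partnered (autapse-like) so the polyadic invariant
  holds.
* **Placement coupling**: with probability `coupling_kappa` (default
  0.6) a mitochondrion is centered within ±`coupling_radius` (default
  500 nm) along the centerline of a uniformly chosen synaptic site of
  its cell; postsynaptic sites use a window `pre_post_asymmetry` (2×)
  wider, which reproduces the pre-closer-than-post distance ordering.
  Coupling is defined along the centerline (path distance) and realized
  in 3D — bouton-local placement, not ambient Euclidean placement.
* **Counts**: per-cell mitochondrion counts are either constant,
  Poisson, or degree-coupled — a latent Gaussian targeting a Pearson
  correlation (default 0.6) between count and out-degree with marginal
  mean 8, sd 3, clipped at 1. Clipping and rounding attenuate the
  realized correlation mildly; the recovery experiment measures ≈ 0.6
  through the full reconstruction path.
* **Muscles** are axis-aligned slabs, each holding one reticular
  mitochondrion: a spine strand along the section axis plus
  Poisson(6)-many comb branches (parallel strands attached by rungs,
  radius 60 nm), kept connected by construction. This is sufficient for
  branch counting, SAV and pooled-MCI statistics; it makes no claim
  about muscle anatomy.
* **2D training pairs**: smooth bright background (clipped at ≥ 0.6),
  darker elliptical mitochondria (interior ≈ 0.32 with sinusoidal
  internal stripes), additive Gaussian noise (default σ 0.05); masks are
  the exact generating ellipses and each pair's foreground fraction lies
  inside a configured band (3–18%).

One global seed drives every sub-generator through spawned seed
sequences: a world is a pure function of its spec, byte-identical across
runs.

**What passing on synthetic worlds does and does not show.** It shows
the measurement chain is correct: components, assignment, surface area,
lengths, distances, nulls, tests and embeddings recover planted
parameters under known ground truth. It does not show detector accuracy
on real EM texture (the pairs are cartoons of contrast, not of
ultrastructure), nor robustness to segmentation errors, section
artifacts, or curved/branching neurites — real neurites are not straight
tubes and real mitochondria are not perfect capsules.

## Problem sizes

Validation experiments use worlds of 25 neurites × 25.6 µm (≈ 300 zones,
≈ 950 sites, ≈ 200 instances, 800×200×128 voxels, ≈ 2 s to generate),
1000 null configurations, 20 worlds for the correlation recovery, and a
depth-3 detector trained on 16 pairs of 128×128 sections with 8 held
out. These sizes were chosen so the full suite and the acceptance script
each complete in minutes on a single CPU while keeping ≥ 500 sites where
rank tests are asserted.

## Known limitations

* Voxel-face surface area carries a ~1.5× smooth-surface bias (absolute
  MCI/SAV values are estimator-specific; comparisons are not).
* Skeleton length assumes tube-like instances; for highly oblate or
  space-filling shapes the centerline-length concept itself degrades.
* The cross-section branch statistic depends on strand orientation
  relative to the sectioning axis; the generator orients muscle strands
  along the axis accordingly.
* Manual proofreading of reconstructions is represented only as an
  optional deterministic merge/split edit step, not interactive tooling.
* The saturation-threshold bin width (0.1 µm) and the object-detection
  overlap criterion (50%) are exposed defaults, not canonical constants.
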