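# cemito

Quantitative reconstruction and analysis of mitochondria in volumetric
electron-microscopy segmentations of the *C. elegans* neuromuscular
system, with a ground-truthed synthetic-volume generator so the whole
pipeline can be validated without terabyte-scale EM data.

## Who this is for

Connectomics and cell-biology groups who have (a) labeled 3D cell
segmentations, (b) mitochondria masks or probability maps from a
per-section detector, and (c) synapse tables (active zones with ordered
postsynaptic partner lists), and who want per-cell mitochondrial
morphometrics and synapse–organelle proximity statistics with proper
randomization nulls.

## What it computes

* **Detection** — a 2D symmetric U-Net (5 levels, feature maps
  16/32/64/128/256, three 3×3 same convolutions per step with instance
  normalization and ReLU, max-pool down, nearest-neighbor upsample + 2×2
  convolution up, concatenation skips, sigmoid head) producing per-pixel
  mitochondria probabilities, binarized at 128/255. Pixel- and
  object-level precision/recall evaluation. Implemented in NumPy with
  explicit backpropagation; trainable at desk scale.
* **Reconstruction** — 3D instances as 26-connected components of the
  thresholded section stack; majority-vote assignment of instances to
  cells; TEASAR-flavored skeletonization (medial-axis thinning, spur
  pruning, tangent-ray tip extension) for length; pseudo-random
  five-section cross-section counts for branch statistics.
* **Morphometrics** — per-instance volume (voxel count × voxel volume),
  exposed-face surface area with anisotropic face areas, and the
  mitochondrial complexity index

  MCI = SA³ / (16 π² V²),

  a scale-invariant shape score (sphere → 9/4π ≈ 0.716 under smooth
  estimators, higher for branched/reticular shapes); per-cell summaries:
  totals, means, volume fraction (ΣV_mito / V_cell), pooled
  surface-area-to-volume ratio SAV = ΣSA / ΣV.
* **Synapse proximity** — per-cell out/in-degree (a zone with fan-out 3
  adds 3 to its presynaptic cell's out-degree), Euclidean
  centroid-to-centroid distances from pre- and postsynaptic sites to the
  nearest mitochondrion of the same cell (postsynaptic sites inherit the
  active-zone centroid and are measured against the partner cell), a
  1000-configuration random-assignment null with a percentile 95% band,
  the cumulative-saturation (<5% tail) near/far distance threshold, and
  near-vs-far size comparisons.
* **Statistics & embeddings** — Pearson correlation, two-sided Wilcoxon
  rank-sum (exact by enumeration for small tie-free samples; p < 1e-20
  displayed as "P ≈ 0"), standardized-feature PCA (8 neuronal features)
  and seeded UMAP (5 muscle features).
* **Synthetic worlds** — lattices of tubular neurites with capsule
  mitochondria whose placement can be coupled to active zones, polyadic
  synapses (fan-out 1–5, size log-linear in fan-out), reticular
  body-wall-muscle stand-ins, and paired 2D image/mask sections for
  detector training — all analytically bookkept for parameter-recovery
  tests.

## Worked example

```python
from cemito.synthetic_data import SyntheticSpec, CountLaw
from cemito.pipeline import RunConfig, run_pipeline

spec = SyntheticSpec(n_neurites=9, n_muscles=2, tube_length_voxels=300,
                     mito_count_law=CountLaw(kind="poisson", mean=4), seed=7)
cfg = RunConfig(out_dir="out", synthetic=spec, n_null_config=1000, seed=7)
manifest = run_pipeline(cfg)
```

This generates a labeled world, reconstructs instances by 26-connected
components, measures them, and writes `mitochondria.csv`,
`features.csv`, `distances.csv`, `null_summary.csv`, `tests.csv` and a
`manifest.json`. On this seed it prints/records:

```
n instances: 24                      # reconstructed = generated, none lost
median volume: 1.50e7 nm^3
median skeleton length: 777.6 nm     # capsule lengths drawn around 800 nm
median MCI: 4.91                     # elongated capsules score well above a sphere's 0.716
median d_mito_pre: 0.922 um, median d_mito_post: 1.152 um
d_mito_pre_vs_post: rank-sum p = 0.00196   # pre sites sit closer, as placed
out_degree_vs_n_mito: r = -0.22 (p = 0.566)  # Poisson counts: no coupling, none found
```

The same run is available from the shell: `cemito synth --out world/`
generates a world, `cemito run --config run.toml` executes a full
configured pipeline, `cemito convert a.h5 b.tif` moves volumes between
containers.

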