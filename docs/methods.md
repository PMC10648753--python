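# Methods

## Data model and conventions

A CT volume is a grid of signed 16-bit grayscale values (GSVs), indexed
`values[x, y, z]`, with x varying fastest on disk (headerless RAW plus a
plain-text sidecar carrying shape, spacing, dtype and byte order — the RAW
format itself records none of these, so the sidecar makes them explicit
rather than guessing a vendor convention; little-endian is the default).
Voxel spacing defaults to 0.160 mm isotropic, the resolution of the
desktop scanner this pipeline targets; anisotropic spacing is supported
throughout because slice stacks often differ in z.  Crop boxes are
half-open `[lo, hi)` with 0-based indices.  Voxel centers sit at
`(i + 0.5)·h`.

## Segmentation chain

Pores and exterior air have identical attenuation, so the pore phase is
recovered indirectly:

1. **Matrix band threshold** — voxels with GSV in the closed interval
   [−750, −250] (config default).  Closed endpoints: the printed band
   notation does not state endpoint semantics, and at integer GSVs the
   choice moves a vanishing fraction of voxels.
2. **Fill holes** — background components not connected to a volume face
   are set true.  The background flood is 6-connected by default, the
   topological dual of the 26-connected foreground used for labeling.
3. **Mask arithmetic** — `filled AND NOT matrix` isolates interior pores.
4. **Ball opening** (erosion then dilation, digitized Euclidean ball,
   default **radius** 3.0 voxels) separates pores touching at thin necks
   and removes threshold speckle.  The "size" of an opening element is
   stated as a radius here; tools that specify a diameter need the config
   value doubled.  Voxels outside the grid count as background in both
   passes.
5. **Label analysis** — 26-connected components, renumbered so label k is
   the k-th component in raster order (deterministic output).

Porosity is measured on the *pre-opening* pore mask (opening is a
separation step, not a volume estimate); per-pore statistics are measured
on the post-opening labels.  Per-day summaries could also be computed on
pre-opening components; the pipeline labels its outputs with the mask they
came from.

**Balanced histogram threshold.**  The histogram is a scale whose
endpoints are the outermost nonempty bins; the masses strictly left and
right of the running midpoint are compared and the outer bin of the
heavier side removed until one bin remains (its lower edge is returned).
On exact balance both outer bins are removed symmetrically — a one-sided
tie rule would end one bin off-center on symmetric input — except that a
balanced two-bin range drops the right bin.  This automatic threshold is
offered as the alternative to the fixed band; on default phantoms it lands
between the air mode (−1100) and the matrix mode (−500).

## Morphometry

* **Volume** is exact for a voxel set (count × voxel volume).
* **Surface area** is the triangulated isosurface at the 0.5 level of the
  label's indicator, mildly Gaussian-smoothed (σ = 0.6 voxels) first: a
  raw binary isosurface carries a ~+8 % staircase bias on smooth blobs,
  while smoothing shrinks the level set by curvature; at this σ the two
  effects cancel to within a few percent for pores of radius ≥ 5 voxels.
  Labels of a couple of voxels fall back to the raw binary isosurface
  (their "area" is resolution-limited no matter what).  Exposed-voxel-face
  counting was rejected: it overestimates smooth surfaces by ~1.5×.
* **EqDiameter** `(6V/π)^{1/3}` is computed from the label's own volume.
* **Length/Width** are the max/min directional Feret extents of the
  label's voxel *corner* points (corners, not centers, so a single voxel
  has nonzero extent) over a fixed direction set: the 13 canonical grid
  directions (axes, face and body diagonals — making axis-aligned extents
  exact and the measurement invariant under 90° rotations) plus a
  deterministic golden-angle Fibonacci sphere, 128 directions total.
  Directional discretization error is ≤ ~2 % for compact shapes; extents
  are computed on the convex hull for speed.
* **Size distribution** bins EqDiameter into half-open [lo, hi) bins,
  default edges 0, 2, 4, 6, 8, 10 mm; pores at or beyond the last edge go
  to a separately reported overflow count.
* Border-touching pores are measured and flagged; summaries include them
  by default with a config switch to drop them.
* **Local ROI analysis** samples cubes of 45 voxels per side and reports
  the fraction of voxels in the pore GSV band (−1250..−1000 by default).

## Pore-throat network

The pore mask is thinned with scikit-image's 3D skeletonization.  The
thinning can annihilate very small blocky components outright; since the
contract is topology preservation, any mask component left without a
skeleton voxel gets one anchor voxel restored at its deepest interior
point (first in raster order on ties).  Skeleton voxels with a 26-neighbor
count ≠ 2 become nodes; maximal degree-2 runs become segments; components
that are pure cycles get a deterministic anchor node (lowest voxel in
raster order) and one closed segment.

Radii come from the exact Euclidean distance transform (center-to-center
convention: a voxel one step from the background has distance one
spacing).  A segment's **throat radius** is the minimum distance value
along its polyline — the bottleneck between the pore bodies it connects.
Two refinements keep dead ends from polluting the statistic:

* **Spur pruning**: leaf segments shorter than `prune_factor` (default
  1.0) times the distance-map radius at their junction are thinning
  artifacts of wide pore bodies and are removed before the final graph is
  built (one rebuild pass, logged).
* **Cap trimming**: at a degree-1 segment end, the strictly increasing
  run-in of distance values (the approach to the closing wall) is skipped
  before taking min/mean — a dead end's wall is not a throat.  With this,
  cylinder phantoms of radius 3–8 voxels recover their radius within half
  a voxel.

## Synthetic phantoms

The generator emulates the imaging situation the pipeline is built for,
with exact ground truth (per-voxel phase grid and sphere list):

* Ellipsoidal body; matrix GSV ~ N(−500, 80²) so ≥ 99.7 % of matrix voxels
  fall in the −750..−250 band; pores and exterior air share
  N(−1100, 40²) so ≥ 99 % of pore voxels fall in −1250..−1000.  The pore
  σ of 40 (rather than the matrix's 80) is what makes the printed pore
  band capture the phase at the ≥ 99 % level; the two phase distributions
  must separate at ±3σ or the spec'd bands cannot work, and this is
  validated at construction.
* Pores are spheres with log-normal radii (median 0.9 mm, log-σ 0.3 for a
  single phantom), centers uniform in the body, rejection-sampled so each
  sphere keeps ≥ 0.5 mm (`wall_clearance_mm`) of matrix between itself
  and the exterior — without the clearance, pores tangent to the surface
  leak to the outside air and hole filling (correctly) refuses to close
  them.  Overlaps are allowed: merging pores are part of the aging process
  being emulated.  `target_porosity_pct` places spheres until the
  phase-grid porosity reaches the target (the final sphere may overshoot
  by a fraction of a point; ground truth is always the exact grid ratio).
* Exterior air deliberately shares the pore GSV distribution — both are
  air — which is precisely why the pipeline must use fill-holes + mask
  arithmetic instead of a single threshold.  This tests the chain, not
  just a threshold.
* Optional delamination: a planar air slab clipped to the body with the
  same wall clearance, emulating the skin/crumb separation gap of aged
  buns.

**Storage series** (5 days): porosity endpoints 23.5 → 28.8 % and sample
volume 165 → 126 mL are the reported day-1/day-5 values for stored buns;
pore radius median grows 0.85 → 1.15 mm (consistent with a size
distribution dominated by 0–4 mm diameters whose large tail grows).
Moisture trajectories (center 45 → 42 %, crumb 43.5 → 39.5 %, skin
41 → 35 %) are free parameters chosen to be realistic for steamed bread
and to preserve the center > crumb > skin ordering, which the generator
enforces by sorting the three noisy values (rearrangement is rare at
default noise).  Hardness = 464.6 − 10.1 × moisture_center + N(0, 1²) N,
calibrated so the default moisture trajectory maps onto the reported
10.1 → 40.4 N range.  Moisture noise defaults to the level at which the
population moisture–porosity R² is 0.94 (the reported fit quality), i.e.
σ = sd(signal)·√((1−R²)/R²); with n = 5 design points the *fitted* R² of
a single series is noisy and its Monte-Carlo mean is biased upward by
~0.02, which is why the calibration check averages 200 covariate-only
replicates.  Setting all noise σ to 0 makes hardness exactly affine in
moisture and moisture exactly affine in the nominal porosity — the exact
r = −1 / R² = 1 degenerate case used in tests.  Each day's phantom seed
derives from the series seed via `SeedSequence`, so a series is
bit-reproducible.

**Problem sizes.**  Porosity is a voxel-count ratio and scale-free, so the
series can be run at a fraction of the physical sample volume via
`volume_scale`; the shipped tests and the acceptance script use
`volume_scale = 0.02` (≈ 3.3 → 2.5 mL per day, ~10⁶-voxel grids) for the
series and ~200-voxel-class single phantoms (≈ 11 mL) for porosity
recovery.  These sizes give dozens-to-hundreds of pores per phantom, enough
for stable means, and were chosen as the package's standard benchmark
configuration.

## What the phantoms do and do not show

Passing recovery tests on phantoms demonstrates that the chain is unbiased
under its own assumptions: two well-separated Gaussian GSV phases,
spherical pores, no imaging physics.  Real scans add beam hardening, ring
artifacts, partial-volume voxels at walls thinner than ~2 voxels, and
non-spherical pores; band edges and the opening radius will need
per-instrument tuning there, which is why every printed constant is a
config default rather than a literal in code.  The phantom's uniform pore
placement also means it has no center-to-skin density gradient unless one
is imposed.

## Statistics

Correlations are Pearson product-moment over per-day means (n = days), the
mode matching how replicate samples are averaged per storage period in
practice; a per-sample mode is a config choice.  Constant inputs raise
rather than returning a silent 0 — r is undefined there and a degenerate
design should be visible.  Missing rows are dropped complete-case and
logged.  The moisture–porosity fit is plain OLS; for simple regression R²
equals the squared Pearson r, asserted as an invariant.  p-values are
available but unadjusted and, at n = 5, descriptive only.

## Known limitations

* Throat radii are skeleton-sampled distance values, not maximal-ball
  pore-body partitions; no flow or percolation modeling.
* Surface area below ~5-voxel radius is resolution-limited.
* The generator does not model dough rheology, X-ray noise spectra, or
  spoilage; its trends are affine between endpoints.
* Label analysis measures every component of the opened mask, including
  clusters the opening could not separate; these appear as large pores in
  the size distribution's overflow bin.
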