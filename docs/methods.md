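# Methods

## Scope and data model

The package analyses whole-brain cell coordinates: tables of
`(x_um, y_um, z_um, cell_type, subject_id, group)` rows, one row per
detected nucleus, registered to a labelled reference volume. All world
coordinates are micrometres and corner-anchored: voxel `(i, j, k)` of a
label volume with spacing `(sx, sy, sz)` spans the half-open box
`[i·sx, (i+1)·sx) × …`, and a point maps to `floor(coord / spacing)`. A
point exactly on a shared voxel face therefore belongs to the higher-index
voxel; points outside the volume are counted and assigned the background
label 0. Label volumes are stored as NIfTI with the spacing in the affine;
image stacks as multi-page TIFF in `(z, y, x)` page order.

## Density-based spatial parcellation

**Neighbor counts.** For each cell, the number of *other* cells of the same
type within Euclidean distance ε, boundary inclusive
(`‖p − q‖ ≤ ε`, self excluded). The default ε = 150 μm reflects the scale at
which local cell density is a meaningful anatomical signal for nuclei
spaced tens of μm apart. Counts are computed with a k-d tree but are
contractually identical to the all-pairs definition (verified exactly
against an O(n²) oracle).

**Percentile thresholds.** Each subject (imaged brain) is an independent
dataset: counts are computed per `(cell type, subject)` on that subject's
own points. For each of the nine decile levels (10th–90th), the percentile
of each subject's count distribution is taken with linear interpolation
between order statistics, averaged over subjects, and multiplied by the
number of subjects — giving the pooled-cloud `MinPoints` (rounded to the
nearest integer, .5 up). Dividing the subject-mean percentile by
`V_ε = (4/3)π(ε/1000)³ mm³` expresses each threshold as a per-brain density
in cells/mm³ (at ε = 150 μm, one neighbor ≈ 70.7 cells/mm³). Subjects with
no cells of a type are excluded with a warning.

**DBSCAN.** Classical semantics with two fixed conventions: the core
condition is `count ≥ MinPoints` with the self-excluded count above, and a
non-core point within ε of a core point joins the cluster of its
*lowest-index* core neighbor (full determinism given input row order;
classical DBSCAN leaves this tie arbitrary). Cluster ids are numbered by
each cluster's smallest core index; noise is −1. Including the point itself
in the count would shift every threshold by exactly one neighbor
(≈ 71 cells/mm³ at ε = 150 μm) — negligible, but all reference
implementations used in tests adopt the same convention so comparisons are
exact.

Implementation: at realistic densities a cell can have thousands of
ε-neighbors, so the full neighborhood graph is never materialised. Core
flags come from count-only tree queries; core connectivity is resolved by
binning core points into grid cells of side ε/√3 (cell diameter ε, hence
points sharing a cell are pairwise ε-close) and uniting nearby cells after
an exact minimum-cross-distance check, skipping pairs already connected;
border points are assigned via chunked sparse distance queries against the
core set. The result is identical to the textbook algorithm (property-tested
against a brute-force all-pairs + BFS reference) but runs in near-linear
time on dense blobs.

**Percentile sweep.** One DBSCAN per level on the pooled cloud (union of
subjects' points) with the pooled MinPoints, counts computed once and
shared. Because the per-point counts are fixed and MinPoints is
non-decreasing in level, core sets are nested across levels — high
percentiles isolate progressively denser foci. Parcels are compared to
atlas regions by Dice and Jaccard over point-index sets.

Open points resolved here: the pooled cloud is the default clustering
substrate (matching the pooled-MinPoints construction; single-subject runs
are just the same call on one subject's table), and percentile densities
are computed from all cells, before any noise classification.

## Region quantification and composition clustering

Density = count / region volume (mm³), per `(region, type, subject)`;
the aggregate is the unweighted mean over subjects, with explicit zeros for
subjects lacking cells in a region. Max normalization divides each cell
type's regional densities by that type's maximum (all-zero types stay zero,
flagged) so each profile lies in [0, 1] with its peak region at exactly 1.

Regions are compared by `d(r, s) = 1 − Pearson r` between normalized
composition profiles (range [0, 2]; constant profiles are rejected by name
since their correlation is undefined). Agglomeration uses Ward's
Lance–Williams recurrence applied to these dissimilarities. Ward is,
strictly, defined for squared Euclidean distances; applying it to
correlation dissimilarities is a pragmatic, widely used choice and is
implemented exactly as stated. The agglomeration is an explicit O(n³) loop
(region counts are small) with a deterministic tie-break — candidate pairs
at equal distance merge in lexicographic order of their smallest leaf
indices — so trees are reproducible across platforms; it agrees with
SciPy's Ward linkage on tie-free inputs. Flat labels at k clusters undo the
last k−1 merges; the cut level is the analyst's choice (no automatic k).

## Two-group comparison

Per `(region, cell type)` with ≥ 2 subjects per group, Welch's
unequal-variance t-test on per-subject densities (Mann–Whitney U available
behind a flag); pairs with fewer subjects are flagged untested. The
Benjamini–Hochberg step-up controls FDR jointly across all tested pairs;
effects are reported as ratios of group means. When both groups are
constant the statistic degenerates to comparing the constants (0 / p = 1 on
equality). Note Welch's test at n = 8 per group is mildly conservative
(raw type-I ≈ 0.047 at nominal 0.05 in the calibration simulation) — a
property of the Satterthwaite approximation, inherited by design.

## Nuclei detection

The detector scores voxels by local image curvature: Gaussian-derivative
second-order tensor at a physical scale σ (μm, default = nucleus radius),
converted per axis into voxels. A bright blob has all tensor eigenvalues
negative; the score is the product of the clamped negative responses. When
an axis is unresolvable at the requested scale (σ below half a voxel pitch,
e.g. 3 μm nuclei against 50 μm section spacing) the tensor is computed
per-slice in the resolved plane — the stack is never resampled — while
component extraction stays fully 3-D (26-connectivity). The score is
thresholded at a percentile of its own distribution (default 99.7; robust
to intensity units, and invariance to affine intensity rescaling is
inherited from the [0, 1] rescale in preprocessing), followed by a
component-size filter (default ≥ 5 voxels) and score-weighted centroids in
μm. Detections are validated by optimal one-to-one matching (Hungarian
algorithm maximising matches within a radius, then minimising total
distance), yielding precision/recall/F1 and centroid errors.

The companion preprocessing operator for registration — gamma compression
of [0, 1]-rescaled intensities followed by a per-slice 3×3 Sobel gradient
magnitude — is included as `enhance_features`.

## Synthetic data generator

The generator emulates the statistical structure of multi-subject
whole-brain datasets, not their anatomy:

- **Toy atlas** — axis-aligned boxes and spheres rasterised by voxel-center
  membership onto a 50 μm grid; region volumes are voxel counts × voxel
  volume. Overlapping regions (a voxel center in two geometries) are
  rejected by pair. The shipped demo brain is 4×4×4 mm with 8 regions.
- **Point clouds** — per (region, cell type), a homogeneous Poisson process
  of the stated intensity (cells/mm³), sampled as a Poisson total over the
  region's voxels placed uniformly inside uniformly-chosen voxels (exact
  for the voxelised support, and fast for sparse atlases). Optional
  multiplicative group effects (e.g. a ×1.2 "male" factor on one type)
  scale intensities per (type, group). Demo intensities span
  2×10⁴–5.3×10⁵ cells/mm³ — the realistic regional density range — sized so
  a 6-subject cohort is ≈ 10⁵ points.
- **Image stacks** — nuclei as additive isotropic Gaussian blobs
  (sd = `sqrt(radius² + psf²)`) on a constant background with i.i.d.
  Gaussian noise, at STPT-like 1×1×50 μm spacing. Detection scenes place
  nuclei at z-slice centers (a µm-scale nucleus is captured by a single
  50 μm optical section) with a minimum in-plane separation (default
  15 μm), emulating fields sparse enough that nuclei rarely touch.

What the generator does *not* model — registration error, anisotropic PSF
tails, autofluorescence gradients, inhomogeneous within-region intensities,
cortical layering — bounds what green tests mean: they certify the
analysis machinery (exactness of counts and clustering, calibration of the
statistics, parameter recovery at realistic scales), not robustness to
real-microscopy artefacts.

Randomness: every public sampler takes one seed; cohorts derive per-subject
streams as `SeedSequence(seed).spawn(n)` children in subject order, so any
subject's cloud is reproducible independently of the rest.

## Numerical conventions and edge cases

- Percentiles: linear interpolation between order statistics; MinPoints
  rounding: nearest integer, .5 up. MinPoints→density→MinPoints round-trips
  are the identity; density→MinPoints→density errs below one neighbor
  (1/V_ε ≈ 70.7 cells/mm³).
- `minpoints = 0` makes every point core (clusters = ε-connected
  components); `minpoints > n − 1` makes everything noise.
- All-zero cell types survive normalization as zeros with a warning;
  zero-volume regions are rejected for density computation.
- Distance matrices must be symmetric, non-negative, zero-diagonal;
  correlation distances are clipped to [0, 2] against floating-point spill.
- The pipeline writes a manifest of SHA-256 hashes over all data products;
  identical config + seed reproduces identical hashes (the config echo
  itself, which contains the output path, is written but not hashed).

## Problem sizes

Defaults are sized for a laptop-class single CPU: the demo cohort is
6 subjects × 3 cell types ≈ 1.16×10⁵ points (full pipeline ≈ 2–4 min);
benchmark experiments use 2×10⁴–9×10⁴ points per scene (density recovery,
planted insert), 20 random fixtures of n ≤ 500 for the DBSCAN oracle,
n = 2000 × 10 seeds for the neighbor-count oracle, 200 replicates for the
null calibration and 50 for power, and five 8×512×512 stacks with 200
nuclei for detection. The reproducibility script completes in ≈ 3 min.

## Known limitations

- Ward on correlation dissimilarities is a heuristic (see above); trees are
  reproducible but heights lack a variance interpretation.
- Border-point assignment differs from implementations that attach borders
  to the first-reached core point; only border labels can differ, never
  core sets or cluster count.
- The detector assumes bright, roughly Gaussian nuclei on slowly varying
  background; it is the bootstrap stage of a detection workflow, not a
  replacement for learned detectors on hard tissue.
- The toy atlas is flat (no region hierarchy roll-up beyond an optional
  parent column) and makes no attempt at realistic anatomy.
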