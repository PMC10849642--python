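# Methods

## Coordinate conventions

Volumes are `(z, y, x)` arrays with 0-based indices; the physical
position of voxel `(i, j, k)` is its center, `((i+0.5)·dz, (j+0.5)·dy,
(k+0.5)·dx)` μm. Anisotropy is carried as metadata — nothing is ever
resampled — and every distance in the package is computed in μm.
Continuous centroids expressed in voxel units convert to μm by exact
multiplication with the voxel size.

## Vessel geometry

**Distance field.** The away-from-vessel coordinate is the exact
Euclidean distance transform of the complement of the vessel mask
(`scipy.ndimage.distance_transform_edt` with the voxel size as
sampling), zero everywhere on the mask. The 3-μm "surface band"
therefore includes vessel-interior voxels; this matches the standard
distance-transform reading of "within 3 μm of the surface" and makes the
band robust to lumen/wall segmentation differences. Distances beyond
the 100-μm export radius are flagged invalid rather than clipped.

**Centerline.** 3D thinning (Lee's algorithm via
`skimage.morphology.skeletonize`) followed by a double-sweep Dijkstra
over the 26-connected skeleton graph with physical edge lengths: the
shortest path between the two mutually farthest skeleton voxels
approximates the graph diameter and automatically drops side spurs.
Thinning can erode tubes of exactly even voxel width to nothing; in that
case the centerline is recovered as a shortest path over the full mask
graph with edge weights inversely scaled by the inside-distance
transform, which pins the path to the medial ridge, and the boundary
approach ramps at the two ends are pruned by their distance-gradient
signature (climb ≥ 0.5 μm per μm walked). The voxelized path is
smoothed with a moving average whose window scales with the local tube
radius (clamped to 3–11 nodes), extended at both ends along a
least-squares tangent until it exits the mask (thinning shortens tubes
by roughly one radius per end), resampled to uniform spacing equal to
the smallest voxel dimension, and oriented to start at the
lexicographically smallest endpoint so arc length is deterministic.
Masks are treated as flat-cut segments of longer vessels, which is how
traced segments end in practice.

**Arc positions.** Each query point maps to the cumulative arc length of
its nearest centerline node (k-d tree; exact ties go to the lower-index
node). With node spacing at one voxel or less, nearest-node assignment
is indistinguishable from continuous projection at voxel resolution.
Voxels whose arc position falls beyond the first/last bin edge (tube end
caps) fold into the terminal bins.

**Diameter.** At arc fractions ¼, ½, ¾ the local mask cross-section
perpendicular to the centerline tangent is measured as the voxel count
in a one-voxel-thick slab (capped at 3 local radii to exclude a curved
tube's far side) and converted to the equivalent circular diameter
2·√(A/π); the mean of the three sites is reported. An area-based
estimate is used instead of an inscribed-sphere estimate because the
discrete medial ridge of an even-width tube sits half a voxel off the
true axis, which biases inscribed-sphere radii low by up to a voxel.
A mask with no interior (1-voxel line) degenerates to one voxel of
diameter with a warning.

## Intensity normalization

Per sample, three anchor intensities — background, tissue
autofluorescence, and positive immunolabel — are each averaged from 3
z-depths × 10 readings (their means must be strictly increasing). A
continuous piecewise-linear map fixes each sample anchor to the
corresponding reference anchor; between anchors it interpolates
linearly, and beyond the outer anchors it continues the adjacent
segment's slope (clamping would destroy ordering among bright tangles).
Reference anchors default to the per-category mean over all samples in
the cohort; a designated reference sample can be configured instead.
Volumes are normalized in full before any vessel-local export, so all
downstream statistics live on one dataspace. Monotonicity of the map
means a global affine staining difference between two samples changes no
percentile ranking — the decile machinery is invariant to it, which the
tests assert.

## Objects

Tangles (tau channel) and neurons (HuD channel) are segmented as
26-connected components above a threshold, size-filtered, with centroids
in μm. This replaces interactively trained pixel/object classifiers;
externally produced object tables can be ingested directly instead. In
the pipeline, the threshold defaults to the autofluorescence anchor plus
0.6 × the autofluorescence-to-positive anchor span, applied in
normalized space — above any plausible halo, below the positive level.
A neuron is NFT-positive when some tangle's voxel overlap covers at
least half of that tangle's volume (each tangle matched to at most one
neuron: largest overlap, ties to the lower neuron id); the 0.5 overlap
fraction is this package's operational definition of colocalization and
is configurable. Layers are read from the label volume at the centroid
voxel; label 0 means unassigned and is reported separately, never
merged.

## Binning, deciles, profiles, densities

Bins are 10-μm arc intervals per vessel; the trailing partial bin is
kept and flagged. Surface tau per bin is the mean normalized intensity
over voxels with distance ≤ 3 μm, each contributing to exactly one bin.
Bins pool **within donor** for percentile ranking (midranks; ties share
the lower decile via the ceiling of midrank/n × 10); per-vessel and
global pooling are available by configuration, but per-donor pooling is
the default because normalization is also per-donor. Radial profiles
use 2-μm distance bands over (0, 100] μm (the interior, d = 0, is
excluded); a voxel near several vessels counts toward the nearest one
and inherits the decile of its along-vessel bin; intensities are
reported as percent change against the whole-image mean of the
normalized volume. Object densities count objects with distance
≤ 30 μm in their arc bin, divided by the bin's 30-μm neighborhood volume
in mm³. The %NFT table pools neuron counts per donor × decile; cells
with zero neurons are missing, never zero. The heatmap table is
log10(bin surface intensity / whole-image mean) with a 10⁻⁶ × mean
offset guarding empty bins.

## Association statistics

The donor × decile %NFT table is tested with a one-way within-subject
ANOVA: total SS partitions into subject, decile (effect) and residual
(error); F = MS_effect/MS_error on (k−1), (n−1)(k−1) degrees of freedom.
Missing cells are handled complete-case — donors lacking any decile are
dropped and logged; at least two complete donors are required. The
reported R² is SS_effect/(SS_effect+SS_error), i.e. **partial
eta-squared**; other definitions of "R²" exist and give different
numbers. Sphericity is not corrected by default; a Greenhouse–Geisser
epsilon-corrected p-value is available as a flag. Immunoassay lanes are
normalized antibody-wise to the control-group mean (so control values
average 1), and group differences use a one-tailed two-sample t-test,
pooled-variance by default with a Welch option.

## Synthetic phantom

The generator renders what the quantification must recover, with
complete ground truth:

- **Vessels**: polyline axes dilated to tubes, flat-cut at the segment
  ends. Default radius 8.5 ± 2 μm (clamped to 5.5–13), i.e. diameters
  around 17 μm — arteriole scale; cohort vessels run the volume's long
  axis with gentle wander.
- **Halo**: perivascular tau is `A·exp(−d/λ)` added on tau-positive arc
  intervals, with defaults A = 20 intensity units and λ = 10 μm; about
  half the cohort's vessels are tau-positive on one or two sub-intervals
  covering 20–45 % of their length each. The exponential form is the
  simplest monotone-decaying profile with a single recoverable length
  scale. The halo is truncated where it falls below 2 % of A (≈ 4 decay
  lengths) so distant tissue is exactly halo-free — below the default
  noise floor and necessary for well-defined anchor classes.
- **Levels**: background b = 10, autofluorescence a = 25, positive
  P = 120, interpreted as absolute class levels (background slab at b,
  tissue at a, NFT blobs/somata at P). Gaussian noise of sd σ = 4 is
  added last and clipped at zero. Anchor readings are sampled at true
  class locations (3 depths × 10 per category); with σ = 0 they are
  exact by construction. When a phantom contains no rendered positive
  structure, positive readings are synthesized as P plus noise.
- **Neurons and NFTs**: somata are a uniform spatial point process in
  tissue (default 3 × 10⁴ /mm³, adult human cortical gray-matter scale),
  excluded from vessel lumina. Each neuron within 30 μm of a vessel
  takes the true decile s of its bin (s = 0 otherwise) and is
  NFT-positive with probability logistic(β0 + β1·s), defaults β0 = −3,
  β1 = 0.35 — a strong gradient from ≈ 6.6 % at decile 1 to ≈ 62 % at
  decile 10. NFT blobs (r = 2.5 μm) render in the tau channel inside the
  soma (r = 4 μm), so overlap matching can recover the flags.
- **Layers**: parallel slabs along y, six by default, label 0 below the
  tissue margin.
- **Cohorts**: per-donor anchor levels are gain/offset-distorted
  (gain ~ U(0.7, 1.3), offset ~ U(0, 3)) with the halo scaled by the
  same gain — the affine-like staining difference the normalization must
  undo. All randomness flows from one seed.

A table-level simulator (`simulate_nft_decile_table`) draws donor ×
decile %NFT tables straight from the same generative model (lognormal
bin intensities → midrank deciles → Poisson neurons → Bernoulli NFTs)
without rendering volumes; it is used for the statistical calibration of
the ANOVA at full replicate counts (200 power replicates, 2000 null
replicates), where volume rendering would add nothing to the statistic
under test.

**What the phantom does not emulate**: optics (PSF, depth attenuation,
photobleaching), vessel branching, non-Gaussian noise, irregular soma
shapes, and spatially correlated staining variation. Passing recovery
tests therefore demonstrates correctness of the geometric and
statistical machinery under the stated generative model, not robustness
to every property of real cleared-tissue data.

## Problem sizes and numerical choices

Validation runs use compact volumes chosen to exercise every stage:
32–48 voxel z-extent phantoms for unit tests, a 48 × 160 × 160 μm
three-vessel phantom for halo recovery, and a 48 × 192 × 192 μm
three-donor, two-vessel demo cohort for the end-to-end pipeline. The
statistical calibration uses 6 donors × 20 vessels × 25 bins per
replicate. Tolerances follow the discretization: lengths and diameters
to one voxel diagonal or 5 %, the fitted halo decay length to 15 %, the
distance transform exactly. Degenerate inputs (empty masks, masks
without interior, vessels shorter than one bin, fewer rankable bins than
deciles, anchors out of order, fewer than two complete donors) raise
errors or warnings rather than producing silent numbers.

## Known limitations

- Branching vessels are out of scope; each mask must be one unbranched
  tube (branches would be absorbed or rejected by the longest-path
  rule).
- Nearest-node arc assignment quantizes at the node spacing (≤ 1 voxel).
- The repeated-measures ANOVA assumes sphericity unless the
  Greenhouse–Geisser flag is set, and complete-case dropping can be
  wasteful with many sparsely populated deciles.
- The threshold/connected-components object stage is a deliberately
  simple stand-in for learned classifiers; on real data, importing
  classifier-exported object tables is preferred.
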