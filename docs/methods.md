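# Methods

## Scope and model

`vascmorph` quantifies contrast-perfused vasculature in 3D microCT volumes
and correlated 2D histology. The measurement model is deliberately simple
and fully specified: vessels are bright tubular structures on a darker
tissue background; after global thresholding, every morphometric quantity
is a function of binary voxel masks and the isotropic voxel side length in
μm. Physical calibration travels with every object (`VoxelVolume`,
`BinaryMask`), so all outputs are in μm, μm² or μm³. Axis order is
`(z, y, x)` with z the stack axis; index boxes are 0-based half-open.

## Synthetic phantoms: what they emulate

No public volumes accompany this kind of study, so validation rests on
seeded generators whose ground truth is known exactly.

**Vessel trees.** Binary branching trees obey Murray's law exactly at every
bifurcation: child radii are `r_parent · f^(1/m)` and
`r_parent · (1−f)^(1/m)` for flow split `f` (default symmetric, `f = 0.5`)
and exponent `m` (default 3, the classical minimum-work value; the radius
law is a modelling choice, configurable). Segment length is
`8 × radius`, branch angle 37°, both in the physiological range for
arteriolar trees. Defaults (root radius 8 μm, depth 4) give terminal radii
of 3.17 μm — genuine capillary calibre (5–8 μm diameters), placing phantom
vessels both above and below the ~10 μm diameter visibility scale of
overview-resolution scans while keeping rasterized volumes around
200³ voxels at 1 μm. Tortuosity is a seeded two-harmonic sinusoidal
displacement of each segment's polyline, perpendicular to the chord, with
endpoints pinned so connectivity is exact; it reproduces the geometric
signature (arc/chord > 1) without any hemodynamics.

**Rasterization.** A voxel belongs to the truth mask iff its *center* lies
within the segment radius of the segment polyline (point-to-polyline
Euclidean distance). This is a capsule model; spherical end caps at
junctions largely cancel against parent/child overlap, and the truth-mask
volume empirically tracks the analytic Σπr²L to well under 1% for the
default trees (and converges as voxel size → 0, which is tested). The
grayscale volume is foreground/background intensity (200/50) plus seeded
Gaussian noise (σ = 10), emulating the homogeneous signal of a polymerized
contrast agent.

**Histology scenes.** Muscle fibers sit on a jittered hexagonal lattice
(pitch 50 μm, a typical murine fiber diameter). Each fiber receives a
Poisson-distributed number of boundary capillaries with mean given by a
spatial profile, so the expected capillary-to-fiber ratio at a position is
the profile value — allowing the deep-vs-superficial gradients seen in real
muscle. Capillary positions are clipped into the section, so counts are
conserved; the scenes have no fiber-type structure, no vessel shapes (points
only) and no annotation error, so passing tests demonstrate correctness of
the mapping arithmetic, not robustness to manual-annotation noise.

**Classification counts.** Per field of view, a Poisson total (mean 105,
matching ~1250 capillaries per animal under a 3 × 4 design) is split by a
multinomial draw over (double-positive, contrast-only, lectin-only). The
doubly-negative class does not exist by construction: an undetected
capillary is never counted. Real data add between-animal heterogeneity in
the true proportions; the generator models only sampling noise.

## Numerical and design choices

- **Thresholding.** Otsu on 256 bins over the observed range; the chosen
  threshold is logged and stored on the mask. A fixed threshold is
  available for auditability. Constant volumes are an error, not a guess.
- **Connectivity.** 26-connected in 3D, 8-connected in 2D, everywhere.
- **Despeckle.** Components smaller than 8 voxels are removed by default —
  below two voxels across per axis is unresolvable structure at
  capillary-resolving voxel sizes.
- **Equidistant sections.** `i_k = round((k + 0.5)·L/n)` with exact halves
  rounded down (so `n = L` selects every slice); collisions shift forward
  by one.
- **Diameters.** Equivalent-circle diameter from profile area on transverse
  sections. Border-touching profiles are censored from size statistics by
  default (truncation biases diameters down) but retained in volume
  fractions. Oblique intersections bias diameters upward (elliptical
  profiles); this is inherent to any section-based estimator and is
  asserted, not corrected. The median is pooled over profiles (each profile
  counted once), making it invariant to the binning. Default bin width
  5 μm. A 3D local-thickness estimator was considered and deliberately left
  out of v1: the section protocol is the primary contract.
- **Shrinkage.** Both `retained = 100·later/earlier` and
  `shrinkage = 100 − retained` are always reported, because the two
  conventions are mixed in the literature and a bare "63%" is ambiguous.
  The cumulative isotropic linear scale factor (cube root of retained
  volume fraction) feeds the coregistration scale candidates.
- **Density maps.** Half-open kernel assignment (no double counting);
  boundary kernels normalize by clipped in-bounds area; sliding
  (default stride = kernel/2) and tiled modes; undefined 0/0 cells carry an
  explicit flag rendered grey, never a numeric sentinel. Kernel size and
  stride are recorded in every output's metadata since results depend on
  them.
- **Systematic random sampling.** Period `T = N/n`, start `u ~ U[0, T)`,
  picks `floor(u + k·T)`; inclusion probability is exactly `n/N` for every
  candidate, which the tests verify by Monte Carlo.
- **Perfusion summaries.** Pooled fractions sum counts before dividing
  (grouping-invariant); per-animal dispersion is the sample SD (n−1) across
  animal-level fractions, matching between-animal reporting over small n.
  Reports round category percentages to integers and marginals to one
  decimal but always retain full precision.
- **Coregistration.** Zero-mean NCC on binarized images over an exhaustive
  (z, rotation, scale) grid — determinism over speed at these search-space
  sizes. Both images are Gaussian-smoothed (σ = 1 px) after binarization so
  that thin binary vessel profiles degrade gracefully under sub-pixel
  resampling instead of collapsing; the same filter on both sides keeps the
  self-match score at exactly 1. Scores are computed on the central square
  inscribed for any rotation angle, so rotation fill never contributes.
  Ties break to smallest z, then smallest |rotation|. The query must be
  binarizable into vessel/non-vessel by the caller (fluorescence and X-ray
  intensities are unrelated; only geometry is shared). The "unmatched"
  score threshold (~0.3 in the tests) is a configuration default, not a
  derived constant.

## Problem sizes

Tests and the acceptance script run phantoms of roughly 200³ voxels
(depth-4 trees at 1 μm), 12-cylinder diameter phantoms, 100-scene
density-map sweeps, 500 stereological replicates and 2000 sampling seeds.
These sizes give the Monte-Carlo checks comfortable statistical resolution
(3 SE bands) while each suite completes in seconds.

## Known limitations

- Tree topology only (no anastomoses or capillary loops), no flow modeling,
  no reconstruction artifacts (beam hardening, rings) in phantoms.
- Global thresholding assumes bimodal intensity; it will not handle
  contrast gradients or bone without prior ROI exclusion.
- Diameter estimates inherit section-based biases (obliquity upward,
  border censoring downward); accuracy is demonstrated by phantom recovery,
  not by equivalence to any proprietary measurement chain.
- The registration is rigid in-plane plus isotropic scale; tilted or
  deformed sections are out of scope.
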