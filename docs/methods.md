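# Methods

This note documents the models, conventions and design choices behind
`chromopos`, in the spirit of a methods appendix: what each stage
assumes, which parameters matter, what the synthetic generators do and
do not emulate, and where genuinely open choices were resolved.

## Gene map and coordinates

The measurement universe is the set of probesets on one microarray
design, each mapped to a gene symbol and a genomic interval. Annotation
TSVs are declared 1-based fully-closed (UCSC browser convention, matching
how locus coordinates are usually printed); internally all intervals are
0-based half-open, converted once on read. Rows must satisfy
`start < end` on the raw coordinates — zero-length rows are rejected
rather than silently reinterpreted (1-bp target regions do not occur for
probesets).

For window membership a gene is anchored at a single point, its lower
(start) coordinate, regardless of strand. A single-point anchor
prevents long genes from being counted in two disjoint windows and makes
window counts additive over a tiling partition (a tested invariant).
Strand is carried but ignored by every positional computation; no step
in the pipeline is strand-dependent. Chromosome labels accept
`chr13`/`13` synonyms and are stored bare; the allowed set is 1–22, X,
Y. Because the published chip had genes on all 24, the enrichment χ²
has df = 23 when run on full-chip data.

Genomic separations are reported in Mb as `|b − a| / 10⁶` with an
integer form truncated toward zero, the convention under which the two
chromosome-13 cluster starts (75,092,571 and 96,672,575) are "21 Mb
apart".

## Differential expression: rank products and dual-normalization intersection

With one mutant and one control sample per tissue there are no
replicates, so moderated test statistics are unavailable and naive
fold-change thresholds are noisy. The pipeline instead:

1. computes signed fold changes (mutant/control as a ratio when ≥ 1,
   minus the reciprocal otherwise, so a halving is −2.0);
2. ranks probesets by the rank-products statistic — the geometric mean
   of a probeset's ranks across comparisons, rank 1 being the most
   extreme in the stated direction. With a single comparison this
   degenerates, by construction, to a plain fold-change sort; the
   implementation makes that explicit and tests it against a sort
   oracle. Rank-product significance machinery (permutation E-values)
   is deliberately not implemented: the statistic is used only to rank
   fixed-size lists.
3. intersects the top-K over-expressed and top-K under-expressed lists
   obtained under two independent normalization variants of the same
   arrays (the published analysis used RMA and MAS5 background
   corrections; this package consumes any two already-normalized tables
   and takes no position on CEL-level processing);
4. collapses probeset calls to unique gene symbols. A gene whose member
   probesets disagree in direction is `discordant` (the published
   shared-gene table contains such a case, DCN at −2.4/+2.5), and
   direction counts partition the unique-gene count.

All ties — within-comparison ranks, final RP order, top-K cutoffs — are
broken lexicographically by probeset id. The choice is arbitrary but
deterministic, which regression tests require.

## Sliding-window genomic clusters

Parameters (`ScanConfig`): window 500,000 bp, slide 100,000 bp, minimum
misexpressed-gene density 75% of local chip-gene density, and more than
one misexpressed gene per window. The window grid starts at coordinate 0
of each chromosome and the final partial window is scanned; grid origin
is otherwise unspecified in the source protocol, and a fixed grid gives
determinism (cluster counts are verified to be stable to ±1 under
translation of the whole map by one slide). Density is computed over
deduplicated *genes*, not probesets, since cluster membership is
reported in genes. Overlapping or abutting qualifying windows on one
chromosome merge into maximal clusters; the merged interpretation is
flagged here because region-level reporting ("ten regions") does not
state whether windows were merged.

The empirical null draws `list_size` probesets uniformly without
replacement from the chip, collapses them to genes (randomization at
probeset level, mirroring the published "lists of 675 probesets" — note
the published DE set had 674 probesets; because of that discrepancy
`list_size` is an explicit required argument with no default), scans and
merges identically, and records the cluster count. The p-value for an
observed count is the plus-one upper tail `(b+1)/(N+1)` where `b` counts
simulations with count ≥ observed; with b = 0 over 1000 simulations the
report renders the conventional bound "<0.001". The plus-one form can
never return 0 and is provably super-uniform under the null — the
acceptance suite measures the type-I error at α = 0.05 over 500
repetitions and finds it well below nominal.

The scan is exact, not approximate: a per-(universe, config) index of
sorted gene anchors reduces each window to two `searchsorted` bounds,
and each null simulation to two cumulative-sum lookups, so 1000
simulations over a chip-sized map cost seconds. Tests compare the
indexed scan against an independent brute-force implementation.

## Per-chromosome enrichment

Expected counts come from the chip's composition, not from genome-wide
gene counts: if a fraction f of all chip genes is misexpressed, each
chromosome c is expected to contribute f·n_chip(c). The test is a plain
χ² goodness-of-fit (scipy's implementation) with df = categories − 1, no
continuity correction and no multiple-testing adjustment, matching the
single published test. Chromosomes without chip genes are excluded from
the categories (and logged). Gene-level counting is the default;
probeset-level counting is exposed because the published text does not
say which was used. Percentages are kept as raw floats everywhere and
rounded only in the report layer.

Shared-gene analysis intersects two tissues' gene-level call sets by
symbol and quotes per-chromosome shared counts against the chip's gene
content of that chromosome (3 shared genes of 340 chip genes on
chromosome 13 → 0.9%).

## 3D image quantification

**Calibration.** Stacks are `(z, y, x)` arrays with anisotropic voxels;
the default is 0.08 µm in x-y and 0.12 µm in z (the stated optical
section spacing). Every distance honors per-axis spacing; conflating the
0.12 µm z-step with sub-pixel x-y sampling would bias all 3D distances.

**Despeckle.** The 3×3 hybrid median filter replaces each pixel with the
median of {median of the "+" neighborhood, median of the "×"
neighborhood, center}. It is implemented directly (vectorized shifts,
reflected borders) and tested against a per-pixel brute-force oracle.

**Segmentation.** Global threshold (Otsu default; fixed, percentile and
half-max available), per-slice 2D hole filling ("filled, no holes"
masks), and largest-component selection for nucleus masks. Two special
cases matter: the lamin shell is segmented *without* hole filling (a
filled annulus is a disk, which would make every interior voxel
"contact" the lamina), and FISH spots use the half-max threshold with
largest-component selection, because a global histogram split is
unstable when the foreground is a few dozen voxels out of millions.

**Territory-to-edge distance (two-plane protocol).** For each x-y slice,
the Euclidean distance map of the nucleus mask is computed with (dx, dy)
spacing and its minimum under the territory mask recorded; the stack is
then resliced perpendicular to x-y and the procedure repeated on x-z
slices with (dx, dz) spacing; the smaller of the two minima is the
territory's shortest distance to the nuclear edge. The *edge* is the
mask's boundary voxel layer: the mask is eroded by one voxel before the
distance transform, so a boundary voxel is itself at distance 0. This
convention is what makes a territory tangent to (or crossing) the rim
score exactly 0 µm, as reported for the Δ303 and D596N territories; the
raw foreground-to-background EDM would instead floor at one voxel
(~0.1 µm). The stand-alone `edm_slice` helper keeps the literal EDM
definition (foreground → distance to nearest background pixel,
background → 0) and is tested for exact equality with an O(n²)
nearest-background search.

The two-plane minimum is faithful to the slice-based protocol rather
than replaced by a true 3D transform; it can only overestimate the true
3D distance (each in-plane distance ≥ the 3D distance), with equality
when the nearest boundary lies in an x-y or x-z plane through the
territory. A 3D mode (anisotropic distance transform, same boundary
convention) is provided as a cross-check and is verified to equal a
brute-force 3D oracle and to lower-bound the two-plane result.

**Other measurements.** Inter-locus distances are plain 3D Euclidean
distances between intensity-weighted signal centroids (the deterministic
analogue of ROI-manager coordinates). Lamina contact is 1 iff any signal
voxel coincides with or is 26-adjacent to a lamin voxel — "physical
continuity" read as the most permissive standard voxel connectivity.
Volumes are voxel counts × dx·dy·dz from the filled masks (no surface
fitting), and territory volumes are normalized to the nuclear volume.
The published territory "volumes" of order 0.017 ± 0.001 µm³ are almost
certainly these dimensionless ratios rather than absolute volumes; both
quantities are emitted and the ambiguity left documented rather than
resolved. Ki-67 indices classify a culture as senescent below 0.02 and
young above 0.40, with both exact boundaries mapped to `intermediate`.

## Statistics

Group comparisons are two-sided t-tests; Welch (unequal variances) is
the default, with a pooled-variance variant exposed, since "Student's
t-test" alone does not pin the choice down. Tests from summary triples
use t = (m₁−m₂)/√(sem₁²+sem₂²) with Welch–Satterthwaite df. Binary
contact scores are compared by the same t-test applied to the 0/1
values, and that route is verified to agree exactly with the
summary-statistic route applied to the lists' own mean/SEM/n.

The published ± values are stated in their source to be standard
deviations, yet they reproduce the published p-values only when read as
standard errors (e.g. 1.778±0.0957 n=56 vs 1.401±0.0750 n=94 → p =
0.0024 ≈ the published 0.002; 0.794±0.162 n=34 vs 0.524±0.203 n=21 → p
= 0.30 exactly as published). The package therefore interprets ± as SEM
by default and documents, without claiming to resolve, the
inconsistency. The published p = 0.0001 for cluster-13A contact cannot
be reconstructed from the per-nucleus counts alone (the per-signal n is
ambiguous) and is not asserted anywhere. Degenerate zero-variance
inputs follow fixed conventions: equal means → p = 1, unequal means →
p = 0 with a `degenerate` flag.

## Synthetic data: what it emulates and what it does not

**Expression.** Each probeset has a latent log2 control intensity
~ N(8, 1.5). Planted probesets carry a signed log2 effect (default 2.0,
i.e. 4-fold — comfortably inside the published fold-change range);
multiplicative log-normal noise (default sd 0.25 in log2) is split into
a shared and an independent component so that the two normalization
variants' fold changes correlate at a chosen ρ (default 0.9). This is
the minimal generative structure the dual-normalization intersection
assumes: two noisy views of one underlying contrast. Planted genomic
clusters are runs of genomically consecutive genes accepted only at
*recoverable* positions — some scan-grid window must contain the whole
run at qualifying density, and runs keep > one window length of
clearance from each other — so that in the noiseless limit every
planted cluster is detected exactly and none merge; per-chromosome
enrichment is planted as an excess DE fraction on chosen chromosomes.
Gene maps use uniform gene starts with exponential lengths (mean 20 kb)
and ~15% of genes carrying a second probeset. Not emulated: probe-level
effects, intensity-dependent variance, batch structure, correlated
co-expression.

**Nuclei.** A nucleus is an axis-aligned ellipsoid (DAPI = filled
interior; lamin = thin boundary shell, default 0.2 µm); territories are
solid spheres, FISH spots 0.25 µm spheres, each in its own channel.
Channels are blurred with an isotropic Gaussian PSF (default σ =
0.08 µm) and corrupted with Poisson-Gaussian noise scaled so a
unit-intensity voxel has the stated SNR (default 20, a clean confocal
regime). Ground truth is analytic: minimum edge distances via exact
point-to-ellipsoid-surface distances (closed form for spheres,
multi-start smooth minimization otherwise, itself tested against dense
surface sampling), pair distances in closed form, volume ratios from
sphere/ellipsoid volumes. The random-nucleus generator places territory
offsets in the equatorial (z = 0) plane so the two-plane protocol's x-y
pass attains the true 3D minimum; this is a property of the *validation
geometry*, not of the measurement code, which handles arbitrary
positions. Not emulated: chromatin texture, photobleaching, depth-
dependent aberrations, microscope-specific optics, touching nuclei
(one nucleus per crop is assumed throughout).

Passing the recovery tests therefore shows the measurement chain is
unbiased to within voxelization error on well-calibrated, well-separated
structures; it does not certify performance on dim, crowded or
aberrated real acquisitions.

## Problem sizes and determinism

The test and acceptance workloads are scaled for a single CPU: planted
cluster recovery over 8 seeded maps (~700 genes each), null calibration
over 500 repetitions of a 199-simulation null on a ~200-gene map,
distance-map oracle agreement on 100 random 12×12 masks, and geometry
recovery on 50 synthetic nuclei at 0.1/0.1/0.12 µm voxels (radius 3–4.5
µm). Every random draw in the package flows through one seeded
`numpy.random.Generator` per call; identical seeds give bit-identical
outputs, which the suite asserts.

## Known limitations

- Rank products are implemented as a ranking statistic only; no
  permutation-based E-values or FDR control anywhere (by design,
  mirroring the reimplemented workflow).
- The scan supports exactly the published window rule; no scan
  statistics, HMMs or gap-based alternatives.
- The two-plane edge distance inherits the protocol's anisotropy: it
  never examines y-z planes, so a nearest boundary approached purely
  along y at an off-plane z is overestimated (bounded by the tested
  two-plane ≥ 3D inequality).
- No genome-assembly liftover: coordinates are treated as an opaque,
  internally consistent system.
- No deconvolution; inputs are assumed deconvolved or synthetic.
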