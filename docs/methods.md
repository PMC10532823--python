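# Methods

## Coordinate model

All coordinates are millimetres in RAS orientation (+x right, +y anterior,
+z superior). Talairach-space foci are converted to MNI by homogeneous
multiplication with an explicit 4×4 affine; the default is the Lancaster
et al. (2007) `tal2icbm_spm` matrix, stored verbatim in
`parcale.coords.TAL2MNI_DEFAULT`. Published meta-analyses often used web
conversion tools whose exact mapping is unstated, so the affine is a
configurable parameter rather than a constant: any user-supplied matrix
(including the identity) is accepted, and the inverse conversion is the exact
matrix inverse. Coordinate plausibility bounds (|x| ≤ 100, |y| ≤ 120,
|z| ≤ 100 mm) and the minimum-sample-size inclusion rule (N ≥ 8) are
reported as warnings by default and promoted to errors with `strict=True`.

Two foci-table dialects are read and written: Sleuth-style text (header
lines beginning `//`, a required `Subjects=` field, a `Reference=` space tag,
blank lines between experiments) and a plain TSV with columns
`study_id, n_subjects, space, x, y, z`. Writing uses `repr` floats and
reading uses round-trip float parsing, so write-then-read is exact.

## Kernel and ALE statistic

A focus from a study of N subjects is modeled as an isotropic Gaussian with

σ²_total = σ²_template + σ²_subject / N.

The defaults derive from the empirical uncertainty estimates of the ALE
literature: mean Euclidean displacements of 5.7 mm (between templates) and
11.6 mm (between subjects), converted to FWHM by √(8 ln 2)/(2√(2/π)) ≈ 1.476,
giving 8.41 and 17.12 mm. A 15-subject study gets a ≈ 9.5 mm kernel; the
width is strictly decreasing in N and tends to the template term alone.
Both components are plain FWHM parameters and can be overridden.

The kernel is discretized separably: each axis factor is normalized to unit
sum over the full axis, so the 3-D kernel sums to exactly 1 over the full
(unmasked) lattice; per-axis tails below 1e−12 of the axis maximum are
dropped (total discarded mass < 1e−9), which keeps permutation work fast
without affecting the 1e−6 normalization guarantee. Only axis-aligned
(diagonal) grid affines are supported — this covers every standard
MNI-aligned lattice and keeps the separable discretization exact.

Per experiment, the modeled-activation (MA) map takes the voxel-wise
*maximum* over focus kernels (non-additive: several nearby peaks from one
experiment cannot mimic convergence). The ALE map is the probabilistic union
1 − ∏(1 − MAᵢ), accumulated in log space over experiments sorted by id, so
the result is bit-identical under any input ordering. Foci farther than
3·FWHM outside the grid bounding box are skipped with a warning.

## Null model and thresholds

The null hypothesis is no spatial association between foci. Each permutation
relocates every experiment's foci to independent uniform draws from in-mask
voxel centers, preserving focus counts and kernel widths, and recomputes the
ALE map. Two tables result:

- the pooled distribution of null ALE values over all in-mask voxels and
  iterations, used for voxel-wise p with the (r+1)/(n+1) correction (p never
  reaches zero at finite permutation counts);
- the per-iteration maximum cluster extent after voxel thresholding at the
  pooled-null critical ALE value, used for cluster-level FWE: survivors must
  exceed the empirical (1 − α) quantile (the `higher` order statistic) of
  that max-extent null.

The per-iteration maximum ALE value is also recorded (`max_ale_null`): it is
the correct reference for calibrating an observed map *maximum*, since the
maximum over thousands of correlated voxels essentially always exceeds any
marginal pooled-null percentile.

Defaults: voxel p < 0.001 uncorrected, cluster α = 0.05, 1000 permutations,
26-neighborhood cluster connectivity (6 and 18 available). Cluster extent
(voxel count) is the cluster-level statistic. Because pooled-null
percentiles differ slightly across voxels (mask-edge voxels see fewer nearby
null foci), voxel-wise calibration is exact on average over the mask rather
than voxel by voxel — the standard behavior of pooled-histogram ALE nulls.

Cluster ids are assigned in raster-scan order and reported sorted by extent
descending (ties by id); peak ties within a flat cluster break to the lowest
linear voxel index. Both rules exist only to make outputs deterministic.

## Dominant-experiment contribution

For a cluster C, experiment i's leave-one-out contribution is

( Σ_{v∈C} ALE(v) − Σ_{v∈C} ALE_without_i(v) ) / Σ_{v∈C} ALE(v),

computed from the stored MA maps in log space. The maximum over experiments
measures how much a single study drives the pooled result; at the minimum
admissible study count (8 experiments) a sound meta-analysis keeps it at or
below 50%. `scripts/acceptance.py` recomputes this bound on simulated
eight-experiment study sets; replicates whose thresholded map has no
FWE-surviving cluster are excluded, because the statistic is defined on the
largest *surviving* cluster.

## Parcellation overlap and contrast

Atlases are integer NIfTI label volumes plus a TSV table
(`label_id, parcel_name, hemisphere, network`). Hemisphere is an explicit
tag (parcels are reported as `L_…`/`R_…`), never inferred from the x sign, so
midline parcels behave deterministically. Grids that differ from the
analysis grid are resampled by nearest neighbor, which cannot invent labels.
Overlap reports both the share of the cluster inside each parcel and the
share of the parcel covered, since either convention appears in published
tables; per cluster the shares (plus the unlabeled remainder) sum to 100%.
Parcels covering at least one voxel are reported; those covering ≥ 10% of a
cluster are flagged *principal*.

The contrast stage is symbolic set algebra on hemisphere-tagged parcel sets
(not a voxel-wise subtraction analysis): per pair, shared and unique parcels;
globally, parcels engaged by ≥ 2 sub-analyses are *core* and parcels engaged
by exactly one are *accessory*. Network co-activation is derived solely from
parcel→network membership, so two tasks with disjoint parcels can still
co-activate a network; a shared parcel always implies co-activation of its
network. Network "uniqueness" is uniqueness among the contrasted tasks only.

## Similarity search

The experiment-database search is a local emulation of coordinate-similarity
services, with a documented, deliberately simple metric: a query focus
matches a record if it lies within the match radius (default 10 mm) of at
least one record focus, in the query→record direction only;
similarity = matched fraction of query foci, top-k (default 10) returned
with ties broken by experiment id. It is monotone in the radius.

## Synthetic data

`simulate_studyset` emulates a meta-analytic corpus: each experiment draws N
uniformly from [8, 30] (honoring the N ≥ 8 inclusion convention), reports
each planted true center with probability 0.9 displaced by isotropic Gaussian
jitter (SD 6 mm — millimetre-scale between-study variability), and adds
Poisson(4) noise foci uniform over the mask. An experiment that would end up
empty receives one fallback noise focus. Everything is a pure function of
(config, seed). The default analysis grid is a 4 mm MNI-aligned lattice with
an ellipsoidal brain-envelope mask (semi-axes 70/85/75 mm centered at
(0, −18, 10) mm); real analyses should supply their own gray-matter mask.

What the generator does *not* emulate: gray-matter-weighted noise (noise is
uniform over the mask), anatomically realistic parcel geometry (the toy
atlas cuts each hemisphere into equal-count posterior→anterior slabs with
cyclic network assignment), between-study heterogeneity in reporting
thresholds, and spatially correlated multi-peak activation patterns. Passing
tests therefore demonstrate the statistical machinery — calibration of the
null, recovery of planted convergence, boundedness of single-study
dominance — not anatomical validity on real corpora.

## Problem sizes and test design

Simulation-based checks run on the 4 mm grid with 100 permutations and 20
seeded replicates (the full suite takes ~2 minutes); unit and oracle tests
use 5³–12³ lattices or the 8 mm grid. Production runs use the 2 mm grid and
1000 permutations — the code path is identical, only `voxel_size` and
`n_permutations` change. Independent oracles in the tests (breadth-first
flood fill for components, exhaustive voxel tallies for overlap, all-pairs
distances for similarity, leave-one-out union recomputation for
contributions) never share code with the implementation they check.

## Known limitations

- Fixed-effects pooling only; no meta-regression and no statistical
  subtraction analysis between study sets (the contrast stage is symbolic).
- The permutation null draws foci uniformly within the mask; anatomically
  weighted nulls are not implemented (the `histogram` null method is declared
  but not implemented).
- Only diagonal grid affines are supported (no oblique lattices).
- Manifest stage runtimes vary between runs; all analytic outputs are
  byte-identical given the same config, and the manifest records their
  checksums.
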