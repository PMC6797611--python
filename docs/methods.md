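# Methods

## Overview

The package summarizes per-subject volumetric brain maps over an atlas
parcellation and visualizes the resulting region × subject matrix for a
whole cohort. The approach assumes (a) each subject's scalar map and
label volume are already on one grid (the atlas having been warped to
the subject with nearest-neighbor interpolation by an external
registration tool), and (b) a scalar summary per area is an adequate
description of the signal within that area. No resampling, registration
or GLM fitting is performed here; the package deliberately consumes
already-computed maps so that the functional data itself is never
smoothed or warped.

## Region extraction

For area *i* of subject *j*, `S[i, j]` is a summary statistic of the
map voxels where the subject's label volume equals the area's label.
The default is the mean; min, max, sample standard deviation
(ddof = 1; defined as 0 for a single-voxel area) and median are
selectable. Two conventions needed fixing:

- **Zero-voxel areas** (a warped atlas can lose small regions) become
  NaN — an explicit missing value that propagates to a hatched grey
  cell in the figure and blocks clustering, never a silent zero.
- **Non-finite map voxels** inside an area are excluded from the
  statistic, with a warning carrying the count. An area whose voxels
  are all non-finite is treated as missing.

Session-level matrices are averaged element-wise with
`average_sessions` (missing entries ignored; a result entry is missing
only when missing in every session), matching a per-session-metrics →
subject-average order of operations.

## Column layout

Columns are grouped by gross anatomical region, groups in order of
first appearance in the atlas description (curated anatomical orderings
would be destroyed by an alphabetical sort). The left half holds all
L areas; the right half holds the paired R areas with group order and
within-group order reversed, so that stripping hemisphere, the right
half read backwards reproduces the left half — the innermost columns of
the two halves show the same area. Hemisphere strings are upper-cased
before validation and must be exactly L or R; the layout algorithm is
strictly two-sided. Areas without a contralateral partner (asymmetric
atlases) are kept, placed at the outer edge of their half, and
reported with a warning; dropping data silently would be worse. This
outer-edge placement is this package's convention for asymmetric
atlases, chosen because no established convention exists.

## Eigenvector centrality

The similarity between two voxels is A_uv = (r_uv + 1)/2 with r the
Pearson correlation of their time series. The additive shift (rather
than |r| or max(r, 0)) makes A non-negative so the dominant eigenvector
is unique and non-negative by Perron–Frobenius, and it admits a
matrix-free product: for Z the matrix of mean-centered, unit-norm
voxel series, A·x = (Z(Zᵀx) + Σx·1)/2, evaluated in O(n·T) per power
iteration step. Iteration starts from the uniform positive vector and
terminates when the eigenvalue estimate changes by < 1e-10 relatively
*and* the vector changes by < 1e-12 in max-norm — the second condition
makes the result independent (≤ 1e-8) of any random starting vector.
The output has unit Euclidean norm over the mask; any monotone
rescaling would be display-equivalent, so no mean-1 normalization is
applied. Masked voxels with zero temporal variance are a hard error
(their correlation is undefined), with offending indices listed.

## Regional homogeneity

Per voxel, Kendall's coefficient of concordance over the K in-mask
series of its neighborhood (the voxel plus face / face+edge /
face+edge+corner neighbors for K = 7, 19, 27; default 27, the most
common convention). Each series is ranked over time with mid-ranks;
with R_t the rank sum at time t and T_j the tie correction
Σ(c³ − c) of series j,

    W = 12 Σ_t (R_t − R̄)² / (K²(T³ − T) − K ΣT_j).

Neighborhoods are clipped at mask and volume borders (the actual K is
used). W ∈ [0, 1], with 1 iff all series are rank-identical; tiny
floating-point overshoots are clipped at 1.

## Temporal high-pass and smoothing

The high-pass removes frequency content below 1/cutoff by projecting
each voxel's series onto an orthonormal DCT-II low-frequency basis of
floor(2·T·TR/cutoff) + 1 components (including the constant, so the
voxel mean is removed) and returning the residual. This is
deterministic and testable in closed form against explicit basis
regression. The cutoff must exceed twice the TR, and the basis must
not span the whole series.

Smoothing is separable Gaussian convolution with σ = FWHM/√(8 ln 2)
per axis converted to voxel units, zero-padded outside the volume with
no mask renormalization (the simplest boundary contract, stated so
comparisons are made at a fixed rule); FWHM 0 is the identity. The
kernel is truncated at 4 σ.

## Subject clustering

Affinity propagation with similarity s(j, k) = −‖x_j − x_k‖² between
subject columns. The shared preference defaults to the median
off-diagonal similarity (moderate cluster counts without an a-priori
K); damping 0.9, up to 1000 iterations, and convergence declared after
the exemplar set is stable for 50 consecutive iterations — stability
over speed. Message passing is implemented directly (vectorized
responsibility/availability updates with deterministic lowest-index tie
breaking) so a non-converged run still returns a usable partition with
`converged=False` and a warning; a well-known reference implementation
is used as an independent cross-check in the tests, not as the
implementation. Two degenerate paths are explicit: all-identical
subjects (zero distances everywhere) collapse to a single cluster, and
an empty exemplar set falls back to the single best candidate.

Clustering input is continuous by default. A binarization threshold is
exposed (`binarize_matrix`, entry = 1 where value > threshold) for the
binary-matrix variant of the workflow, but since no principled default
threshold exists, binarization is opt-in. Missing entries block
clustering rather than being imputed silently. Cluster display order is
descending size with ties broken by exemplar index, so figures are
deterministic. Cluster rows in the figure get height 1 + log₁₀(size)
(base 10 with a +1 offset so singleton clusters remain visible; the
height rule only needs to be monotone).

## Native- vs template-space comparison

D = S_native − S_template per region and subject (sign convention:
native minus template). Each region's differences are tested with a
two-sided one-sample t-test, t = d̄/(s_d/√n), p from Student's t with
n − 1 degrees of freedom, where n counts the region's non-missing
subjects. Two-sided because differences of either sign are
scientifically meaningful here. No multiple-testing correction is
applied by default — the comparison is deliberately reported at an
uncorrected threshold — with Bonferroni and Benjamini–Hochberg
available behind a flag. Zero-variance regions: all-zero differences
get t = 0, p = 1; constant nonzero differences are flagged degenerate
(p = 0, warning) rather than hidden.

## Rendering

One global color normalization across the displayed matrix (symmetric
about zero when the data spans both signs), so values are comparable
across subjects within a column; per-region normalization would break
that reading and is not offered. The default palette is a diverging
blue–white–orange map (negative blue, positive orange). SVG output is
the contract surface: a fixed hash salt and stripped date metadata make
repeated renders byte-identical. The internal grid geometry (column
count, row units, separator positions) is validated before the file is
written.

## Synthetic fixtures

The generators emulate the pipeline's inputs with known ground truth:
block-structured mirror-symmetric label volumes (hemispheres split
along x, gross regions along y, areas along z, ≥ 8 voxels per area),
subject maps with planted per-cluster region means plus i.i.d. Gaussian
voxel noise, and 4D time series with planted connectivity hubs (a hub
voxel's latent signal mixed into its face neighbors at a chosen
correlation). Defaults for the demo dataset: 10 subjects, 2 planted
subgroups, per-cluster region means drawn with SD 2.0 against voxel
noise SD 0.5 — a clearly separated regime appropriate for a
demonstration of subgroup recovery. All generators are pure functions
of their spec including the seed.

What the phantoms do *not* simulate — spatial autocorrelation,
hemodynamics, physiological noise, motion, registration error — bounds
what passing tests show: they verify the algorithms and contracts, not
robustness to realistic fMRI noise structure. In particular,
template-space processing is emulated by smoothing the native maps,
which captures the smoothing component of the native-vs-template
comparison but not warping-induced distortion.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances chosen to exercise every code path at full fidelity:
16³/10³ phantoms with 8–32 areas, 50-voxel centrality instances
against dense eigendecomposition, cohorts of 5–16 subjects, a
2000-replicate × 50-region null simulation for t-test calibration, and
a 10-subject end-to-end demo. These sizes make the oracle comparisons
exact and the whole suite fast; the algorithms themselves are
independent of scale (the matrix-free centrality in particular is
O(n·T) per iteration and handles full-brain masks).

## Known limitations

- The exact similarity variant and normalization used by other ECM
  tools differ between implementations; numerical identity with maps
  from such tools is not promised (the invariants — non-negativity,
  unit norm, affine invariance — are).
- Affinity propagation's cluster count depends on the preference; the
  median heuristic is a default, not an inference.
- Accuracy is bounded by the warped atlas: systematic registration
  shifts masquerade as functional differences, and small areas are
  affected most. Validate label volumes (`validate_label_volume`)
  before trusting the output.
- Cluster membership has no causal interpretation; subgroups may
  reflect vascular or acquisition differences rather than functional
  organization.
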