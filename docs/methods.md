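# Methods

## The analysis model

The package treats fate segregation as a deterministic labelling problem on
an annotated expression matrix. Cells carrying the focal gene (strictly
positive log-CPM expression) are the population of interest; two curated
gene signatures — here smooth-muscle (SMC) and mesothelium (MC), 15 genes
each — define candidate fates. Three views of the same population are
computed: continuous enrichment (rank-AUC scores), pairwise association
(per-stage Pearson correlation of each signature gene with the focal gene),
and discrete class membership (≥ k signature genes expressed). The discrete
view is the primary readout because it yields per-cell classes whose counts
can be intersected and tracked across stages; the continuous and
correlation views contextualise it.

Assumptions: expression is log-normalized CPM and non-negative; annotations
(stage, tissue, sample) cover every cell; the two signatures are disjoint
(heavy overlap triggers a warning since it confounds the class partition);
and positivity is meaningful at the "> 0" boundary, which holds for
log-normalized counts where 0 encodes "not detected".

## Signature scoring

Genes are ranked per cell by decreasing expression; ties are broken by a
seeded uniform shuffle so the ranking is a true permutation and runs are
reproducible (the tie seed is recorded in the run manifest). The score of a
signature with in-matrix ranks r₁ < … < r_k, integrated to
R = ⌊top_fraction · n_genes⌋, is

    AUC = Σ_{rᵢ ≤ R} (R − rᵢ + 1)  /  (kR − k(k−1)/2),

the rectangle area under the step recovery curve normalized to the
front-loaded optimum. `top_fraction` defaults to 0.05, the published
default of the rank-AUC method. The implementation uses the closed form
above; the test suite checks it exhaustively against a literal cumulative-
count integration over every 3-gene placement in 10 ranks.

Score thresholds are suggested per signature from three families — the
99th percentile of a global normal fit, the density inflection between the
outer modes of a kernel-density fit, and the posterior boundary of a
2-component Gaussian mixture — and `auto` mode selects the mixture
boundary. Any manually chosen threshold must be given explicitly and is
logged; there is no hidden default, because that choice is a judgement call
in practice.

## Correlation dynamics

Correlations are computed among focal-positive cells only, per stage, which
is the regime where sample sizes are tiny; masking is therefore explicit:
`absent` (n = 0), `insufficient` (n < 3), `zero_variance` (a flat vector),
with r reported only for unmasked pairs. Whether n counts all focal-positive
cells of the stage or only those with non-zero marker expression is
configurable (`nonzero_only`); the default counts all focal-positive cells.
"Significantly correlated" markers are counted as two-sided p < 0.05 with
r > 0 by default (an unsigned variant is provided), and no multiple-testing
correction is applied to the starred tiers — a Benjamini–Hochberg q column
is emitted alongside for users who want it.

## Fate classification

Membership in a signature class is the count of that signature's genes with
expression > 0 reaching k (default 3). The count reading is used — not a
per-gene significance gate — because it is the only reading that yields
discrete per-cell classes whose stage-wise counts can be intersected; an
alternative mode additionally gates membership on the signature score
exceeding a per-set threshold, for sensitivity analyses of that ambiguity.
The focal gene never counts toward a signature even if listed in one. The
partition {A-only, B-only, both, neither} is exhaustive and exclusive by
construction, monotone in k, and invariant to gene order.

## Vessel morphometry

Preprocessing is rolling-ball background subtraction applied slice-wise
(the 2-D-per-slice convention of the ImageJ family; default radius 15
voxels), a 3-D median filter with a ball footprint (default radius 1 — a
7-voxel cross, chosen over a full 3×3×3 cube because the cube erodes the
surface of thin tubes), and binarization at an explicit intensity value or
Otsu's threshold. Density is the foreground percentage of a half-open,
0-based (z, y, x) ROI box. Skeletonization is Lee-style topology-preserving
3-D thinning; skeleton voxels are classified by their 26-neighbor count
(end-point < 2, slab = 2, junction > 2) and 26-connected clusters of
junction voxels are merged into single junction nodes before counting, so a
thick crossing is one junction. Branches are the connected components of
the skeleton minus its junction voxels, with voxel-count lengths. Group
variability uses the sample standard deviation (n − 1) and
CV% = 100·s.d./mean, computed only for groups with positive mean and at
least two embryos. The batch check is a centered PCA of the embryo ×
ROI-density table with a between-batch / within-batch centroid-distance
ratio; values near or below 1 indicate negligible batch structure.

## Synthetic data

The atlas generator emulates the statistical structure the analysis relies
on, not scRNA-seq chemistry. Defaults (fixed once, used by the tests and
the acceptance script): 9 stages E6.5–E8.5 at 0.25-day spacing; 3,000 cells
per stage in library-scale runs (1,000 for repeated-seed studies — sizes
chosen so planted classes contain tens of cells); five tissues with
composition drifting from epiblast-dominated to LPM-dominated; focal
fraction ramping linearly 0.65% → 1.66%; focal-positive expression
log-normal with arithmetic mean 1.0 (σ = 0.25) on the log-CPM scale;
class probabilities (A-only, B-only, both, neither) = (0.10, 0.08, 0.02,
0.80); classed cells placed in the LPM-like tissue with probability 0.8;
signature genes of a member cell expressed with probability 0.9 (coupled
multiplicatively to the cell's focal level, giving positive within-class
correlations) versus 0.02 background; 400 unstructured noise genes at 5%
positivity. Zero-inflated log-normal values match the support and sparsity
of log-CPM data; they do not model ambient RNA, doublets, batch chemistry
or library-size variation, so passing tests demonstrate correctness of the
pipeline's logic and its statistical recovery under the stated generative
model, not robustness to those artefacts.

Vessel volumes are random trees of tube segments (each new segment attached
at the far node of a random existing segment, deflected 30–60°), rasterized
as "Euclidean distance to the centerline ≤ radius", plus a smooth linear
background gradient (15% of tube amplitude) and additive Gaussian noise.
Ground truth records the centerline voxels and the graph-degree end-point
(degree ≤ 1) and junction (degree ≥ 3) counts. Default volumes are 64³
(56³/48³ for the fixed Y-tree and straight-tube fixtures) with radius-2
tubes — small enough to run in seconds, thick enough that thinning recovers
the topology.

## Numerical choices and degenerate inputs

Rank ties are broken by seed, never by index order, so permuting the gene
order changes nothing but the tie outcome. Stages with zero positive cells
report an explicit NaN mean rather than being dropped. Constant score
distributions yield a single degenerate threshold candidate with a warning.
A square expression matrix on disk is ambiguous between orientations and
requires an explicit flag; rectangular matrices are auto-oriented against
the id-file lengths. Per-sample normalization uses the ceiling, so any
non-empty sample reports at least 1. TSV outputs are written with a fixed
float format and hashed into the manifest, making end-to-end runs
byte-reproducible under a fixed config.

## Known limitations

Real-atlas ingestion expects the user to export the processed matrix to
MTX/TSV; raw-count processing, QC and doublet handling are out of scope.
The correlation module does not correct the starred tiers for multiple
testing by design. Skeleton branch lengths are voxel counts, not physical
lengths (voxel size is carried but not yet applied to lengths), and vessel
diameters are not estimated. The threshold families mirror the common
rank-AUC tooling but are not bit-compatible with any particular release of
it; the mixture boundary depends mildly on the mixture seed, which is
logged.
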