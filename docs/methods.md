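# Methods

This note documents the models, parameter choices and numerical decisions
behind `mammodev`, and what the synthetic benchmarks do and do not show.

## Single-cell preprocessing

**QC.** A cell is retained iff its total UMI count is at least `min_umi`
(default 5000) *and* its mitochondrial UMI fraction is at most `max_mito`
(default 6%); genes must be detected in at least `min_cells_per_gene`
(default 3) of the retained cells, with the gene filter applied after the
cell filter. Mitochondrial genes are recognized by a case-insensitive
`mt-` prefix (mouse convention). Filtering an already-filtered matrix is a
no-op, and tightening any threshold can only shrink the result; both
properties are tested.

**Normalization.** Two layers are produced. `pearson` holds analytic
Pearson residuals of a negative-binomial model with per-cell depth offset
and fixed overdispersion θ = 100, clipped at ±√n_cells (computed through
scanpy's implementation); residual variance per gene ranks the highly
variable genes. This layer feeds HVG selection and PCA, where residual
variance is the meaningful signal. `lognorm` holds log1p counts-per-10k
and feeds everything that averages expression across cells — module
scores, marker fold changes, GAM smoothing, ligand–receptor means — where
a depth-normalized, positively valued scale is required. Using Pearson
residuals for those averages would make `expm1`-based fold changes and
detection fractions ill-defined.

**PCA.** Exact SVD on the centered HVG submatrix of the residual layer
(default 2000 HVGs, 15 PCs). Each component is oriented so its
largest-magnitude gene loading is positive, making scores reproducible
across linear-algebra backends.

**Clustering.** Unweighted symmetric kNN graph (k = 20, Euclidean in PC
space), Leiden modularity optimization at resolution 0.8 with a fixed
seed; labels are relabeled 0..K−1 by decreasing size. Modularity
optimization at this resolution subdivides even statistically homogeneous
cell populations of a few hundred cells — the reference single-cell
toolchain behaves identically — so cluster labels are treated as an
over-segmentation and merged downstream by lineage annotation (below)
whenever a lineage-level statement is needed.

**Markers.** One-vs-rest two-sided Wilcoxon rank-sum per gene on the
lognorm layer. Reported genes must exceed 10% in-cluster detection and a
natural-log fold change of 0.1 computed as
`ln(mean(expm1(x_in)) + 1) − ln(mean(expm1(x_out)) + 1)`. P values are
Benjamini–Hochberg adjusted within each cluster. The test statistic and
pseudocount follow the defaults of the standard marker procedure; the
upstream analysis does not state them.

**Cell-cycle regression.** S and G2/M module scores are computed from
user-supplied phase gene lists; each gene's lognorm expression is
regressed on (intercept, S, G2M) by OLS and the corrected layer keeps
residual + intercept, i.e. expression minus the fitted cycle contribution.
A proliferation score from the packaged 13-gene program is attached when
those genes are present.

## Identity (module) scores

Genes are ranked by mean expression on the scoring layer and split into
`n_bins` (24) equal-frequency bins; each signature gene draws
`n_ctrl_per_bin` (100) control genes from its bin (seeded, without
replacement, signature genes excluded; if a bin contains only signature
genes the bin itself is the pool, which makes the self-control score
exactly zero). The score is mean(signature) − mean(controls) per cell. It
is invariant to adding a constant to the whole layer and centered at zero
for random gene sets.

Cluster annotation assigns each cluster the signature with the highest
median score, or `hybrid` when the top two medians differ by less than
`hybrid_margin` (0.05). Because the control draw shifts every score by an
arbitrary constant (different controls, different offset), score columns
are median-centered across all cells before medians are compared;
without centering the margin would be swamped by the offset. Uncommitted
early-stage clusters then annotate as `hybrid` and committed clusters by
their lineage, which is also how lineage-level cluster counts and
branch-recovery ARI are measured.

## 3D trajectory and pseudotime

The embedding axes are (luminal score, basal score, developmental axis).
The developmental axis defaults to the principal component most
(Spearman-) correlated with stage rank — in the motivating data this is
PC2 — oriented so the earliest stage has the lowest mean, and all three
axes are min–max scaled by default so score units and PC units are
commensurate before distances are taken (recorded in the embedding
metadata). Pseudo-bulks are coordinate-wise cluster medians; the MST uses
Euclidean edge lengths with lexicographic tie-breaking on cluster-id pairs
(Kruskal with a stable sort), making the tree deterministic; coincident
centers produce a zero-length edge and a warning. Lineage paths are the
unique tree paths from the root (largest earliest-stage cluster) to the
endpoint clusters (final-stage clusters with the highest median basal and
luminal scores; if both maxima coincide, the two most score-divergent
final-stage clusters). Pseudotime projects each cell onto every path
segment (clamped), picks the segment with the smallest orthogonal
residual (ties to the earlier segment), and returns arc length from the
root. Cells are projected onto both lineages; lineage-restricted analyses
(pattern discovery, pseudotime-vs-latent-time checks) use only cells whose
clusters lie on that lineage's path.

## Expression patterns

Within a lineage, genes are ranked by variance (two-pass, ddof 1) of
lognorm expression across the lineage's cells; the top 10% (ceil, ties by
gene symbol) are smoothed. Smoothing fits a penalized cubic regression
spline per gene: 6 cubic B-spline basis functions with interior knots at
quantile positions, a second-order difference penalty on coefficients, and
the penalty weight chosen per gene by generalized cross-validation over a
30-point log-spaced grid (10⁻⁶…10⁶). Cells sharing a pseudotime are
aggregated to their mean with multiplicity weights; with fewer distinct
pseudotimes than basis functions the fit degrades to linear
interpolation. (scipy's `make_smoothing_spline` GCV was evaluated for this
step and rejected: it collapses to a near-linear fit even on noiseless
curves of moderate range.) Smoothed profiles are z-scored across the grid
(switchable), clustered agglomeratively with Euclidean distance and
complete linkage, and the dendrogram is cut at k (defaults: 5 basal, 7
luminal). Pattern ids are ordered by the grid position of the pattern
mean's maximum, so pattern 1 always peaks earliest.

## Ligand–receptor permutation test

Observed statistic: the arithmetic mean of the ligand's mean lognorm
expression in the sender cluster and the receptor's in the receiver
cluster, for every ordered cluster pair (self-pairs included). Null:
cluster labels of all cells permuted `n_perm` (1000) times; the p-value
uses add-one smoothing, p = (1 + #{null ≥ observed}) / (1 + n_perm), so
p ∈ [1/(n_perm+1), 1]. Pairs whose ligand (receptor) is detected in fewer
than 10% of sender (receiver) cells are assigned p = 1 without testing.
Cells are internally sorted by barcode before permuting, so results do not
depend on input cell order. Multi-subunit complexes are out of scope: the
pair table is strictly gene–gene. Adding a cluster changes the permutation
pool and therefore can move p-values of other cluster pairs; this is a
property of the statistic, verified against exhaustive enumeration at toy
scale.

## smFISH quantification

**Segmentation.** The membrane channel is Gaussian-smoothed (σ = 1.5 px);
seeds are h-minima of depth 10% of the in-mask intensity range; watershed
floods the smoothed intensity inside the bud mask; regions under 30 px are
merged into the neighbor sharing the longest boundary; labels are
renumbered from 1. Every mask pixel receives exactly one label.

**Spot detection.** Channels are normalized by the dtype range (integer
images) or clipped at zero and divided by the maximum only when it exceeds
one (float images) — deliberately *not* per-image min–max stretched, which
would amplify noise-only channels to full scale and make a
signal-independent threshold impossible. The scale-normalized negative
LoG is evaluated at ≥5 σ values in [1, 2] px; 3-D local maxima of the
response cube above the threshold are kept; the adaptive default threshold
is Otsu over the positive responses with a floor of 0.1 (fraction of the
normalized dynamic range), and a stronger maximum suppresses weaker ones
within √2·σ. Spots are integer-pixel maxima; subpixel refinement is not
attempted.

**Ratios.** Spots map to the label under their rounded coordinates; the
two-probe ratio nA/(nA+nB) colors each cell on a perceptual purple→yellow
colormap (viridis); spotless cells are rendered neutral gray.

**Rings.** The bud's Euclidean distance-to-boundary transform, normalized
by its maximum, is banded into equal thirds: outer [0,⅓), middle [⅓,⅔),
inner [⅔,1]. This is well defined for irregular outlines and partitions
the mask exactly. Per replicate and probe, ring percentages are counts
over the in-mask total; replicates without in-mask spots are excluded with
a warning. The two-way fixed-effects ANOVA (percentage ~ probe × ring,
type II sums of squares) tests differential radial distribution; per-ring
probe contrasts are Šidák-corrected t-tests.

## Branching morphometrics

**Segmentation.** Gaussian smoothing → Otsu → largest connected component
→ morphological closing; boolean input bypasses segmentation so external
segmenters (e.g. a trained network) can be plugged in.

**Tips and tracking.** Tips are skeleton pixels with exactly one
8-connected skeleton neighbor, excluding a 2 px border margin. Linking is
greedy by increasing distance between consecutive frames under a 30 µm
gate; unlinked tips open new tracks; tracks shorter than 3 frames are
discarded. Velocity is traveled path length (µm) divided by elapsed time
(h) — a path-length reading of "distance traveled over time" — which
slightly exceeds net-displacement velocity when tips jitter.

**Morphometrics.** Area is foreground pixels × pixel size²; fold change is
relative to frame 0 (exactly 1 there, independent of calibration). Branch
count is the tip count of the final frame. Base diameter is twice the
distance-transform value at the first skeleton junction (degree ≥ 3)
walking from the tip, or at the widest point of the walked path when the
skeleton has no junction.

**EdU.** Nuclei are LoG blobs (σ 3–8 px) on the normalized nuclear channel
inside the epithelium mask; a nucleus is EdU⁺ when its mean EdU intensity
within a disk of its detected radius exceeds Otsu over all nuclear means
(explicit threshold overridable). If all nuclear means are equal the
fraction is 100% for positive means and 0% for zero — the all-bright and
all-dark edge cases.

## Synthetic data

**Lineage counts.** A Y-shaped latent time t ∈ [0,1] with branch point at
0.4 mirrors commitment at E15.5; stages map to overlapping windows
(E13.5 [0,0.25], E14.5 [0.2,0.4], E15.5 [0.35,0.7], P0 [0.7,1.0]) and
default per-stage cell numbers equal the atlas's high-quality cell counts
(228/59/740/409). Gene baselines are log-normal; 50 basal and 50 luminal
signature genes diverge by ±1.5 log2 × commitment along the branches; 150
temporal genes ramp up or down with t (1.5 log2 swing) and carry the
developmental axis; 10 `mt-` genes are rescaled per cell so the expected
mitochondrial share equals `mito_fraction` (3%). Counts are
negative-binomial (dispersion 0.1) at log-normal library sizes (mean
20 000 UMIs); 5% of cells are injected with low depth (500–4000 UMIs) or
high mitochondrial load (10–25%) to exercise QC. Not emulated: doublets,
batch effects, ambient RNA, gene–gene correlation beyond the latent
factors — so passing benchmarks show the pipeline recovers structure it
models, not robustness to those artifacts.

**Bud images.** An elliptical mask (42% of each dimension) holds a Voronoi
mosaic of uniformly sampled cell centers; the membrane channel is a
Gaussian-blurred boundary map; each probe draws Poisson spot counts per
cell at the ring density of the cell's centroid ring and renders Gaussian
spots (σ 1.5 px, amplitude 1) plus Gaussian noise (sd 0.1 → SNR 10);
channels are written at fixed intensity scale into uint16. The default
profile opposes an inner-biased and an outer-biased probe, the
configuration of the two early lineage markers the ring statistic was
built to compare.

**Branch movies.** Thick rays (width 7 px) from a central body advance
their distal endpoints at fixed velocities; defaults are 25 frames at
60-min intervals (the 24-h imaging protocol) with velocities 5/10/20 µm/h
at 1 µm/px on an 1100² canvas sized so the fastest tip stays in frame.
Branches never bifurcate mid-movie; track births from branch splitting are
handled by the tracker but not exercised by the generator.

## Problem sizes

The shipped verification uses desk-scale problems chosen to exercise every
code path with comfortable statistical margins: ~1450-cell simulated
atlases (3 seeds), 100 random MST configurations against exhaustive
enumeration (≤6 nodes), 100 null datasets of 100 cells for test
calibration, 100–140 archetype profiles, 512² bud sections, and three
25-frame movies. All are generated at run time from seeds.

## Known limitations

- Pearson-residual overdispersion is fixed (θ = 100) rather than fitted
  per gene with regularization; at desk scale the residuals agree with the
  regularized fit's published behavior, but very highly expressed genes
  may be slightly over-weighted.
- Cluster labels oversegment homogeneous populations at resolution 0.8
  (inherent to modularity optimization); lineage-level conclusions use
  annotations, not raw labels.
- Spot assignment is by containing pixel; boundary spots are not
  fractionally shared between cells.
- The tracker is greedy, not a global assignment; at high tip densities
  (< gate spacing) identities may swap.
- 2D only throughout the imaging modules.
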