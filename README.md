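# mammodev

Analysis toolkit for embryonic mammary gland development: single-cell
lineage trajectories from bud invagination (E13.5) to birth (P0),
single-molecule RNA-FISH spatial quantification of lineage markers within
mammary buds, and branching morphometrics of ex vivo explant movies.

The embryonic mammary gland is built by multipotent mammary stem cells
(MaSCs) that commit to the two adult epithelial lineages — outer basal
(myoepithelial) and inner luminal cells — around the first sprouting events
at E15.5. `mammodev` implements the computational machinery to resolve this
commitment from data:

- **Single-cell pipeline** — QC (UMI ≥ 5000, mitochondrial fraction ≤ 6%,
  genes in ≥ 3 cells), analytic Pearson-residual normalization of a
  negative-binomial count model, PCA on the top 2000 variable genes (15
  PCs), Leiden clustering on a kNN graph (resolution 0.8), Wilcoxon
  one-vs-rest markers (detection fraction > 10%, ln fold change > 0.1),
  and cell-cycle regression on S/G2M module scores.
- **Identity scores** — per-cell module scores
  `s_c = mean(expr[signature]) − mean(expr[controls])` with controls drawn
  from expression-matched bins (24 bins, 100 controls per signature gene),
  used as basal/luminal/LP/ML lineage IDs.
- **3D trajectory** — cells embedded in (luminal score, basal score,
  developmental axis); cluster pseudo-bulks (coordinate-wise medians)
  joined by a Euclidean minimum spanning tree; basal and luminal lineages
  are root-to-endpoint tree paths; per-cell pseudotime is the arc length of
  the cell's orthogonal projection onto the lineage polyline.
- **Expression patterns** — genes in the top 10% of variance along a
  lineage smoothed against pseudotime with a penalized cubic regression
  spline (GCV), then grouped by complete-linkage hierarchical clustering
  (5 basal / 7 luminal patterns by default).
- **Ligand–receptor inference** — for each ordered cluster pair and
  gene pair, the statistic ½(mean ligand in sender + mean receptor in
  receiver) tested against a null from permuting cluster labels
  (significant at p < 0.01).
- **smFISH quantification** — watershed cell segmentation on the membrane
  channel, scale-space Laplacian-of-Gaussian transcript detection
  (σ ∈ [1, 2] px), per-cell probe ratios on a purple→yellow key, and a
  three-concentric-ring statistic (inner/middle/outer distance-transform
  bands) compared across probes by two-way ANOVA.
- **Branching morphometrics** — skeleton-endpoint tip tracking with greedy
  frame-to-frame linking, growth velocity (traveled path length / time),
  explant area fold change, branch counts, base diameters, and EdU⁺
  nuclear fractions.

Every data type has a synthetic generator
(`mammodev.simulate`) with known ground truth — negative-binomial counts
over a Y-shaped basal/luminal lineage, Voronoi-cell bud images with
controlled per-ring spot densities, and growing-branch mask movies — so the
whole pipeline is testable without any downloads.

## Worked example

Simulate a four-stage atlas and run the full lineage pipeline:

```python
from mammodev import (GeneSignature, LineageSimSpec, gen_lineage_counts,
                      run_lineage_pipeline)

adata, truth = gen_lineage_counts(LineageSimSpec(seed=1))
res = run_lineage_pipeline(
    adata,
    GeneSignature("basal", tuple(truth.basal_genes)),
    GeneSignature("luminal", tuple(truth.luminal_genes)),
)
print(res.root, res.endpoints)
print([p.clusters for p in res.paths])
```

prints

```
E13.5:0 {'basal': 'P0:3', 'luminal': 'P0:1'}
[['E13.5:0', 'E13.5:1', 'E14.5:0', 'E14.5:1', 'E15.5:0', 'E15.5:2', 'P0:0', 'P0:3'],
 ['E13.5:0', 'E13.5:1', 'E14.5:0', 'E14.5:1', 'E15.5:0', 'E15.5:1', 'P0:2', 'P0:1']]
```

— the two differentiation routes share their early (E13.5→E15.5) prefix
and diverge into the basal-annotated and luminal-annotated P0 clusters,
the Y-shaped hierarchy the trajectory analysis is designed to expose. On
this simulation the P0 lineage annotation matches the true branch exactly
(adjusted Rand index 1.0) and pseudotime correlates with the latent
developmental time at Spearman ρ ≈ 0.99 on both lineages.

The same steps are available from the shell:

```sh
mammodev simulate counts --out sim --seed 1
mammodev pipeline sim --basal-sig basal.txt --luminal-sig luminal.txt --out results
mammodev fish bud.tif mask.tif --out fishout
mammodev branches movie.tif --px-size 1.0 --dt 60 --out tracks
```

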