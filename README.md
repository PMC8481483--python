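# cordatlas

Harmonization, clustering, and two-tiered classification for multi-study
single-cell RNA-seq atlases of the mouse spinal cord.

Independent single-cell and single-nucleus studies of the same tissue rarely
agree on its cell types: they differ in sequencing depth, per-gene capture
efficiency, and protocol artifacts (dissociation of whole cells induces
immediate-early/stress genes and enriches metabolic transcripts relative to
nuclei), and each group clusters at its own granularity.  `cordatlas`
implements the analysis pattern used to build harmonized spinal cord
atlases: uniform QC and normalization across studies, anchor-based batch
integration, multiphase graph clustering with explicit cluster-hygiene rules,
marker statistics, cross-atlas registration and embryonic lineage inference,
and a two-tiered cell-type classifier that can place new datasets onto the
harmonized reference.  A seeded synthetic multi-study generator reproduces
the statistical structure this workflow assumes, so the entire pipeline runs
and is tested without any external download.

## The method

- **QC and normalization.** Cells with > 200 detected genes and < 5%
  mitochondrial transcripts are kept.  Counts are library-size normalized to
  10,000 per cell and log-transformed: `x = ln(1 + c·10⁴/total)`.  Highly
  variable genes (HVGs) are selected by mean/dispersion cutoffs (mean in
  (0.0125, 3), bin-standardized dispersion > 0.5) or as a top-N by
  standardized dispersion.  Expression is scaled per gene by OLS-regressing
  out total counts and mitochondrial percentage, z-scoring, and clipping.
- **Integration.** Two batches are co-embedded by diagonalized canonical
  correlation analysis — the SVD of the cross-product `A Bᵀ` of their scaled
  HVG matrices, with 20 components and L2-normalized rows.  Anchors are
  mutual nearest-neighbor cell pairs in that space, scored by shared-neighbor
  overlap.  Each query cell is corrected by a Gaussian-kernel, score-weighted
  average of its nearest anchors' difference vectors; studies merge
  sequentially, largest first.  Mixing and coherence are quantified by the
  Local Inverse Simpson Index (LISI) of batch and cell-type labels.
- **Clustering.** k-nearest-neighbor graphs with shared-neighbor Jaccard
  weights, partitioned by Leiden.  Phases follow the atlas workflow: all
  cells (28 PCs, resolution 1.2), then the neuronal compartment re-selected,
  re-scaled, and re-integrated (4,000 HVGs, 40 PCs), then targeted
  sub-clustering (40 PCs/res 4; 7 PCs/res 0.6).  After each phase: clusters
  with fewer than three significant markers are flagged low-quality;
  clusters whose markers span two unrelated coarse signatures and whose
  individual cells co-express both ("barnyard" pattern) are flagged as
  doublets; mutually-nearest cluster pairs with fewer than three genes
  enriched per side (six total) are merged unless a classic marker gene
  ranks among the pair's top five DE genes.  Cluster robustness is the
  bootstrapped co-clustering frequency across 100 subsampled re-clustering
  iterations, plus per-cluster silhouette.
- **Markers and DE.** Wilcoxon rank-sum (exact enumeration for small groups,
  tie-corrected normal approximation otherwise, Bonferroni adjustment) and
  AUROC analysis (power = 2·|AUC − 0.5|), with minimum-fraction and
  log-fold-change prefilters; class-level signatures (>30% expressing,
  logFC > 0.25, power > 0.6); within-cluster condition DE (Wilcox, FC 0.25,
  10% expressing, top 30 per cluster, deduplicated union); and a greedy
  combinatorial (family marker + given marker) panel.
- **Cross-mapping.** Cluster centroids in 50-PC space, complete-linkage
  dendrograms, row-normalized overlap matrices, top-500-HVG correlation
  registration, and embryonic lineage assignment combining centroid-distance
  ranks with nearest-cell label votes; secondary lineages above a vote
  threshold are reported as convergences.
- **Two-tier classifier.** Tier 1 projects the query onto the reference PCA
  (28 dims for coarse types) and transfers labels through mutual-nearest-
  neighbor anchors with weighted voting; cells labeled neuron, motoneuron,
  or doublet are routed to Tier 2, a softmax network (one hidden layer of
  256 units, SGD, batch size 32) over fine neuronal types + doublet, trained
  on log-transformed counts scaled by each cell's maximum.  A linear SVM
  (max-abs scaling, `dual=False`, `max_iter=10000`) is the baseline.  An
  unknown query cluster is identified with a reference type when ≥ 80% of
  its cells receive that single non-junk, non-doublet prediction.

## Worked example

```python
from cordatlas.pipeline import PipelineConfig, run_pipeline

results = run_pipeline(PipelineConfig(seed=1, robustness_iterations=100))
print(round(results["clustering"]["ari_discrete"], 3))
print(round(results["robustness"]["freq_discrete"], 3),
      round(results["robustness"]["freq_overlapping"], 3))
print(round(results["classifier"]["overall_accuracy"], 3),
      round(results["classifier"]["mean_cocluster_frequency"], 3))
```

prints

```
1.0
1.0 0.528
0.957 0.843
```

Discrete-regime fine types (the analogue of well-separated dorsal
populations) are recovered exactly (ARI 1.0) and are perfectly stable under
bootstrapped re-clustering (co-clustering frequency 1.0), while
overlapping-regime types (the continuously varying mid/ventral analogue)
co-cluster only 53% of the time — the robustness gradient the atlas reports.
The two-tier classifier labels 95.7% of held-out cells correctly, exceeding
the 84.3% mean co-clustering frequency of the same clustering: the
classifier is more reliable than re-clustering, which is the argument for
using it to standardize cell-type assignment.

The same pipeline is exposed on the command line:

```bash
cordatlas simulate --outdir sim/ --seed 1     # MTX + sidecars per study
cordatlas qc --indir sim/studyA --out qc/     # filter report as JSON
cordatlas integrate --indir qc/ --out emb/    # corrected PC embedding
cordatlas run --outdir run/ --seed 1          # full pipeline + summary.json
```

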