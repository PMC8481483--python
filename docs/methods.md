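# Methods

This note documents the models, parameter choices, and numerical conventions
behind `cordatlas`, and what the synthetic benchmark does and does not show.

## Synthetic multi-study generator

The generator (`cordatlas.synthetic`) emulates the statistical structure of
a multi-study spinal cord compilation rather than any particular dataset.

**Cell-type hierarchy.** Types are organized coarse → family → fine.  Each
fine type has a mean log-expression program built from a shared baseline, a
coarse-class shift (sd 0.9), a family shift (sd 0.3), fine-specific jitter,
and a marker boost on a dedicated gene block.  Two separation regimes are
planted: *discrete* types carry strong (+2.5 log) boosts on mutually
disjoint marker sets; *overlapping* types carry weak (+1.1) boosts on
partially shared marker sets, are pulled toward their coarse mean, and —
crucially — each overlapping cell's program is mixed by a per-cell uniform
weight in [0, 0.7] toward the mean program of its class's overlapping
types.  The last makes overlapping populations a genuine continuum:
clustering algorithms split them inconsistently, which is what produces the
robustness gradient between regimes (the dorsal-vs-mid/ventral analogue).
Overlapping flags are assigned in within-class pairs from the end of the
type list, so the neuronal class always contains both regimes; the count is
`floor(overlap_fraction · n_fine)`.

**Counts.** Per cell: gene rates `exp(program + capture bias)` are
normalized to a composition, multiplied by a log-normal library size
(sigma 0.4, a typical droplet-data spread; expected depth 2,500 ×
`depth_factor`), and sampled as negative binomial via gamma–Poisson
(dispersion 0.15; dispersion 0 falls back to Poisson).  Capture bias is a
per-study per-gene normal log-offset, `batch_effect_strength ×
N(0, capture_bias_sd)`.  The default strength 2.0 was calibrated to the one
stated criterion available: unintegrated graph clustering should separate
the studies (at 2.0, 97% of unintegrated clusters are dominated by a single
study; at 1.0 only 18% are).

**Artifacts.** Protocol effects multiply fixed contiguous gene modules
(immediate-early, 30 genes, ×3 in cell protocols; metabolic, 40 genes, ×2),
a 10-gene mitochondrial module is rescaled so the expected mitochondrial
fraction is 2.5%, doublets are raw sums of two uniformly drawn same-study
singlets (the dual-signature "barnyard" phenotype used for detection), and
low-quality barcodes are singlets binomially downsampled to an expected 120
total counts, which keeps their detected-gene count below the 200-gene QC
threshold in ≥ 90% of draws across the default depth range.  Doublet and
low-quality rates are applied as fixed counts (`floor(rate·n)`) so tests
are exact.

**Embryonic companion.** Progenitor programs are convex mixtures of fine
programs plus a +1.5 boost on a shared 40-gene immaturity module and small
progenitor-specific jitter (sd 0.15) that keeps convergent parents
distinguishable.  By default progenitor *i* descends 1:1 into fine type
*i mod n_fine*; planted convergences give one fine type two progenitor
parents, recorded in the ground-truth lineage map.

**What the generator does not model:** ambient RNA, UMI collisions,
spliced/unspliced structure, per-study gene universes, and realistic gene
names.  Passing tests therefore demonstrate that the pipeline's logic is
correct under its own assumptions, not that it is robust to every artifact
of real data.

## Pipeline conventions and defaults

- QC: strictly more than 200 detected genes (the headline inclusion
  criterion; an `inclusive_min_genes` flag switches to ≥), mitochondrial
  fraction strictly below 5%; mito genes found by `var["mito"]` or the
  `mt-` prefix.
- HVG dispersion standardization uses 20 equal-frequency mean bins;
  mean cutoffs act on `log1p` of the back-transformed mean.  Bins with
  undefined spread fall back to the raw log dispersion.
- Scaling clips at ±10; zero-variance residual genes scale to zero.
  Covariates are standardized internally so the fitted state can transform
  query data.
- Integration: CCA on scaled HVG matrices; component signs fixed so the
  largest-magnitude entry is positive; neighbor ties broken by index; merge
  order is size-descending (largest study is the reference).  Anchor scores
  are min-max-normalized shared-neighbor counts; correction weights are a
  Gaussian kernel over the distance to each cell's `k_weight` nearest
  anchors (bandwidth = distance to the furthest of them) times the anchor
  score.
- PCA keeps loadings for projection; a seeded randomized SVD is used for
  large problems, exact SVD otherwise — both deterministic.
- LISI: Gaussian kernel bandwidth per cell tuned by bisection to a target
  perplexity (default 30) over ~3·perplexity neighbors.
- SNN graph: k = 20 neighborhoods including self, Jaccard weights, edges
  ≤ 1/15 pruned.  Leiden (not Louvain) for determinism and quality; RB
  configuration modularity; seeded.
- Merge rule: candidate pairs are mutually-nearest centroids (a
  deterministic surrogate for dendrogram-plus-inspection curation).  A pair
  merges when each side has < 3 significantly enriched genes (adjusted
  p < 0.05, logFC > 0.25, ≥ 10% expressing) and no classic marker ranks in
  the pooled top 5 by adjusted p.  The surviving id is the
  lexicographically first; provenance is recorded and remains acyclic.
- Doublet rule: condition (a) significant markers intersect ≥ 2 unrelated
  coarse signatures; condition (b) ≥ 50% of cluster cells score above half
  the positive peak (90th percentile of out-of-cluster scores) on *both*
  signatures' top-10 marker sums.  Expressing the threshold as a fraction
  of the positive peak keeps the rule valid whichever share of the
  background expresses each signature.
- Robustness: 100 iterations, 80% subsampling without replacement (the
  bootstrap scheme is a documented choice).  Because the clustering being
  scored includes batch correction, subsamples are drawn from the corrected
  expression matrix and PCA → graph → Leiden are re-run per iteration.
  Fine-type robustness is scored at resolution 4 with 28 PCs — the targeted
  sub-clustering resolution, i.e. the setting under which hard populations
  are actually split — and reference groups are the ground-truth fine types
  so robustness can be paired with per-class F1.
- DE: logFC uses pseudocount 1 inside the ratio of back-transformed means;
  Bonferroni over the tested (post-filter) genes, matching the named
  tooling's default; tables are enrichment-directional (positive logFC).
  The AUROC "power > 6" threshold quoted for class signatures is impossible
  on the power scale (bounded by 1) and is implemented as `power_cut = 0.6`.
  For the *pooled* within-cluster covariate union, the null-calibration
  stage controls the familywise error over the total pooled test count.
- Lineage: combined rank = centroid-distance rank + vote rank over the 50
  nearest embryonic cells; ties broken by distance; secondaries require a
  ≥ 0.2 vote fraction.  Marker evidence is surfaced in reports rather than
  folded into the score, since its original weighting was manual.
- Tier 1 uses 28 reference dims (100 all-neuron, 30 mid/ventral in the
  two-phase variant); cells without usable anchors fall back to a k = 15
  reference-cell majority vote and are flagged.  Tier 2 defaults to one
  hidden layer of 256 ReLU units, SGD with momentum 0.9 at learning rate
  0.05, batch size 32, up to 50 epochs with early stopping (patience 8) on
  a 10% validation split; no class reweighting, so prevalence effects are
  preserved.  "Scaled by the maximum" is implemented as division by the
  per-cell maximum of the log-transformed values.
- The end-to-end driver runs at desk scale by default: 3 studies × 1,000
  cells, 1,500 genes, 12 fine types with 4 overlapping (two blending
  pairs), 1,000 HVGs, 28 PCs — sizes chosen so the full run, including 100
  bootstrap iterations, completes in a few minutes on one CPU while keeping
  every planted contrast detectable.

## Known limitations

- The anchor corrector removes planted batch offsets to within the
  estimation noise of the anchor difference vectors (~`sqrt(2·n_genes /
  n_anchors)` in z-score units); with small studies the residual study gap
  is noise-dominated rather than bias-dominated.
- Phase selection feeds later phases by signature score with a midpoint
  threshold; on data without a clear neuronal compartment the phase is
  skipped with a warning rather than guessed.
- The two-sided rank-sum p uses a continuity-corrected normal approximation
  above group size 10; exact enumeration below.  Observed null false-positive
  rates on discrete counts run slightly above nominal (~6% at 5%).
- The Tier-2 network is a CPU numpy implementation; the architecture sweep
  tokens cover the shapes studied (linear, 1–3 hidden layers, optional L2
  on all or the first layer) but not arbitrary graphs.
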