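# Methods

This note documents the models and procedures implemented in
`polypcontinuum`, the study conditions encoded in the synthetic-cohort
generator, and the numerical choices made where the design was open.

## The analysis model

The pipeline assumes a cohort of samples from four disease states
(normal colon, unaffected tissue from polyp-bearing donors, polyps,
carcinomas), each profiled at single-cell resolution for chromatin
accessibility (peak × cell counts) and/or expression (gene × cell
counts). The central biological assumption is that malignant
transformation acts through the stem-like epithelial compartment: as a
lesion progresses, (i) the fraction of stem-like cells rises, and
(ii) the regulatory state of those stem-like cells drifts away from
normal intestinal stem cells through a stereotyped sequence of
chromatin opening/closing and gene up-/down-regulation events.

The latent quantity of interest is each sample's position on this
progression. It is estimated without supervision: per-sample log₂
fold-change profiles of stem-like cells versus a fixed normal-stem
background are embedded by PCA, a one-dimensional curve is fitted
through the 2-D principal-component scatter, and the arc-length
coordinate of each sample's projection onto the curve is its continuum
position.

## Stage-by-stage procedure and numerics

### Iterative LSI and projection (`lsi`)

* TF–IDF: tf = count / per-cell total over the selected features;
  idf = ln(1 + N_cells / n_cells_with_feature). Features absent from
  all reference cells receive idf via max(n, 1) smoothing and are
  masked (zeroed) both in fitting and projection, so query-only
  features cannot perturb the embedding. Cells with zero total over
  the selected features map to the origin.
* Each round: variable features (per-cell variance of log1p
  depth-normalised counts in round 1; variance of cluster-aggregated
  log₂-CPM profiles with a depth-scaled prior count of 3 afterwards)
  → TF–IDF → truncated SVD (ARPACK, fixed seed) → Leiden clustering on
  a kNN graph (k = 15; resolutions default 0.1 / 0.1 / 0.2 between
  rounds, RNA convention 0.1 / 0.2 / 0.4; a k-means fallback is
  available behind `cluster_method`). Defaults: 4 rounds; 1,600
  variable genes and 8 dimensions for RNA, 15,000 features and 30
  dimensions for ATAC (the synthetic pipeline uses 5,000/15 because
  its peak set is smaller).
* SVD sign convention: each component is flipped so its
  largest-magnitude feature loading is positive; this makes serialised
  models and re-fits bit-comparable.
* Embedding dimensions whose point-biserial correlation with any
  sample indicator exceeds 0.8 (configurable) can be dropped before
  neighbour search; dropping all dimensions is an error.
* Label transfer: modal label of the 25 nearest reference cells
  (Euclidean). Ties are broken by summed inverse distance, then
  lexicographically — fully deterministic.
* ATAC counts are used as-is by default; binarization is a flag, since
  the appropriate convention for accessibility counts is unsettled.

### Differential testing (`stats`, `differential`)

* Rank-sum test: exact enumeration of the null rank-sum distribution
  (dynamic programming) when the pooled size is ≤ 10 with no ties;
  otherwise the normal approximation with tie correction and a 0.5
  continuity correction. Identical constant samples give p = 1. The
  matrix path (`rank_sum_rows`) always uses the asymptotic form, which
  is the regime of real group sizes.
* Hurdle test (for sparse expression): Fisher exact test on detection
  proportions combined with the rank-sum test on positive values via
  Fisher's method (χ², 4 df); when one part is degenerate the other is
  returned alone. This is a deliberate two-part substitute for a
  mixed-model expression test; results are labelled "hurdle".
* Fold changes: log₂((mean_t + c)/(mean_b + c)) on per-cell
  depth-normalised values (each cell scaled to the median depth),
  pseudocount c = 1. The pseudocount bounds attainable |log₂FC| at low
  abundance; the generator's effect sizes were chosen with this in
  mind (below).
* Multiplicity: Benjamini–Hochberg step-up within each sample's table;
  Bonferroni where a small fixed family of composition comparisons is
  tested.
* Per-sample differentials: unaffected samples sharing donor and colon
  region are merged before the minimum-cell rule (default 250 target
  cells for full-size ATAC cohorts, 100 for RNA; the synthetic
  pipeline uses 50, matching its 500-cell samples); groups larger than
  `max_cells_per_group` (300 for RNA) are subsampled with a fixed
  seed.

### Continuum (`continuum`)

* PCA is the column-centred SVD with the same sign convention as LSI.
* Principal curve: Hastie–Stuetzle iteration — project points onto the
  current polyline, re-smooth each coordinate against arc length with
  LOWESS (default frac 0.35, locally linear, no robustness
  iterations), resample to a 200-point polyline, repeat until the mean
  projection distance changes by < 1e-4 relative. The curve is
  initialised from the first principal component, which also makes the
  procedure deterministic. A smoothing-spline-of-PC2-on-PC1 fallback
  is not provided; the principal curve subsumes that case (a scatter
  that is a function of PC1 yields exactly that curve).
* Positions are arc lengths of nearest polyline points; orientation is
  anchored by flipping the coordinate when the mean position of
  normal/unaffected samples exceeds that of the rest, so "low =
  normal-like" regardless of the curve's internal direction.
* Exact ties in arc-length coordinates during smoothing are separated
  by an order-preserving 1e-9-relative jitter so the smoother sees
  strictly increasing abscissae.

### Programs, motifs, links, scores (`programs`)

* k-means: Lloyd's algorithm, k-means++ initialisation, Euclidean
  metric, max 500 iterations, empty clusters re-seeded from the point
  farthest from its centroid. Ten restarts are run (sub-seeded from
  the given seed) and the lowest-inertia solution kept; single-restart
  behaviour is available via `n_init=1`. Restarts guard against the
  local optima that otherwise merge adjacent same-direction programs.
* Hypergeometric enrichment: upper tail P(X ≥ overlap) with the
  clustered feature set as the universe (the whole peak set can be
  passed instead); BH across motifs within a cluster.
* Motif deviations: expected motif counts per cell = (motif's share of
  total accessibility) × cell depth; raw deviation =
  (observed − expected)/expected; z-scored against 50 background peak
  sets matched on total accessibility via equal-frequency bins
  (50 bins). GC-content matching is not applicable to synthetic peaks
  and is therefore not implemented; a GC column would slot into the
  same binning. Motifs with no peaks give NaN.
* Peak–gene links: cells are grouped into 100 pseudo-bulk aggregates
  (k-means on a PCA of log-normalised expression, or a supplied
  embedding); pairs with TSS within 250 kb of the peak are tested by
  Pearson correlation of log-normalised aggregate profiles with the
  t-distribution p-value; links require |r| ≥ 0.45 and BH FDR ≤ 0.05.
  Window and cutoffs mirror the conventions of the standard tooling
  for this step and are exposed as parameters.
* Module score: mean normalised signal over the feature set minus the
  mean over control features drawn per set-feature from the same
  average-abundance bin (25 bins, 100 controls per feature, seeded).
  This is the standard control-gene-set scheme; the exact stemness
  score formula used in any particular study is swappable via this
  interface. Score distributions are summarised per sample in 50
  equal-width bins over the pooled range.

### Methylation integration (`methylation`)

* Differential probes: rank-sum across samples plus a mean β-value
  difference threshold, defaults p ≤ 1e-5 and |Δβ| ≥ 0.25. The test
  behind the published cutoffs is a package internal; here the cutoffs,
  which define the analysis, are applied to a transparent rank-sum.
* Overlap: probes are 1-bp points at the CpG coordinate; a probe at p
  overlaps peak [s, e) iff s ≤ p < e.
* Concordance: probe-bearing peaks are classed up/down by membership
  in program clusters whose mean log₂FC is positive/negative, else
  non-differential. A peak overlapping both hyper- and hypomethylated
  probes is counted in both probe-class columns and flagged; both
  resolution strategies (exclusive vs. double-counting) reduce to the
  same table when mixed peaks are absent, as in the generator's
  planted data.
* Sign test: exact binomial, two-sided (minlike convention), zeros
  dropped.

## The synthetic cohort

The generator encodes the study conditions under which the pipeline is
validated. Defaults (all in `SimConfig`):

* **Cohort**: 6 normal, 8 unaffected, 20 polyp, 6 CRC samples × 500
  cells; 5,000 peaks, 2,000 genes. Latent malignancy m = 0 for
  normal/unaffected, evenly spread over [0.05, 0.92] for polyps,
  [0.93, 1.0] for CRC.
* **Cell types**: stem → TA → enterocyte progenitor → immature
  enterocyte → enterocyte, plus a goblet (secretory) branch. The
  stem fraction is 0.15 + 0.5·m (capped at 0.85); mature-enterocyte
  weight decays fastest with m. Each type has 150 marker peaks
  (rate 3.0 vs background 0.3) and 60 marker genes, which is what makes
  types separable in LSI space.
* **Programs**: 10 programs × 25 peaks (12 genes), alternating
  direction, activating via a logistic ramp in m (steepness 25,
  re-anchored to exactly 0 at m = 0). Up-programs rise from baseline
  2.0 to 2.0·2³; down-programs start at 2.0·2³ and fall to baseline.
  The effect size of 3.0 log₂ units on a baseline of 2.0 was chosen so
  that a fully switched program clears the |log₂FC| ≥ 1.5 inclusion
  rule in *both* directions under the c = 1 pseudocount, which bounds
  down-regulation fold changes at low abundance. Up/down switch points
  are paired at five evenly spaced stages so total stem-cell read mass
  stays balanced along m.
* **Mass balance**: every non-stem type receives "ballast" features
  (50 peaks, 25 genes per type) sized to equalise expected per-type
  read mass. Without this, library normalisation of pseudo-bulk
  aggregates converts composition shifts into spurious correlations
  among unrelated flat features, which contaminates peak–gene link
  calling — a real compositional artifact, deliberately removed here so
  the planted links are the only true couplings.
* **Weak peaks**: 300 peaks with a 0.8-log₂ effect switching at
  m = 0.5 — directional but below the significance rule. These supply
  the non-differential-but-shifted stratum the sign test detects.
* **Motifs**: 30 motifs; each program has one driver motif carried by
  members with probability 0.8 against a background rate of 0.05.
* **Probes**: 1,000 probes — 300 on program peaks, 300 on weak peaks
  (class anti-correlated with the peak's accessibility direction with
  probability 0.99, matching the near-perfect concordance the analysis
  is designed to detect; discordant otherwise), 200 class-none probes
  on marker peaks, 200 intergenic. A `probe_null` flag assigns classes
  independently of direction for null-calibration runs.
* **β values**: hyper probes mean 0.25 (normal) vs 0.65 (tumor), hypo
  mirrored, none 0.45/0.45; Beta-distributed noise with concentration
  150 (sd ≈ 0.04); 20 samples per group — enough for the asymptotic
  rank-sum test to reach the 1e-5 cutoff under full separation (a real
  methylation array cohort is far larger; the cutoff is scale-bound).
* **Counts**: negative binomial (gamma–Poisson) with dispersion 0.5
  and log-normal per-cell depth factors (σ = 0.35).
* **QC covariates** are simulated per cell with configurable failure
  fractions per rule (5% TSS, 5% fragments, 2+2% gene bounds, 2%
  depth, 4% mitochondrial), independent of the count matrices.
* **Doublets** are optional (default off): a chosen fraction of cells
  is replaced by the sum of two cells' counts and flagged in truth.

### What the generator does and does not emulate

It reproduces the *statistical* structure the pipeline relies on:
overdispersed sparse counts, depth variation, type-specific features,
staggered stem-cell programs, motif enrichment, probe anti-correlation.
It does not emulate fragment-level data, realistic genome coordinates,
batch/chemistry effects, doublet-driven cluster artifacts, CCA-style
cross-assay misalignment, or biological covariance between cell types.
Passing recovery tests therefore demonstrates correctness of the
machinery under the stated model, not robustness to every artifact of
real single-cell data.

## Problem sizes used in validation

Parameter-recovery checks run on the default 40-sample × 500-cell
cohort (continuum recovery, 10 seeds). Supporting checks use reduced
cohorts with the same structure — a 16-sample × 200-cell `small`
configuration for projection, methylation and calibration runs, a
30-sample × 300-cell configuration with all ten programs for program
and motif recovery, and a 40-sample × 200-cell × 1,500-peak
configuration for the program-free control — sizes chosen to keep a
full validation run on a single CPU in the minutes range while leaving
each property's signal-to-noise regime intact.

## Known limitations

* The hurdle test approximates, but is not, a mixed-model single-cell
  expression test; detection and continuous parts are combined as
  independent, which is mildly anticonservative when they correlate.
* The rank-sum normal approximation is conservative for extremely
  sparse features; features with no signal at all in the compared
  populations yield p = 1 by construction and should be excluded from
  calibration summaries.
* The principal curve assumes the sample scatter is one-dimensional in
  PC1–PC2; strongly branched cohorts would need a tree-structured
  generalisation.
* Motif deviations match backgrounds on accessibility only; with real
  sequence, GC matching should be added.
* `drop_sample_correlated_dims` tests dimensions one at a time;
  combinations of dimensions jointly encoding batch are not detected.
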