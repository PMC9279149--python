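# polypcontinuum

Single-cell analysis of malignant transformation in colon polyps:
ordering samples along a **malignancy continuum** from chromatin
accessibility (scATAC-seq) and transcriptome (snRNA-seq) profiles.

Colorectal cancer follows a stereotyped progression from normal
epithelium through precancerous adenomas to carcinoma, typically
initiated by *APC* loss and WNT-pathway activation. Along this
transition an increasing fraction of epithelial cells occupies a
stem-like state, and those stem-like cells accumulate regulatory changes
— groups of peaks and genes that switch on or off at characteristic
stages. `polypcontinuum` implements the computational machinery for
charting that progression from multi-sample single-cell data, and ships
a synthetic cohort generator with planted ground truth so that every
stage of the pipeline is testable by parameter recovery, without any
sequencing data.

It is aimed at computational biologists analysing multi-sample
scATAC-seq / snRNA-seq cohorts of premalignant lesions, and at method
developers who need a fully specified, seed-reproducible reference
implementation of this class of analysis.

## What it computes

**Reference projection.** A normal-epithelium reference subspace is
built by iterative LSI: repeated rounds of variable-feature selection,
TF–IDF weighting (tf = count / cell total; idf = ln(1 + N/nᵢ)),
truncated SVD, and SNN-graph clustering, re-selecting features on
cluster-aggregated log-CPM profiles. The fitted transform (feature
list, row mask, IDF vector, right singular vectors V) is frozen; query
cells x are projected as tfidf(x)ᵀ·V into exactly the reference
coordinates and labelled by the modal annotation of their 25 nearest
reference neighbours. Embedding dimensions with high point-biserial
correlation to sample of origin can be dropped.

**Per-sample differentials.** For each diseased sample, stem-like cells
are tested feature-by-feature against a pooled background (normal or
unaffected stem cells) with a self-implemented Wilcoxon rank-sum test
(exact enumeration at small n, tie- and continuity-corrected normal
approximation otherwise) or a two-part hurdle test for sparse
expression; log₂ fold changes use pseudocounted depth-normalised means,
and Benjamini–Hochberg adjustment is applied within each sample.

**Continuum ordering.** Features significant in ≥ 2 samples
(FDR ≤ 0.05, |log₂FC| ≥ 1.5 for peaks; ≥ 0.5 for genes) form a
samples × features log₂FC matrix. Its first two principal components
are fitted with a Hastie–Stuetzle principal curve; each sample receives
the arc-length coordinate of its nearest point on the curve, oriented so
normal-like samples sit at the low end. Cell-type composition is then
related to position (rank-sum tests with Bonferroni correction across
states; Spearman trends along the continuum).

**Programs and motifs.** Recurrently differential peaks are k-means
clustered (k = 10 by default, Lloyd + k-means++, multiple restarts)
into stage-specific programs; each program is tested for
transcription-factor motif enrichment with the upper-tail
hypergeometric test, and chromVAR-style per-cell motif deviation
z-scores are computed against accessibility-matched background peak
sets. Peak-to-gene links are called by correlating pseudo-bulk
aggregate accessibility with proximal gene expression (≤ 250 kb), and
module (stemness) scores use abundance-matched control features.

**Methylation concordance.** Differentially methylated probes
(rank-sum p ≤ 1e-5 and |Δβ| ≥ 0.25) are overlapped with the peak set;
probe-bearing peaks are cross-tabulated by program direction
(up / down / non-differential) against probe class (hypo / hyper /
none), and an exact binomial sign test quantifies the residual
directional shift of non-differential peaks.

## Worked example

```python
from scipy.stats import spearmanr
from polypcontinuum import SimConfig, generate_cohort
from polypcontinuum.pipeline import (
    PipelineParams, run_continuum_pipeline, unit_malignancy,
)

cohort = generate_cohort(SimConfig.small(seed=1))   # 16 samples x 200 cells
result = run_continuum_pipeline(
    cohort, PipelineParams(min_cells=20, n_program_clusters=4)
)
positions = result.continuum.positions.sort_values()
print(f"{len(result.features)} recurrent differential peaks")
print(positions.round(2).to_string())
m = unit_malignancy(cohort.truth.malignancy, cohort.samples).loc[positions.index]
print(f"Spearman(position, latent malignancy) = "
      f"{spearmanr(positions.to_numpy(), m.to_numpy()).statistic:.3f}")
```

prints

```
42 recurrent differential peaks
donor_4_transverse    -0.00
donor_3_ascending      0.08
donor_5_descending     0.52
polyp_0                3.51
polyp_1               12.87
polyp_3               14.01
polyp_5               14.06
polyp_2               14.15
polyp_4               14.31
polyp_6               14.70
polyp_7               18.51
CRC_0                 19.39
CRC_1                 21.77
Spearman(position, latent malignancy) = 0.967
```

The three merged unaffected units sit at the start of the continuum,
the polyps spread along it in order of their latent malignancy, and the
two carcinomas sit at the end; the recovered arc-length positions
correlate 0.97 with the planted truth.

Every stage is also scriptable from the shell via the `polypcontinuum`
executable (`simulate`, `qc`, `fit-reference`, `project`,
`differential`, `continuum`, `programs`, `methylation`); run
`polypcontinuum --help`.

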