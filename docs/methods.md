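# Methods notes

## Model and assumptions

SPSNet tests, for each candidate subnetwork S, the null hypothesis that S
is irrelevant to the difference between phenotypes C and ¬C, against
per-patient score differences

SPS_Score(p) = Σ_g F(g,p)·β(g, Q(S,¬C)) − Σ_g F(g,p)·β(g, Q(S,C)),

whose mean is examined with a two-sided one-sample t-test (df = n − 1).
The key assumption is that every hidden subpopulation has at least one
subnetwork in which it ranks highest within its phenotype, and that the
smallest subpopulation of interest has at least x members. When a
subpopulation is smaller than x, its representative sets are contaminated
by other patients and sensitivity degrades — this is a property of the
method, not of the implementation.

The class-label permutation null of the whole-phenotype predecessor is
kept only for pfsnet mode (`pfsnet_permutation_pvalues`): with x = 10
representatives per side, too few distinct label permutations move the
statistic for a permutation null to be meaningful in spsnet mode.

### Which patients enter the t-test

The score difference is defined for every patient, so by default the test
population is C ∪ ¬C (df = n_C + n_¬C − 1). `test_population={"all",
"control","test"}` restricts it for comparability with per-phenotype
testing in the method's lineage.

### Candidate filter

A subnetwork is tested when at least `min_genes` (5) genes reach β ≥
`min_beta` (0.5, boundary inclusive) on **either** side; the reported
direction comes from the sign of the mean score difference. Either-side
admission covers subnetworks highly expressed in either phenotype. This
filter carries most of the specificity: under the null, representative
selection produces small but coherent β differences whose one-sample t can
be large, and it is the β ≥ 0.5-in-5-genes requirement that removes such
candidates (see the worked example in the README).

## Parameters

| parameter | default | meaning |
|---|---|---|
| θ₁, θ₂ | 0.05, 0.15 | GFS top-quantile fractions: top 5% of a sample's genes score 1, below top 15% score 0, linear in between |
| x | 10 | representative patients per side (5 recommended when groups have very few samples) |
| min_genes, min_beta | 5, 0.5 | candidate filter |
| α_sig | 0.05 | significance threshold; optional Benjamini–Hochberg adjustment via `adjust=True` |
| min_size | 5 | smallest ego subnetwork kept |

GFS quantile convention: q(g) = (rank_from_top − 1)/(n_genes − 1) with
average ranks on ties; membership uses q ≤ θ₁ (closed) and q > θ₂ (open),
so a gene exactly at θ₂ scores 0 and one exactly at θ₁ scores 1. Ties get
identical scores, making the transform independent of input row order.
Constant samples are rejected (ranks undefined).

Representative selection breaks vote ties by lexicographically smaller
sample id, making runs deterministic across platforms. With x ≥ phenotype
size the representative set is the whole phenotype and spsnet mode is
bitwise identical to pfsnet mode.

## Subnetwork generation

Candidates are per-(pathway, gene) ego networks; identical gene sets from
different seeds or pathways are deliberately kept distinct, so the count
over a graph equals |{(pathway, gene): deg(gene)+1 ≥ min_size}|. Gene
identifiers are matched to the expression matrix exactly after whitespace
trimming and case-folding; unmatched genes are dropped per subnetwork with
the size filter re-applied. Edge-list parsing ships three tolerant
dialects (generic, PathwayAPI-style, KEGG-style with organism-prefix
stripping); self-loops are dropped and undirected duplicates merged.
`spsnet.datasets.synthetic_pathway_collection` provides a synthetic
collection at curated-database scale (300 pathways, 5654 filtered ego
subnetworks) used by tests and examples.

## Simulation framework

`generate_base_cohort` draws a homogeneous cohort: per-gene level
μ_g ~ N(6, 0.25²) on the log scale, i.i.d. samples with within-gene
log-noise SD 0.12, genes independent. Because scoring is rank-based
within samples, only the interplay between the between-gene spread and
the injected fold changes matters. The defaults are calibrated so the
multiplier ladder {1.2, 1.5, 1.8, 2.0, 3.0} straddles the GFS detection
band: a 1.2-fold change rarely lifts a gene into the top 15% of a sample
while a 3-fold change almost always saturates its fuzzy score. In this
regime the framework reproduces the method's characteristic behaviour —
whole-phenotype scoring detects single-subtype subnetworks only when the
subtype share α is large (≈ 0.05 → 0.19 median sensitivity across
α = 0.2 → 0.5 at 240 samples), the subpopulation-sensitive mode is
comparatively flat (≈ 0.60 → 0.66), and null subnetworks stay far below
the 5% bound.

Injection follows the benchmark design: equal-half N1/N2 split (odd
remainder to N1), N21 = round(α·|N2|), two independent 10% gene
subsamples, per-gene multiplier applied on the raw scale in the
respective subtype. G1 is the full first subsample (including the G12
overlap, whose size is hypergeometric, ≈ 1% of genes); G0 contributes
four times the genes actually chunked for G1. Benchmark subnetworks are
consecutive 7-gene chunks of the leaf-ordered dendrogram (correlation
distance of log expression, average linkage), with the trailing remainder
discarded, so counts are floor(floor(0.1·n)/7) per DE category — 292 and
1168 for a 20,502-gene universe, 197 and 788 for 13,801 genes. Chunks are
clustered on the full post-injection matrix: the induced differential
expression is part of the expression pattern being emulated, and
clustering on unperturbed samples alone would scatter the fold-change
structure across chunks. Optimal leaf ordering is applied up to 1500
genes (it is cubic in the gene count); beyond that the plain dendrogram
order is used, which does not change chunk counts.

What the generator does **not** emulate: heavy-tailed real rank
distributions, co-expression modules in the null background, count noise,
and platform effects. Passing benchmarks therefore demonstrate the
method's selectivity and calibration under clean rank structure, not
performance on any particular real cohort.

## Experiment scales

Experiments default to cohort sizes typical of the large benchmark
cohorts (13,801 genes, ~240 samples, 100 iterations, 50 repetitions per
subsample size). The shipped tests and the acceptance script run reduced
configurations chosen for quick turnaround — e.g. 4000 genes × 240
samples × 20 iterations for the α-contrast check and 10,000 genes × 120
samples × 5 cohorts for the false-positive benchmark — which the
measurements above show are already stable.

## Evaluation metrics

The feature matrix collects per-patient score differences of significant
subnetworks (columns keyed by subnetwork id). PCA is an SVD of the
mean-centred (not variance-scaled — scores share a scale) matrix;
silhouettes use Euclidean distance on a chosen set of components, by
default the first three; an explicit component list (e.g. `pcs=[2, 3]`)
supports dropping a batch-dominated PC1. Purity is the majority-label
fraction in a subnetwork's representative set (ties to the
lexicographically smallest label); enrichment of high purity uses a 1-df
chi-squared goodness-of-fit of the (> 0.75 strictly) high/low split
against 50/50. Jaccard reproducibility compares significant subnetwork
*ids* (pathway + seed gene), not gene-set equality, across runs.

## Degenerate inputs and numerical choices

* Zero-variance score vectors: all-zero → t = 0, p = 1 (maximally null);
  constant non-zero → p = 0 with a RuntimeWarning.
* Empty significant set → `feature_matrix` raises; Jaccard of two empty
  sets is defined as 0 with a warning.
* x larger than a phenotype clamps to the phenotype with a warning;
  phenotypes below 3 samples are rejected (no t-test).
* Expression round-trips are exact: writes use `repr` and reads parse
  with Python `float`.

## Known limitations

* Subnetworks are fragmented per-gene neighbourhoods; no attempt is made
  to merge overlapping candidates or to estimate the number of
  subpopulations.
* No multiple-testing correction by default (the conventional 0.05
  threshold is the method's operating point); BH adjustment is optional.
* The t null treats patients as exchangeable within the test population;
  strong within-phenotype correlation structure (e.g. repeated measures)
  violates this.
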