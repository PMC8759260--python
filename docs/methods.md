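# Methods

## The model under study

An epigenetic clock is a linear functional of a methylation profile:
`score(x) = β₀ + Σᵢ wᵢ xᵢ` over a fixed CpG panel, followed by one of
three transforms:

* **identity** — the score is the predicted age in years;
* **piecewise log-linear** ("adult-age anchored") — ages below an
  anchor `a` (default 20 y) live on a log scale, ages above on a linear
  one: `F(age) = log(age+1) − log(a+1)` for `age ≤ a`, else
  `(age − a)/(a+1)`; predictions invert `F`.  `F` is strictly
  increasing and continuous at 0, so the inverse is well defined;
* **per-sample standardization** — each sample's beta vector is
  standardized to mean 0, SD 1 across *all* supplied CpGs (population
  SD, divisor n) before scoring.  This makes predictions invariant to
  per-sample additive shifts of the whole methylome.

The package's central hypothesis-testing machinery asks how methylation
at clock CpGs relates to gene expression genome-wide, on the premise
that shifts in immune cell composition (naive vs activated T and NK
cells) drive both.

## Synthetic whole-blood cohort

Because the analyses are meaningless without data in which the truth is
known, the generator is first-class code.  It emulates:

* **Composition.** Nine compartments: naive T, activated T, canonical
  NK, adaptive NK, B, monocytes, neutrophils, eosinophils, basophils.
  The neutrophil share is Beta-distributed (mean 0.55); a small Beta
  share of the remainder goes to monocytes/eosinophils/basophils; the
  rest is lymphocytes, split T/NK/B by a Dirichlet.  Because the
  neutrophil share is the dominant source of compositional variance,
  neutrophil and lymphocyte percentages are strongly anticorrelated
  (r ≈ −0.96 at the defaults), the collinearity that motivates dropping
  neutrophils from the regression covariates.
* **Immuno-senescence.** The activated share of T cells is logistic in
  age: `logit(p) = slope·(age − 52) + ε`, slope 0.07 logit/yr, with
  per-sample logit noise (SD 0.5).  The noise encodes that same-age
  individuals differ substantially in immune history — precisely the
  heterogeneity the association scan must exploit, since age itself is
  a covariate.  The adaptive-NK share rises *linearly* with age
  (0.006/yr from 0.10 at age 18).  Keeping one linear and one logistic
  activation axis makes chronological age an exact linear functional of
  the noise-free methylome (the beta columns span {1, σ(age), age}), so
  a least-squares clock on a zero-noise cohort reproduces age to
  machine precision — the pipeline's strongest self-check.
* **Methylation.** Per-compartment reference beta profiles: "cluster 1"
  CpGs are hypermethylated in naive compartments and hypomethylated in
  activated ones (independent T-axis and NK-axis gaps, each ≥ 0.45),
  "cluster 2" CpGs the mirror image, "neutral" CpGs identical across
  compartments.  Bulk beta = fraction-weighted mixture + N(0, 0.01),
  truncated to [0, 1].  Truncation (not redrawing) keeps the map
  monotone and cheap.
* **Expression.** Marker-gene log-means are affine in the matching
  aggregate fraction (naive T + canonical NK, or activated T + adaptive
  NK) with slopes U(8, 12) — strong activation markers; null genes are
  flat.  Counts are negative-binomial (dispersion 0.15) around
  exp(log-mean) × log-normal library size (SD 0.2).  45 + 45 markers
  among 300 genes keep signal a minority, so per-CpG empirical-null
  estimation retains a null majority.
* **Nuisance structure.** Additive per-level batch shifts on both
  modalities (bisulphite plate, array position, flowcell); one latent
  expression confounder loading on a random half of the genes; optional
  Hardy–Weinberg genotypes with additive cis-meQTL/trans-eQTL effects;
  optional technical replicates (fresh measurement noise around the
  same mixture).
* **Scale.** Defaults: 500 samples, ages uniform 18–87 y, 200 clock
  CpGs (70/70/60), 300 genes.  Chosen once as a desk-scale cohort that
  the full scan, permutation null and clustering traverse in seconds.

What the generator does **not** emulate: probe-level array artifacts,
genomic autocorrelation of methylation, realistic LD, read-level
RNA-seq, or cohort-specific age distributions.  Passing tests therefore
demonstrate that the *machinery* is correct and calibrated under a
plausible compositional model — not that real cohorts will show effects
of any particular size.

## Association scan

Expression preprocessing: protein-coding autosomal genes with median
raw count strictly > 1; log₂-CPM with a (count + 0.5)/(library + 1)
offset; per-gene rank-inverse-normal transform `Φ⁻¹((r − 0.5)/n)` with
average ranks for ties.  The RIN step makes the per-gene response
Gaussian by construction, so OLS t statistics are well calibrated.

Design: intercept, cohort, age, sex, basophil/eosinophil/lymphocyte/
monocyte percentages (neutrophils excluded for collinearity), dummy-
coded technical batches with levels under 5 observations pooled, plus
five latent factors.  Rank deficiency is a hard error naming the
collinear columns.

**Latent factors.** Factors are the top left singular vectors of the
expression residuals after removing known covariates — with one
protection step: the residuals are first projected off the top 10
*within-design* principal directions of the methylation matrix.
Without protection, the dominant residual direction is the activation
axis itself (it drives half the marker transcriptome), the first factor
reproduces it, and conditioning on that factor regresses away the very
signal under study.  Protected factors can absorb technical and latent
confounding orthogonal to the measured methylome but cannot absorb
anything a methylation predictor could explain.  Factor signs are fixed
by making each factor's largest-magnitude gene loading positive, so
results are reproducible across runs and BLAS builds.

**Shared factorization.** For each scan the design (with factors) is
QR-factorized once; methylation and expression are both residualized
against it, and the per-pair t statistics follow from three matrix
products (Frisch–Waugh–Lovell).  Perfect fits (zero residual) are
flagged ±∞ rather than silently clipped.  The result is identical to
gene-by-gene OLS (tested against statsmodels to 1e-8) at a tiny
fraction of the cost.

**Empirical-null correction.** Each CpG's genome-wide t statistics are
converted to z scores (through the exact t CDF, stable in the tails)
and recalibrated by the location/scale of their central mass.  The
estimator is truncated-normal central matching: starting from
(median, 1.4826·MAD), fit a Gaussian by maximum likelihood to the
points inside μ ± 1.96σ (moment fixed-point iteration), refreshing the
window from the updated estimate (3 outer rounds).  Genuine signal
lives in the tails, outside the window, so the estimate tracks the null
component; on a pure standard-normal sample the estimator is consistent
(a mixture-EM alternative was rejected because its flank components
absorb the null's own tails and bias the scale down by 5–25% depending
on sample size).  Corrected z = (z − μ̂)/max(σ̂, 1): inflation and bias
are removed, but an *estimated deflation* is never allowed to sharpen
statistics — at ~300 statistics per CpG the scale estimate has ~4%
sampling noise, and sharpening on it makes a genome-wide Bonferroni
screen anti-conservative.  The raw σ̂ is always reported; symmetric
correction is available via `inflation_floor=0`.  A median/MAD fallback
covers degenerate fits.

**Distance classes.** Distance is the bp gap between the CpG point
(1-based) and the nearest gene edge, 0 inside the gene (gene-body, not
TSS, since only a CpG-gene distance is defined).  gap ≤ 100 kb → cis;
different chromosome or gap > 5 Mb → trans; otherwise excluded.
Boundary conventions: exactly 100,000 is cis, exactly 5,000,000 is
excluded.  Chromosome names are matched strictly; mixing `chr1` and `1`
styles is an error, not a silent non-match.  Bonferroni families are
the tested pair counts within cis and trans separately.

**Core set.** A gene enters when its Bonferroni-significant trans-CpG
count within any single clock reaches ⌈0.05 · clock size⌉ (4/18/20/26
for panels of 71/353/391/514 CpGs); a CpG enters with ≥ 10 significant
trans-genes.

**Permutation null.** Methylation sample identifiers are shuffled —
covariates and latent factors stay with the expression — and the full
trans analysis (including per-CpG null correction) is recounted.  The
empirical p uses +1 smoothing: `p = (1 + #{perm ≥ obs})/(1 + n_perm)`.

## Clustering and cell-type attribution

The core CpG × gene matrix of corrected t statistics, with entries that
are not Bonferroni-significant trans associations zeroed, is clustered
hierarchically on rows and columns independently (Euclidean distance,
complete linkage — exposed as a parameter since only the metric is
canonical) and cut at k = 2.  An all-constant matrix has no valid
2-split and is an error.  Cluster labels are arbitrary 1/2; tests map
them to ground truth via the adjusted Rand index.

Sorted-cell profiles are min-max normalized per feature across cell
types (`(X − min)/max(X − min)`); constant profiles are emitted as
missing rather than divided by zero.  Cluster membership is tested
naive-vs-activated with Welch (unequal-variance) t tests on per-member
medians.  Paired clock-age differences use one naive and one activated
sample per donor per lineage; the summary is the median per-donor
difference with a paired t test (significance stars at 0.05/0.01).

The sorted-cell generator injects a target clock-age offset exactly:
the activated profile is the naive profile shifted along the
activated-minus-naive reference direction, scaled so the chosen clock's
score difference equals the requested offset (converted through the
clock's transform at a reference age of 55 y).  Donor random effects
are shared within a pair and cancel in the paired differences.  Clocks
other than the injection clock will generally report different deltas —
pure sorted-cell profiles are far outside a bulk-trained clock's input
distribution, and the nonlinear transforms compress extrapolated
scores; this mirrors the wide between-clock spread of naive/activated
deltas seen in real sorted-cell data.

## QTL crosscheck

Association pairs are flagged when a single SNP ID appears as cis-meQTL
for the CpG and trans-eQTL for the gene (direction `cpg_first`), or as
cis-eQTL for the gene and trans-meQTL for the CpG (`gene_first`).
Matching is by SNP identifier only — the check is a catalog lookup, not
a colocalization analysis — and supplied tables are taken as already
significance-thresholded.

## Reproducibility

One global seed feeds every stage through a stable per-stage hash
(CRC32 of the stage name, kept below 2³¹), so stages rerun
independently yet deterministically; identical configs produce
byte-identical outputs, and the run summary is stamped with a hash of
the scientific configuration (output paths excluded).

## Known limitations

* The latent-factor protection assumes confounders of interest are
  (approximately) orthogonal to the measured methylome; a confounder
  that genuinely shifts both methylation and expression will be
  attributed to methylation, not removed.
* The empirical-null floor makes the correction one-sided by default;
  analyses that need symmetric recalibration must opt in.
* Cell-type attribution accepts any user taxonomy; no harmonization of
  external sorted-cell datasets is attempted.
* The generator's effect sizes are set for clear signal at desk scale
  and are tunable; they are not calibrated to any particular cohort's
  variance decomposition, which published resources do not report.
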