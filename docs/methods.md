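# Methods

This note documents the models, procedures and numerical choices behind
`gbmnoise`: what each stage computes, what the synthetic-data generator
emulates (and what it does not), and where the design was genuinely open.

## 1. Gene-body methylation classification

For each gene, methylated and total read calls are summed over every covered
cytosine inside the transcribed region (transcription start to termination,
exons and introns alike; an exon-only mode exists for the robustness check),
separately for the CG, CHG and CHH sequence contexts and pooling calls from
both strands at a position.  The per-context level k/n is compared with the
genomic average level via the upper tail of a binomial distribution,
P_c = P(X >= k), X ~ Binomial(n, p̄_c).

Decision rules, applied with a two-sided significance level alpha = 0.05:

1. P_CHG < alpha or P_CHH < alpha → *highly methylated non-gbM* (excluded
   from gbM/unmethylated contrasts);
2. otherwise P_CG < alpha → *gbM*;
3. otherwise P_CG > 1 − alpha → *unmethylated*;
4. otherwise → *ambiguous*.

A gene keeps a final gbM or unmethylated label only when both replicate
methylomes agree on it.

Numerical and procedural choices:

* **Background level.**  The genomic average p̄_c is the unweighted mean of
  per-gene levels over covered genes.  The read-pooled alternative
  (Σk/Σn, available as `method="pooled"`) weights genes by call count;
  because gbM genes are systematically long, pooling drags the CG
  background toward the gbM rate and erodes the classification margin.  The
  two coincide under equal coverage.
* **Uncovered contexts** get P = 1: with no calls a context cannot be
  significantly *higher* than background.  A corollary is that a gene with
  zero CG coverage would classify as unmethylated; callers working with
  sparse data should apply a coverage filter first (the generator always
  covers genes).
* **No multiple-testing correction** on the per-gene binomial P values; the
  raw 0.05/0.95 thresholds are the procedure's definition, not inference.
* The upper tail includes the observed count (P(X ≥ k), not P(X > k)), so
  the gbM and unmethylated thresholds are symmetric.
* Tails are computed through the binomial survival function, stable for n
  up to at least 10⁶ calls.

## 2. Expression noise and consistency

From a genes × cells FPKM matrix (20 cells by default), genes with
log₂(FPKM + 1) > 1.5 in at least one cell are retained.  Per gene, μ is the
arithmetic mean over all cells (zeros included) and σ² the sample (n−1)
variance.  Because variance scales with expression, the noise statistic F*
divides the observed variance by the variance expected at the gene's mean:
the expectation comes from the least-squares fit of log σ² on powers of
log μ, and F* = σ² / exp(fit).  The polynomial degree is the smallest
d ≤ 6 for which Kendall's rank correlation between F*(d) and μ is
non-significant at 0.05; if no degree decorrelates, the maximum degree is
returned with a warning flag.  By construction the geometric mean of F*
over the fitted genes is exactly 1.

F′ is the plain coefficient of variation (sample sd / mean), and expression
consistency is the number of cells with FPKM strictly > 0 (an integer in
0..n_cells).

Choices: the filter's log base (unstated in the defining formula) defaults
to 2 and is configurable; genes with σ² = 0 are excluded from the trend fit
and keep an undefined F*; the degree search runs forward from 1; Kendall τ
is tie-corrected (τ-b), with exact enumeration P for n ≤ 8 without ties and
the normal approximation otherwise.

## 3. Intron retention

Genes whose spans overlap another gene on either strand are removed (both
members of a pair).  Introns are the parts of the span covered by neither
exon nor UTR; the modified annotation emits them as features typed "exon"
so that exon-counting tools count intronic reads directly.  Reads are
counted in two independent passes — against the intron set and against the
annotated exon/UTR set — so a junction-spanning read increments both, with
a configurable minimum overlap (default 1 bp).  Counts are pooled across
cells; intron FPKM uses the summed intron length, total FPKM the gene
length, both normalised by the pooled library size, and genes must pass the
same log(total FPKM + 1) > 1.5 filter as the noise analysis.  Counting is
vectorised over sorted disjoint intervals and is verified in the tests
against an all-pairs overlap oracle.

## 4. Covariate models

Group contrasts use the two-sided Mann–Whitney U test (exact null for the
smaller sample ≤ 8 without ties) with Benjamini–Hochberg adjustment across
features.  The ANCOVA layer standardises every predictor — binary ones
included — by sample mean and standard deviation; the response keeps its
scale, so coefficients are per-standard-deviation effects.

* **Transform selection** is a greedy single pass in declared predictor
  order: a continuous predictor is logged iff logging it increases the full
  additive model's R² (log(x+1) recorded when zeros are present; variables
  with negative values are never logged).  When the response is F*, the
  mean expression level is exempt from logging, so no correlation between
  F* and the mean is re-introduced.
* **Collinearity** is screened with the variance inflation factor,
  vif_j = 1/(1 − R²_j); every predictor must satisfy √vif < 2, and the
  worst offender is dropped iteratively until all do.  Perfectly collinear
  columns are removed first (the vif itself is undefined there).
* **ANCOVA tables** report per-term Type II sums of squares (each term
  adjusted for all others) with F tests, matching the convention of the R
  "car" package.
* **BIC model averaging** enumerates all 2^p predictor subsets (p ≤ 20),
  weights model m by exp(−ΔBIC_m/2), and averages coefficients over all
  models with absent terms contributing zero ("full" averaging).  A
  predictor's relative importance is the summed weight of models containing
  it; the best model minimises BIC.  BIC = n·ln(RSS/n) + k·ln(n) with k
  counting the intercept — the dropped constant cancels in every ΔBIC.  The
  enumeration runs on precomputed Gram matrices (X'X, X'y), so its cost is
  independent of n; the tests cross-check it against per-subset OLS fits.
* **Principal-component regression** regresses the response on the gbM
  indicator plus all principal components of the other standardised
  features; since the components span the feature space, the gbM term is
  tested net of every feature while confining collinearity to one block.
  Its type-I error for a null gbM effect is calibrated in the tests.
* **The gbM-prediction model** treats the 0/1 gbM indicator as an ordinary
  least-squares response (not logistic), vif-screens the candidate features
  first, then model-averages.

## 5. The synthetic-data generator

The generator emulates the statistical regime the analysis assumes, with
planted ground truth for every stage.  Defaults encode the study
conditions: 20 cells, ~20× methylome coverage, a census of 35% gbM, 45%
unmethylated, 12% highly methylated, 8% ambiguous genes.

* **Genome.**  2000 genes by default, lognormal lengths (median ≈ 2 kb),
  1–12 exons with terminal UTRs, 5 chromosomes, and a configurable fraction
  (default 5%) of overlapping gene pairs to exercise the overlap filter.
* **Methylomes.**  Cytosine sites are placed at context-specific densities;
  per site and replicate, coverage is Poisson(20) and methylated calls are
  Binomial(coverage, rate) with class-specific rates (gbM: CG 0.25 only;
  highly methylated: elevated CHG/CHH too; unmethylated: 0.02 everywhere).
  Ambiguous genes draw a per-gene CG rate uniformly from [0.10, 0.22],
  straddling the genomic background — their labels are deliberately
  knife-edge.
* **Covariates.**  Gene classes are assigned by thresholding a latent
  correlated with log gene length; the other features (lethality, Ka/Ks,
  co-expression module size, α/βγ-WGD retention, expression breadth, tandem
  duplication) derive from one Gaussian copula conditioned on that latent.
  Planted gbM–feature correlations are specified on the indicator scale
  and converted through the point-biserial factor of the thresholding;
  correlations involving binarised features are therefore approximate.
  Default signs follow the observed contrasts (gbM genes longer, broader,
  more lethal, larger modules, less often duplicated).
* **Expression.**  Per gene, a class-specific lognormal mean M (gbM genes
  intermediate and narrow); log variance follows the configured cubic in
  log M plus the gene's log noise multiplier.  Multipliers are driven by
  covariates (length, breadth, α-WGD, plus a direct gbM term that defaults
  to **zero**) or by a planted high-noise subset.  Cell values are
  lognormal.
* **Detection / consistency.**  Each gene has a per-cell detection
  probability π from a logistic model in expression, length, noise and a
  direct gbM term (default +0.6, the planted consistency effect).  Zeros
  are *moment-preserving*: a cell is zero with probability 1 − π and the
  nonzero draws are compensated (mean M/π, variance adjusted) so that the
  gene's marginal mean and variance equal (M, V) regardless of π.  This is
  the zero-inflation construction under which a direct consistency effect
  leaves measured noise untouched to first order; simple censoring or
  dropout-at-random provably leaks detection effects into F* at these
  sample sizes.  Feasibility requires π ≥ M²/(M²+V); requested values below
  that bound are clamped (a requested π of exactly 0 silences the gene).
* **Reads.**  Per cell, read counts are multinomial over genes with weights
  FPKM × length; each 50-bp read falls entirely inside an intron with the
  gene's class-specific retention fraction (gbM 0.05 vs unmethylated 0.10),
  else inside an exon.

### Named scenarios and what passing them shows

`gbmnoise.scenarios` freezes one configuration per validation question
(classifier recovery; region-mode agreement; multiplier recovery; the
headline direct-vs-indirect regime).  Two deliberate departures from the
default configuration:

* The **agreement** scenario omits the ambiguous class and overlapping
  pairs: knife-edge genes flip labels under *any* region choice and
  overlapping genes feed different neighbour signal into the two region
  summaries, so both measure something other than region sensitivity.
* The **multiplier-recovery and headline** scenarios use a
  moderate-dispersion variance trend (σ²/μ² < 1).  With only 20 cells, the
  sample variance of a CV ≈ 3 lognormal is biased far below the truth and
  the bias grows with the underlying variance, so planted multipliers are
  attenuated (a planted 2× subset measures ≈ 1.3×) under the heavy default
  trend.  The default trend is kept heavy because it matches the scale of
  observed single-cell coefficients of variation; the attenuation is a
  genuine limitation of variance-ratio noise estimators at this cell
  count, not of the implementation.

What the generator does **not** emulate: read-level sequencing error, UMIs,
isoform structure, cell-type heterogeneity, spatial methylation profiles
within genes (methylation is uniform within a gene), or dependence between
intron retention and expression level beyond read-depth scaling.  Passing
the planted-recovery tests therefore shows the estimators and decision
rules behave as designed under the assumed regime; it does not certify
behaviour under real-data artefacts outside that regime.

## 6. Determinism and problem sizes

All randomness flows from one seed; each stage derives an independent
stream from (seed, stage name), so stages rerun identically in isolation.
The pipeline writes SHA-256 digests of every output into a manifest, and a
rerun with the same configuration reproduces them byte for byte.

Validation problem sizes are chosen to keep each experiment at desk scale
while leaving clear statistical margins: 2000 genes for classifier
questions, 5000 genes and 20 cells for the regression-layer questions,
20 Monte-Carlo seeds for seed-fraction statements, and 200 simulations for
type-I-error calibration.

## 7. Known limitations

* The binomial classification treats calls within a gene as independent;
  real bisulfite data show local correlation, so the synthetic margins are
  optimistic relative to equally sized real data.
* F* from 20 cells is attenuated for high-variance genes (Section 5); group
  *contrasts* in F* remain directionally valid, absolute multipliers do
  not.
* The OLS model of a 0/1 gbM response is a linear-probability model;
  coefficients are interpretable as marginal associations, not
  probabilities.
* With pooled intron counts, per-cell retention heterogeneity is invisible;
  a per-cell mode exists but is off by default.
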