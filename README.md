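# gbmnoise

Does gene-body methylation (gbM) make gene expression quieter, or does it
just travel with gene properties that do?  `gbmnoise` is a Python toolkit
for asking that question the way it must be asked in *Arabidopsis thaliana*
single-cell data: classify genes by gene-body methylation from bisulfite
cytosine counts, quantify per-gene expression noise and expression
consistency across single cells, count reads falling into introns, and then
separate direct gbM effects from covariate-mediated ones with
centred/scaled ANCOVA under BIC model averaging.  A fully seeded
synthetic-data generator with planted ground truth makes every stage
testable without downloading any sequencing data.

It is aimed at researchers in plant epigenomics and regulatory genomics who
want a reusable, tested implementation of this analysis chain — or a
simulation harness to probe when it can and cannot recover planted effects.

## The statistics at the core

**gbM classification.**  For each gene and context c ∈ {CG, CHG, CHH}, the
methylated call count k out of n total calls over the gene body is compared
with the genomic average level p̄_c through the binomial upper tail
P_c = P(X ≥ k), X ~ Binomial(n, p̄_c).  Genes with P_CHG < 0.05 or
P_CHH < 0.05 are *highly methylated non-gbM*; otherwise P_CG < 0.05 → *gbM*,
P_CG > 0.95 → *unmethylated*, else *ambiguous*.  Final gbM/unmethylated
labels require agreement between two replicate methylomes.

**Expression noise.**  With μ and σ² the per-gene mean and sample variance
of FPKM over cells, stochastic expression is F\* = σ² / σ̂²(μ), where
log σ̂² is the lowest-degree polynomial in log μ whose residual ratio is
uncorrelated with μ (Kendall rank test).  F′ is the coefficient of
variation sd/μ, and expression consistency is the number of cells with
FPKM > 0.  Genes enter the analysis if log₂(FPKM+1) > 1.5 in ≥ 1 cell.

**Intron retention.**  For non-overlapping genes, introns are the gene-span
positions in neither exon nor UTR; reads are counted separately against the
intron and exon sets, and intron FPKM = intron reads / (intron kb × library
millions).

**Covariate models.**  Marginal gbM-vs-unmethylated contrasts use two-sided
Mann–Whitney U tests with Benjamini–Hochberg adjustment.  ANCOVA models
standardise predictors, select log transforms by R², require √vif < 2, fit
Type II sums of squares, and average over all predictor subsets with
weights ∝ exp(−ΔBIC/2); a predictor's importance is the summed weight of
models containing it.  A principal-component regression of the response on
gbM plus all PCs of the other features cross-checks robustness to
collinearity.

## Worked example

`examples/04_covariate_models.py` simulates the central regime — gbM has
*no* direct effect on noise but is collinear with gene length, expression
breadth and α-WGD retention (which do drive noise), and has a positive
direct effect on detection — then runs the marginal tests and the averaged
models:

```
Marginal gbM vs unmethylated contrasts (BH-adjusted Mann-Whitney):
                   summary        gbM  unmethylated    P  P_adj
feature
F_star              median     1.2851        1.7899  0.0    0.0
consistency         median    19.0000       18.0000  0.0    0.0
gene_length         median  2699.0000     1666.0000  0.0    0.0
expression_breadth  median    64.0000       56.0000  0.0    0.0

BIC-averaged model for F_star (n = 3270):
  best model: ['gene_length', 'mu', 'alpha_wgd', 'expression_breadth']
  gbM importance: 0.017, averaged coefficient: -0.000

BIC-averaged model for consistency (n = 3270):
  best model: ['gbM', 'gene_length', 'mu', 'alpha_wgd', 'expression_breadth']
  gbM importance: 1.000, averaged coefficient: +0.225
```

Read: gbM genes *are* marginally less noisy (median F\* 1.29 vs 1.79,
adjusted P ≈ 0), but once the covariates enter, gbM drops out of the noise
model entirely (importance 0.017, averaged coefficient ≈ 0) — the marginal
association is inherited from gene length, breadth and α-WGD retention.
For consistency, where a direct effect was planted, gbM stays in the best
model with a positive per-standard-deviation coefficient.  The other
examples cover classification (01), noise quantification (02), intron
counting (03) and the full pipeline with its run report (05).

## Command line

```bash
gbmnoise all --seed 5 --outdir runs/demo     # simulate + all analysis stages
gbmnoise report --outdir runs/demo           # human-readable summary
```

Individual stages (`simulate`, `classify`, `noise`, `introns`, `models`)
run from the same directory layout; all thresholds live in one YAML config
(`SimConfig.to_yaml`) with the analysis defaults.

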