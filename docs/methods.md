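# Methods

## Problem setting and model

`apaenrich` analyses a two-condition, replicated isoform-level expression
design. Each multi-UTR gene carries exactly one short-3′UTR (SU) and one
long-3′UTR (LU) isoform; single-UTR genes carry one isoform. The quantity
of interest is poly(A) site usage,

    PAU = SU / (SU + LU),

a fraction in [0, 1] (the same quantity is exposed as the short-3′UTR
index, SUI). Genes with more than one isoform and a total of at least
3 TPM in one or more samples enter the analysis; per-condition PAU is the
unweighted mean of per-replicate PAUs (a pooled-count mode is available
behind a flag), and dPAU = PAU_B − PAU_A, where condition B is by
convention the state in which short isoforms may be upregulated
(erythroblast-like).

The pipeline distinguishes two routes to higher mRNA output: an increase
in transcript production (SU and LU rise together; gene-level fold change)
and an increase in 3′ end processing at a weak proximal poly(A) site (SU
rises alone; dPAU and SU fold change). Its end point is whether the second
route is preferentially associated with cell type-specific enhancers.

## Statistical tests

**Gene level (NB Wald).** Counts are normalized by median-of-ratios size
factors (geometric-mean reference over genes positive in every sample; no
pseudo-reference fallback). Per gene, a negative-binomial model with
variance μ + αμ² is fitted by the method of moments: α is estimated from
within-condition means and variances, pooled across the two conditions
with (n−1) weights and floored at 1e-8. The Wald statistic is
log2(μ̂_B/μ̂_A) over its delta-method standard error. Because the plug-in
dispersion comes from very few replicates, p-values are referenced against
t(n_A + n_B − 2) rather than the standard normal; with 3+3 replicates this
keeps the null rejection rate at ~0.04–0.05 instead of inflating it. A
condition with zero mean is substituted by half a normalized count
(0.5/n_c) and flagged; all-zero genes get p = 1, log2FC = 0.

**Usage level (beta-binomial LRT).** Conditional on the SU+LU total n, the
SU count k is beta-binomial with usage proportion π and overdispersion ρ
(variance inflation 1 + ρ(n−1)). The test compares H0 (one π for both
conditions) against H1 (π_A, π_B). Two design choices matter:

* *Common overdispersion.* ρ is shared across genes: a single value
  maximizing the summed per-condition profile likelihood over all covered
  genes is selected from a fixed grid (1e-8, then 24 log-spaced points
  from 1e-4 to 0.5), and every gene is tested at that ρ. Re-estimating ρ
  per gene under H0 would let the null fit absorb a real condition
  difference into overdispersion and roughly halve the statistic — the
  standard motivation for shared dispersion in count-based usage tests.
  At each ρ the optimal π solves a concave 1-D problem; it is found by a
  vectorized bracketed Newton iteration (max 100 iterations, scale-aware
  gradient tolerance 1e-8, bisection fallback).
* *Genomic control.* With ~6 observations per gene the LRT statistic
  remains mildly inflated relative to χ²(1). The statistics are rescaled
  by λ = median(LR)/median(χ²(1)), floored at 1; the median is robust to a
  minority of truly changing genes. The correction is skipped below 100
  covered genes, where a median carries no calibration information. After
  this correction the null rejection rate at α = 0.05 is 0.03–0.05 across
  seeds while power on planted dPAU = 0.2 genes remains ≈ 0.95.

Genes with zero SU+LU coverage in every replicate of either condition are
flagged and excluded from the BH correction. BH q-values use the step-up
rule with m equal to the number of non-NA p-values.

## Gene categories

Thresholds (defaults are the printed analysis values): gene FC > 2 with
gene q < 0.10 (gene-up); SU TPM FC > 2 **and** dPAU > 0.1 **and** usage
p < 0.05 **and** usage q < 0.10 (SU-up); SU FC < 2 **and** dPAU < 0.1
**and** usage p > 0.05 (strict control). The SU fold change is computed on
size-factor-rescaled SU TPM condition means with a pseudocount ε = 0.01
TPM in numerator and denominator.

Gene-up genes are subdivided into GENE_AND_SU_UP (SU-up holds) and GENE_UP
(its complement): a purely transcriptional increase raises SU
proportionally, so a SU FC < 2 requirement can never hold for a true
2-fold gene-up gene and would empty the category. Among genes that are not
gene-up, SU_UP requires the SU-up criterion, GENE_NOT_UP requires the
strict control criterion, and genes in between — slight SU upregulation,
neither significant nor clearly absent — are UNCLASSIFIED and excluded
from group comparisons. All inequalities are strict: boundary values
(FC = 2, dPAU = 0.1) are UNCLASSIFIED. The "gene not up" side requires
only failure of the gene-up conjunction, not separate evidence of
no change.

## Enrichment and the stratified control

Per-category enrichment uses Pearson's chi-square on the 2×2 table of
{category vs GENE_NOT_UP} × {enhancer-associated or not}, computed in
closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) with p from χ²(1). No Yates
continuity correction is applied by default (a flag enables it for
sensitivity analysis); a zero margin is an error; odds ratios on zero
off-diagonal cells are flagged. Genes missing from the enhancer map are
treated as not associated and counted in the log.

Because SU upregulation usually drags gene expression up slightly, the
stratified control matches the SU_UP and GENE_NOT_UP groups on gene
log2FC before comparing enhancer fractions: 13 equal-width strata between
the minimum SU-up log2FC and an upper bound of 1, half-open [lo, hi) with
the final interval closed at the upper bound; genes outside the range are
excluded and logged. In each stratum both groups are subsampled without
replacement to the size of the smaller; the pooled matched samples are
compared by chi-square. The default of 3 repeats is configurable; each
repeat uses an independent sub-seed spawned from the run seed and its
sampled gene lists are persisted for audit.

## Reporter calculus

Transcriptional activity is renilla/firefly per replicate (mean ± sd).
CPA activity is the ratio of test-PAS to SV40-PAS activities under the
same promoter/enhancer context (contexts are checked; mismatches are
errors), with uncertainty propagated by the delta method from replicate
standard deviations (a bootstrap is intentionally out of scope). Decay
series are normalized to t = 0 and fitted to y = e^(kt) by nonlinear least
squares initialized from a log-linear regression (SSE tolerance 1e-10);
half-life = ln(0.5)/k; non-negative k is flagged "stable" with infinite
half-life. Screen hits are banded by Welch's two-sided unequal-variance
t-test at α = 0.05: significant, and strong when |mean ΔCPA| > 0.30.

## Synthetic data generator

The generator emulates the analysis-level structure of a stem-vs-
differentiated bulk RNA-seq contrast, not reads: gene totals are
negative-binomial (gamma–Poisson) with mean
baseline_mean × 2^log2FC(condition) × library factor; multi-UTR totals are
split SU/LU by a beta-binomial draw with per-condition PAU (plain binomial
at ρ = 0); TPM treats all isoforms as equal length (1 kb default, lengths
cancel). Every gene draws from its own sub-stream keyed by (seed, gene
index), so datasets are bitwise reproducible independent of iteration
order; the enhancer assignment uses a separate dedicated sub-stream so
flags are independent of the planted-effect draws.

Defaults describe the emulated study conditions: 4000 multi-UTR + 1000
single-UTR genes, 3 replicates per condition, baseline mean 200 counts,
NB dispersion α = 0.05, beta-binomial ρ = 0.01, 15% of multi-UTR genes
with a planted log2FC of 1.5, 10% with a planted dPAU of 0.20 on a
baseline PAU of 0.05, enhancer background rate 0.10 with relative risk 3
for affected genes. The baseline PAU of 0.05 reflects an intrinsically
weak proximal site (well under the ~30% usage ceiling typical of weak
PPAS) and makes the planted shift a five-fold SU change; together with
the depth it is chosen so that planted effects are recoverable with
margin (recovery 0.95–0.98 across seeds), i.e. for test power rather than
to mimic any particular library.

What the generator does **not** emulate: per-gene variation in baseline
expression and dispersion, more than two isoforms per gene, correlated
planted effects, coverage-bias artifacts, or any read-level process.
Passing tests therefore demonstrate correctness of the statistical chain
under its stated model, not performance on real libraries with
heterogeneous depth and dispersion.

## Problem sizes used in the automated checks

The calibration checks use 10 null datasets of 2000 multi-UTR genes; the
recovery and stratified-control checks use 20 datasets at the full default
design (4000 multi-UTR genes); the chi-square oracle sweep covers every
2×2 table with margins ≤ 20; the BH oracle covers all p-vectors of length
≤ 6 over a 5-value grid; decay recovery uses 100 series at 5%
multiplicative noise. The acceptance script runs one full planted design,
five null datasets and 100 decay series.

## Known limitations

* The usage test's genomic-control factor assumes most genes are null; in
  a dataset where the majority of genes change usage it would overcorrect.
* The NB Wald test has no dispersion shrinkage or outlier handling, and no
  covariates; it is a two-group test only.
* Exact numerical agreement with DESeq2/DEXSeq is not a goal; those tools
  differ by shrinkage, GLM fitting and filtering details.
* PAU requires exactly one SU and one LU isoform; >2-isoform genes are out
  of scope.
* The chi-square enrichment treats genes as independent; co-regulated gene
  clusters would inflate significance on real data.
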