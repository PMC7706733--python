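# Methods

This note documents the models implemented in `hybridexpr`, the
assumptions behind the synthetic-data generator, and the numerical and
design choices that were genuinely open.

## Differential expression engine

Counts are modelled as K_gj ~ NB(mean = s_j q_gc, dispersion α_g): s_j
is the sample's size factor, q_gc the group mean of gene g in condition
c, and Var(K) = μ + α μ².

**Size factors** are median-of-ratios: with reference genes those having
no zero count in any sample, s_j = median_g (k_gj / geometric-mean_g).
No post-hoc rescaling is applied, so factors are defined exactly by
this formula.  When no gene is all-positive the estimator is undefined;
a `pseudo_reference` flag switches to geometric means over positive
counts only (median of positive ratios).  A consequence of the
no-rescaling convention worth knowing: scaling one library by c scales
its factor by c only *relative to the other samples* (all factors also
absorb a common c^(1/m) through the geometric means), which is what
normalization cancels.

**Dispersions** are estimated in three steps. (1) A pooled within-group
method-of-moments estimate per gene, α̂ = max(0, (var − mean)/mean²) on
normalized counts. (2) A mean–dispersion trend α(μ) = a₀ + a₁/μ fitted
by iterated least squares with outlier exclusion (genes whose ratio to
the current fit falls outside [1e-4, 15] are dropped and the fit
repeated). (3) A posterior-mode shrinkage of log α̂ toward the log
trend; the sampling variance of a log dispersion estimate is
approximated by trigamma((m − p)/2) for m samples and p groups, and the
prior variance defaults to 0.25 (configurable).  Genes with α̂ = 0
(e.g. constant counts) take the trend value directly, floored at 1e-8.
The prior variance is fixed rather than estimated because with 13
samples the hyper-estimate is unstable and the Wald calibration is
insensitive to it within a factor of a few.

**Wald test.** Per gene, a log-link NB GLM with a two-level group factor
is fitted by vectorized IRLS at fixed dispersion, with log s_j offsets
and a weak always-on ridge (precision 1e-6) on the group coefficient so
that genes with all-zero counts in one group converge to large finite
fold changes instead of diverging.  The Wald statistic uses the Fisher
information without the ridge; p-values come from the standard normal,
BH-adjusted over tested genes.  Genes with zero counts in all samples
of the contrast are "untested".  DE means adjusted p < 0.05.

**Shrunken fold changes** are MAP estimates under a zero-centred normal
prior on the group coefficient, computed by the same IRLS with the
prior precision added.  The prior variance, unless fixed, is estimated
as the excess variance of high-information MLE fold changes (genes with
below-median standard error): Var(lfc) − mean(se²), clipped to
[1e-3, 100] on the natural-log scale.  Shrinkage therefore vanishes as
the prior variance grows, strictly reduces |LFC| otherwise, and
affects low-count genes most — the properties the classifier relies on.

**Transform for ordination.** The regularized-log transform that
inspired this step is replaced by log2(k/s + 1).  It is monotone,
depth-invariant and preserves the distance structure PCA needs; the
difference matters only for genes near zero counts, which carry little
ordination weight.

## Expression structure

TPM is computed from counts and effective lengths (rate = count/length,
scaled to 10⁶ per sample).  τ follows Yanai's index on per-tissue mean
expression; because the index is scale-sensitive and the choice of
input scale is a convention, values are log2(x + 1)-damped by default
(`tau_log_transform`).  The cross-species consensus τ is the first
principal component of the per-species τ vectors, sign-fixed to
correlate positively with the mean τ and min–max rescaled to [0, 1].
The expressed-gene census counts genes with within-group mean TPM
strictly above 1 (a boundary value of exactly 1.0 is not counted).

PCA centres genes across samples and uses the SVD; projection of
held-out (hybrid) samples applies the stored centring vector and
loadings, so projecting a training sample returns its own score and the
map is linear.  Between-groups PCA reports the percentage of total
(gene-centred) variance carried by the group means; significance is a
Monte-Carlo test with p = (#{permuted ≥ observed} + 1)/(B + 1),
B = 99 by default, so the smallest attainable p is 0.01.  Conditioning
on a second factor (species given tissue) is implemented as within-level
centring plus permutations restricted within levels — the standard
partial between-groups analysis.

## Inheritance modes and misexpression

With t = log2(1.125) and (x, y) the shrunken hybrid-vs-parent fold
changes, the six regions partition the plane (see the module docstring
for the exact inequalities).  Boundary values |x| = t count as beyond
the threshold: the event has measure zero and a deterministic rule is
required.  Classification uses shrunken fold changes — raw fold changes
of low-count genes scatter far from the origin and would inflate every
non-conserved class.  The type II regression is the major axis: the
first eigenvector of the 2×2 covariance through the centroid.

Misexpression is called among genes conserved between the parents
(CP not DE): it requires DE in both hybrid contrasts and, by default,
sign-consistent hybrid fold changes (`require_sign_consistency`), so
that "misexpressed" coincides with the over/underdominant geometry
rather than including additive-like sign-discordant genes.  The switch
exists because the definition of the hybrid-DE pair does not itself fix
the sign convention.

## Allele-specific expression

The gene-level test aggregates phased SNPs of one gene in one
individual.  Under the null every haplotype-A count is
beta-binomial(n, 0.5, ρ); under the alternative the SNPs share a ratio
r estimated by maximum likelihood (bounded scalar optimization; at
ρ = 0 the model is binomial and r̂ = ΣA/Σn is closed-form, making the
test reduce exactly to the binomial LRT).  The statistic is compared to
χ²(1).  ρ is a per-individual genome-wide method-of-moments estimate
around ratio 0.5 over all SNPs (E[(a − n/2)²] = (n/4)(1 + (n − 1)ρ)),
clamped to [0, 0.5], with a configurable fallback (default 0.05) below
50 informative SNPs.  Estimating ρ from all SNPs makes the estimate
conservative when many genes are truly imbalanced; this is the price of
not modelling a per-gene ρ, and it biases the test toward fewer false
positives.

Filters precede testing: per-SNP total coverage ≥ 10 and minor-haplotype
depth strictly greater than 2, then ≥ 2 surviving SNPs per
(gene, individual, tissue).  "Allelic depth greater than 2" is read as
min(A, B) > 2 — the strict minor-allele reading — and is configurable
because per-allele readings are also defensible.  BH adjustment is
applied within individual × tissue; the population rule then calls a
gene ASE when ≥ 2 individuals reach adjusted p < 0.05, untested when
fewer than 2 individuals were tested.  The rule does not require the
significant individuals to agree in direction; direction concordance is
deliberately not imposed because segregating variation can produce
genuine opposite-direction ASE in different individuals.

## Regulatory inference

Association tests operate on autosomal genes.  Mann–Whitney tests are
two-sided with a separate direction flag (sign of the median
difference); exact enumeration is used when both groups have ≤ 10
observations and no tied values, otherwise the tie-corrected normal
approximation with continuity correction.  The compensation test is a
Pearson χ² with Yates continuity correction (|O − E| − 0.5 floored at
0) on the misexpressed × ASE 2×2 of CP-conserved genes; an empty margin
returns an untestable "NA" result rather than an error.  The fast-Z
test is the one-sided hypergeometric tail P(X ≥ de_Z) with the
tissue's own expressed, chromosome-assigned genes as background, Holm-
adjusted across tissues.  GLM determinants regress the 0/1 DE indicator
(logistic) or |shrunken LFC| (OLS) on z-scored covariates,
complete-case only; z-scoring makes the per-covariate statistics
comparable since the covariates live on very different scales.

## Synthetic-data generator

The generator emulates the study design: 5 + 5 parental and 3 hybrid
males, five tissues, one library per individual × tissue.  Per gene it
draws a baseline mean (log2-uniform in [5, 10], i.e. 32–1024 counts), a
dispersion (lognormal, median 0.01, log-sd 0.5) and per gene × tissue a
baseline offset (log2-normal, sd 1.0) that makes tissue identity the
dominant axis of variation, as in real multi-tissue data.  Library
sizes are lognormal (log-sd 0.15) unless fixed.

Per gene × tissue an inheritance mode is drawn from `mode_fractions`
(remainder conserved); divergent modes place the parental means
±effect/2 log2 units around the baseline (|LFC| is the configured
effect size exactly, default 1.0) and the hybrid mean at the log-scale
midpoint (additive), at one parent (dominant), or ±effect beyond the
(equal) parental means (over/underdominant).  The regulatory regime is
drawn conditionally on the mode so the truth invariants hold by
construction: divergent modes are cis or trans (weights from
`regime_fractions`), over/underdominant modes are compensatory or null,
conserved genes are null.  Hybrid allelic ratios follow the regime:
cis genes have collared-haplotype fraction 2^lfc/(1 + 2^lfc) (2:1 at
one log2 unit), compensatory genes carry the hidden cis shift of the
configured effect size, trans/null genes are balanced.  Parental SNPs
are balanced unless a (gene, individual) draws segregating within-
species ASE (probability 0.05, ratio from a Beta(2,6)/Beta(6,2)
mixture) — so parental ASE exists without between-species divergence.
Allelic counts are beta-binomial with overdispersion ρ = 0.02; SNP
counts per gene are 2 + Poisson(4) and coverages gamma-Poisson with
mean 30 (shape 10); 5% of SNPs are generated to violate the
coverage/depth filters, standing in for the mapping-bias removal that
happens upstream of this pipeline.  CNE fixed-difference flags are
Bernoulli with probability 0.3 for cis-regime genes and 0.1 otherwise.

All distributional defaults are modelling assumptions chosen to be
realistic for a well-controlled bulk RNA-seq comparison of closely
related vertebrates — they are not estimates from any data set, which
publishes no empirical dispersion or effect-size distributions usable
for that purpose.  A single seed is split into independent child
streams (counts, alleles, annotation), so adding one generator call
never perturbs the others and identical configurations reproduce
bit-identical tables.

What the generator does *not* emulate: read-level artefacts (mapping
bias beyond the filter-violating fraction, phasing error, duplicate
reads), correlated dispersion–mean structure beyond the fitted trend,
within-species expression polymorphism beyond the NB noise, and any
cell-type composition signal.  Passing tests therefore demonstrate that
the inference chain is correct and well calibrated under its own model
assumptions, not that those assumptions hold for any particular real
data set.

## Problem sizes and numerical choices

Test and acceptance simulations use 600–2000 genes with the study's
5/5/3 design — large enough that binomial confidence intervals on
calibration rates are a fraction of the tolerances, small enough to
keep the whole suite inexpensive.  Calibration checks use the 95%
binomial interval around the nominal 0.05.  IRLS iterates to a 1e-6
coefficient tolerance (maximum 100 iterations, non-converged genes
reported as untested); the beta-binomial MLE uses bounded Brent search
with 1e-10 tolerance; fixed-precision scientific notation (6
significant digits) is used for all numeric TSV output so files diff
stably across platforms.  Known limitations: no Cook's-distance outlier
handling, no independent filtering before BH by default (off-by-default
flag), single-factor designs only, and no significance-based
(McManus-style) classification variant.
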