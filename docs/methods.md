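# Methods

This note documents the statistical procedures implemented in `rvbench`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Genotype model and MAF

All analysis operates on dominant-coded genotypes: 1 iff the individual
carries at least one minor allele. When raw allele counts are available
(VCF input) the minor allele frequency is the exact allele fraction, the
minor allele being determined per site by cohort allele count with ties
broken to ALT. When only the collapsed 0/1 matrix is available, MAF is
recovered from the carrier fraction *f* under Hardy–Weinberg
equilibrium, `q = 1 − √(1 − f)`, folded to `min(q, 1 − q)` so the result
stays in [0, 0.5]. Both pathways are exposed because collapsed matrices
do not retain allele counts; on HWE data they agree within binomial
sampling error (tested). Missing VCF genotypes are coded non-carrier
with a logged count — conservative for burden counts — and multiallelic
records are skipped.

SNP-set selection mirrors the three standard analysis sets: rare-only
(MAF < 5% by default), all SNPs, and nonsynonymous-only. Genes left
without SNPs are dropped from the gene map.

## The four tests

**CMC.** SNPs with MAF < 0.01 (configurable) are collapsed into one
carrier indicator; other SNPs keep their own columns. The case and
control design matrices are compared by the two-sample Hotelling T² with
pooled covariance; p comes from the F transform
`F = T²·(n₁+n₂−k−1)/((n₁+n₂−2)k)` on (k, n₁+n₂−k−1) df. A
rank-deficient pooled covariance (common with collinear collapsed
designs of rare indicators) is handled by the Moore–Penrose
pseudo-inverse with k replaced by the effective rank; a covariance of
rank 0, or n₁+n₂−k−1 ≤ 0, is reported degenerate with p = 1. An F
rather than a chi-square reference was chosen because it is the exact
small-sample transform under multivariate normality; at the simulated
sample sizes the difference is small.

**WS.** Variant weights are `w_j = √(n q̂_j (1 − q̂_j))` with
`q̂_j = (m_j^U + 1)/(2(n^U + 1))` estimated from the unaffected group
with +1 pseudo-counts; under dominant coding the carrier count stands in
for the minor-allele count. Individual scores `Σ_j x_ij / w_j` are
ranked over the whole cohort with midranks for ties, and the statistic
is the rank sum over the affected. Estimating weights from the
unaffected only is the default (a `weights_from="pooled"` switch
exists): weights that depend on the phenotype are recomputed inside
every permutation, which the vectorised batch implementation does
exactly.

**PR.** The predictor is the fraction of the gene's loci carried.
The logistic fit is Newton/IRLS (via statsmodels) with tolerance 1e-8
and 50 iterations; the test is the two-sided Wald z on the slope. A
constant predictor, non-convergence, or a diverging slope (|β₁| > 30 on
a [0, 1] predictor, the signature of separation) yields a degenerate
outcome with p = 1 rather than a spurious extreme p.

**CMAT.** The 2×2 table counts carried vs non-carried loci in cases and
controls (`A = m·n_cases` slots, etc.); the statistic is the Pearson
chi-square with 1 df and no continuity correction, degenerate-to-zero
when a margin is empty. Because carried loci within an individual are
not independent, significance is always assessed by phenotype
permutation, never by the chi-square reference.

**Stratified CMAT.** Per-stratum 2×2 tables are pooled in
Mantel–Haenszel form, `(Σ_s (a_s − E_s))² / Σ_s V_s`, with E and V the
hypergeometric mean and variance of `a_s` under fixed margins. Strata
lacking cases or controls are skipped with a warning; significance is by
within-stratum permutation, which preserves each stratum's case/control
margins and hence removes the confounding signal from the null. With a
single stratum the procedure reproduces the unstratified CMAT
permutation p exactly (same seed), since both statistics are monotone
transforms of (a − E)² at fixed margins.

**Permutation engine.** p = (1 + #{stat_perm ≥ stat_obs})/(B + 1) with
B = 1,000 by default — the add-one convention avoids p = 0 and bounds p
below by 1/(B+1). Permutations are uniform shuffles of the phenotype
vector (within strata when given). Every grid cell derives its own seed
from the master seed and the (method, gene, replicate) indices via
numpy `SeedSequence` spawn keys, so any single cell is reproducible in
isolation and grids are deterministic end to end.

## Evaluation statistics

*Discovery summaries* report, per method and α ∈ {0.05, 0.005}: mean
significant genes per replicate, mean causal significant, true-discovery
% (NaN when nothing is significant), and false-/true-positive rates over
noncausal/causal gene×replicate cells. Degenerate cells carry p = 1 and
count as non-significant.

*Spurious-gene classification.* A noncausal gene is spurious when every
one of the four base methods finds it significant (p < 0.05) in at least
`c` replicates, where `c` is the smallest count with
Bin(n_reps, 0.05) CDF ≥ 0.96, computed by exact pmf summation (16 for
200 replicates). The count convention is the percentile one —
`P(X > c) ≤ 1 − percentile` — and the result is floored at 1 so a
degenerate α = 0 null never labels genes. The 0.05 cut and the
percentile are configurable; 0.05 is deliberately sensitive, since the
point of the classifier is to collect genes for covariate analysis, not
to control family-wise error.

*P* is the per-replicate Pearson chi-square of the 2×K status ×
population table (no continuity correction; empty populations dropped;
NaN when fewer than two remain). Its Pearson correlation with the
per-replicate significant-gene count measures how strongly a method's
discoveries track stratification.

*G* is the r² from OLS of one noncausal SNP's genotypes on all causal
SNPs' genotypes, with intercept (the standard r² definition; the
no-intercept variant is not offered), pseudo-inverse under
collinearity, clipped to [0, 1], NaN for constant SNPs. Under
independence its null expectation is ≈ k/(n−1) for k causal predictors.

*S* is the mean squared Pearson correlation over random cross-chromosome
SNP-column pairs (100,000 by default), sampled with replacement;
same-chromosome or constant-column draws are rejected and redrawn. The
permutation null permutes rows independently within each column —
destroying all between-column correlation while preserving every
column's carrier count — and recomputes S B times;
`Z = (S_obs − mean_null)/sd_null`. For independent Bernoulli columns
E[r²] ≈ 1/(n−1), so S is small but nonzero in any finite sample; the Z
score asks whether the observed correlation exceeds that chance level.

*Power–effect correlation*: per causal gene, the number of replicates
significant at α versus the aggregate effect `Σ_j MAF_j·β_j`; Pearson r
per method, NaN below 3 causal genes or at zero variance.

## Synthetic data

The generator produces the study conditions everything above is
exercised under. Ancestral frequencies follow Beta(0.25, 12.12) — the
second shape solved so that 87% of frequencies fall below 0.05, matching
the rare-variant share of a typical mini-exome panel — truncated below
at 0.001 and above at 0.5 by redraw. Per-population frequencies follow
the Balding–Nichols model, Beta(q(1−F)/F, (1−q)(1−F)/F), with
F_st = 0.10 by default (continental-scale differentiation); F_st = 0
copies q exactly. Genotypes are Bernoulli draws of the diploid carrier
probability 1 − (1−q)². Gene sizes are a shifted Poisson with mean 7.6
clipped to [1, 50]; genes are assigned to chromosomes round-robin so
cross-chromosome pair sampling is always possible.

Phenotypes follow a logistic liability:
`P(affected) = logistic(intercept_pop + Σ_{j causal} β_j x_ij)` with a
baseline prevalence of 30% and causal β drawn uniformly from
[0.5, 2.0] log-odds units — large enough that causal genes are
detectable at the scaled sample size while leaving power well below 1,
the regime of interest. At full scale ~1.15% of genes are causal with
1–8 causal SNPs each; the scaled test profile (200 individuals, 2
populations, 150 genes, 20 replicates) raises the causal fraction to 8%
so that causal-gene statistics (power–effect correlations need ≥3
genes) are defined at 150 genes. Causal SNPs are flagged nonsynonymous;
55% of all SNPs carry the flag. The confounding scenario spreads the
per-population intercepts symmetrically by ±strength, leaving β
untouched, so confounded and matched unconfounded runs differ only in
the phenotype mechanism. Replicates with zero cases or controls are
redrawn with a logged warning, capped at 100 attempts.

What the generator does **not** emulate: within-gene linkage
disequilibrium (SNPs are independent given population), relatedness,
genotyping error, unmeasured causal variants, and any non-logistic
disease architecture. Consequently, passing tests demonstrate the
methods' behaviour under idealised rarity + stratification + chance-GPD
conditions, not their behaviour on real sequence data, where LD and
systematic artefacts add further correlation. In particular, on this
generator's unconfounded output the S-permutation Z is calibrated
(|Z| < 3 almost always), whereas real panels can show substantially
larger Z.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the pipeline at the scaled
profile: 150 genes × 20 replicates × 200 individuals with B = 1,000
permutations (~1.5 minutes per four-method grid), chosen as the smallest
size at which the 3-Monte-Carlo-SE calibration band around 5% is
reasonably tight (±1.2 percentage points at 3,000 cells). Degenerate
statistics are reported as NaN markers, serialised "NA" in TSV, never as
numeric sentinels. Asymptotic p-values are floored at the smallest
positive float to keep them in (0, 1].

## Known limitations

Permutation tests at B = 1,000 are slightly conservative at α = 0.05
for genes with few carriers (ties in the permutation distribution), so
the null false-positive rate of CMAT typically lands a few tenths of a
percentage point below 5%. The WS weight estimate uses unaffected-only
carriers; with very unbalanced case/control splits the weights are
noisy. The Hotelling F reference assumes approximate normality of group
means — adequate at n = 200 but optimistic for genes whose every column
is nearly constant. The stratified CMAT requires each contributing
stratum to contain both cases and controls; heavily confounded draws can
lose strata.
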