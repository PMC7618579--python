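# Methods

pleiokit implements the summary-statistics toolchain used to study the
common-variant architecture of a rare trait by borrowing strength from
better-powered, genetically related traits.  This note records the models,
estimators, defaults and numerical choices, what the synthetic data do and
do not emulate, and the design decisions taken where the problem was
genuinely open.

## Harmonisation

Summary-statistic sets are per-variant tables keyed by
`(chromosome, position, other allele, effect allele)` with effect size
`BETA` (log odds for case-control traits, per-SD units for quantitative
traits), its standard error, a two-sided p-value and optional effect-allele
frequency and QC fields.  All sets are aligned to a reference variant panel
(canonical allele order plus reference minor-allele frequency): a record
whose alleles match in reverse order is flipped (`beta := -beta`,
`eaf := 1 - eaf`, alleles swapped); a record matching in neither order is
dropped.  Strand-complement rescue is deliberately not attempted — inputs
are assumed verified positive-strand, and silently complementing A/T and
C/G sites is a classic source of sign errors.

Missing effects are recomputed from odds ratios and p-values as
`beta = ln OR`, `|z| = Phi^-1(1 - p/2)`, `se = |beta|/|z|`.  A p-value of
zero is clipped to the smallest positive double rather than dropped, so
`-log10 p` stays finite downstream; an OR of exactly 1 with no stated SE is
dropped because its SE is undefined.

Variant QC removes records with imputation info < 0.4, Hardy-Weinberg
p < 1e-6, reference MAF < 0.001, or |beta|/se > 10, all strict
inequalities; filters whose fields are absent are skipped, and removals are
reported per filter so that counts plus survivors always equal the input.
Genome-wide analyses of shared architecture exclude the extended MHC
(chr6:24,000,000-45,000,000, inclusive), whose long-range LD is
unrepresentative of the genome.  Coordinates are 1-based and intervals
inclusive throughout.

## Synthetic data

The generator emulates the *statistical* structure the downstream methods
consume, not individual-level genetics.  A panel of `n_snps` variants on
two chromosomes is partitioned into contiguous blocks; within a block,
haplotype dosage correlation is AR(1) (`corr(i,j) = rho^|i-j|`, default
rho 0.9, blocks of 20) and across blocks exactly zero.  This makes pairwise
r² closed-form (`rho^(2|i-j|)`) — the LD "matrix" is evaluated, never
estimated — and gives pruning an analytically checkable structure.  Genes
are placed on a spacing grid (>= 110 kb between bodies) so 50 kb flanks
never bridge neighbours.

A trait pair shares one causal-variant set (per-SNP probability
`pi_causal`, multiplied by `enrichment_boost` inside the special gene
subset); standardised causal effects are bivariate normal with correlation
`rho_shared` and variance `h2 / E[#causal]`.  Marginal (LD-convolved)
effects are obtained by propagating causal effects through the block AR(1)
correlation with two O(n) recursions.  Observed z-scores add unit-variance
noise carrying the same within-block AR(1) correlation — a design choice:
purely independent noise would make LD pruning cosmetic, whereas correlated
noise reproduces the dependence structure that motivates pruning before the
two-groups fit.  Noise is independent between traits (non-overlapping
cohorts).  Standard errors follow the classical approximations
`se = 1/sqrt(2 n maf (1-maf))` for a standardised quantitative phenotype
and `se = sqrt((1/n_cases + 1/n_controls) / (2 maf (1-maf)))` on the
log-odds scale.

Not emulated: population structure and confounding, in/dels and
multi-allelic sites, recombination-map LD, allele-frequency spectra, study
heterogeneity, sample overlap between traits.  Passing calibration tests
on these data therefore demonstrates correctness of the estimators under
their own assumptions, not robustness to the pathologies of real GWAS.

Default study conditions (used throughout the tests): 10,000 SNPs in 500
blocks, MAF uniform on (0.01, 0.5), 1% causal variants, heritability proxy
0.2 per trait, quantitative sample size 20,000, case-control 2,000 cases /
20,000 controls, 400 genes with a 40-gene special subset.  All generators
are bit-reproducible given (seed, config).

## Meta-analysis and genomic control

Fixed-effect inverse-variance weighting:
`beta* = sum(w_i beta_i)/sum(w_i)`, `w_i = 1/se_i^2`,
`se* = sum(w_i)^(-1/2)`, two-sided normal p.  Which SNPs enter is decided
by the join (the anchor study's SNPs under a left join), not by the
estimator; a study missing at a variant contributes no weight.

Genomic control computes `lambda = median(chi2)/0.45494` (the chi-squared
1-df median) from the p-values and, only when lambda > 1, divides the
chi-squared statistics by lambda; deflation is never applied.  In the cFDR
pipeline the correction is applied to the principal trait only, in the
first iteration only, to enforce the method's assumption of uniform
principal p-values under the null.

## Gene-set enrichment

Per-SNP statistics are the chi-squared values implied by the two-sided p.
The observed 50th/90th/95th/99th percentiles of statistics at SNPs inside
the flanked special regions (union semantics, each SNP counted once) are
compared with the same percentiles in `B` resamples (default 5,000) of
equally many genes drawn uniformly without replacement from the full
catalogue, regions rebuilt per resample.  The per-level p is the plain
proportion of resamples at or above the observed percentile; an exact zero
is reported as "< 1/B" (an add-one correction is available behind a flag,
off by default).  Percentiles use linear interpolation between closest
ranks, identically for observed and resampled values, which keeps the
comparison exchangeable.  The sampling frame includes the special genes
themselves unless excluded by flag.

## GPS test

For paired p-value vectors (MHC removed, pruned to r² < 0.8), the
statistic is `sqrt(n/log n) * max_i |F_uv(u_i,v_i) - F_u(u_i) F_v(v_i)| /
sqrt(F_u F_v (1 - F_u F_v))` with right-continuous ecdfs (denominator n);
terms with zero weight — the corner where both margins reach 1 — are
skipped.  The statistic is rank-based and symmetric.  Its null is
calibrated by permuting one margin (which preserves both marginals and
destroys dependence); `p = (1 + #{perm >= obs})/(n_perm + 1)` with
`n_perm = 1000` by default.  An optional maximum-likelihood generalised
extreme-value fit to the permutation statistics gives a smooth tail p,
falling back to the permutation p with a warning if the fit fails.  The
bivariate ecdf evaluation uses a Fenwick tree compiled with numba,
O(n log n) per statistic.

## Conditional FDR

For principal p and auxiliary q over the same SNPs, the empirical
conditional FDR at a point is

    cfdr(p, q) = p * (1 + #{j: q_j <= q}) / (1 + #{j: p_j <= p, q_j <= q})

capped at 1 when reported.  The two-groups null for Q given no principal
association is `pi0 * foldedN(0,1) + (1-pi0) * foldedN(0, sigma^2)` on the
z-scale, fitted by bounded L-BFGS-B maximum likelihood (multiple starts;
pi0 in [0,1], sigma in [1,100]) on the r² < 0.2 pruned subset restricted
to principal p > 0.5 — the principal-null proxy — requiring at least 50
points.  A vanishing complexity penalty (one log-likelihood unit times
1 - pi0) selects the null-heavy representation on the sigma -> 1 ridge
where the mixture is unidentifiable; it shifts identified optima by O(1/n).

### v-values

A SNP's v-value is the probability, under the fitted null joint
distribution (P' uniform and independent of Q'), of the region of the unit
square where the empirical cFDR is at or below the SNP's own level.  The
pinned construction:

* the level is the leave-one-out empirical cFDR at the observed pair,
  *uncapped* so the level functional is strictly increasing;
* the region is the raw sub-level set of the full-data empirical cFDR.
  Within a q-slice with m member pairs the estimator is piecewise linear
  in p' (slope `(1+m)/(1+k)` on the segment holding k members), so the
  p-axis measure of the sub-level set is computed exactly from prefix sums
  over segments ordered by their entry (`a_k P_k`) and saturation
  (`a_k P_{k+1}`) thresholds;
* the measure is a step function of q' — it changes only where a data q
  crosses the slice threshold — so when the distinct q values fit within
  the grid budget (default 500) the q'-integral is evaluated *exactly* on
  slices at the data values, weighted by the fitted null CDF of Q.  Above
  that size, slices sit on a uniform grid of the auxiliary z-scale from 0
  to `z(q_min) + 1`; member entries inside a grid interval are allocated
  by their actual null mass (exact when at most one entry falls in an
  interval), with an analytic term for the tail beyond the grid.  The
  residual grid error shrinks roughly linearly in the grid size and is
  below ~1e-3 at the default for n = 10,000 — negligible against the
  sampling noise of the quantities the calibration tests measure, and
  identically zero once the grid covers the data.

This makes the v-value a probability integral transform of the cFDR level:
under the joint null v is uniform (Kolmogorov-Smirnov-clean at n = 10,000),
and when the auxiliary is uninformative v reproduces p (mean relative
error under 2 %; single SNPs at extreme auxiliary quantiles deviate more
because their leave-one-out counts are O(1)).  An earlier variant that
monotonised the estimator along p before inversion was rejected: the
running-maximum direction is dominated by the estimator's spike below the
smallest observed p, and the opposite envelope is flat over large regions,
creating conservative atoms; the raw sub-level measure has neither defect
and needs no monotonisation for the inversion.  Nesting of regions in the
level holds by construction.  Monotonicity of v in p at fixed q holds up
to the local non-monotonicity of the raw leave-one-out level itself.

### Iteration

Auxiliary traits are conditioned on in a stated order: iteration 1 applies
genomic control to the principal p, left-joins the first auxiliary, prunes
(r² < 0.2, significance-first order) for the fit subset only, fits the
two-groups null, and computes v-values for every SNP with auxiliary data;
SNPs missing the auxiliary carry their input forward bit-unchanged and
flagged.  Later iterations feed the previous v-values in as principal
input.  More auxiliaries than the configured maximum (default 3) are
refused, because iterative conditioning on strongly dependent covariates
can lose type-1 error control.  Auxiliary p-values are not themselves
GC-corrected.  The final v is compared against 5e-8 for the significance
call.

## LD pruning

Greedy: variants are visited in ascending principal p (most significant
retained first; ties broken by chromosome and position) or in position
order, and kept when their r² with everything already kept stays below the
threshold.  Significance-first retention maximises retained signal and is
deterministic; on the interval structure of block-AR(1) LD, position-order
greedy additionally attains the maximum-size subset (verified against
exhaustive enumeration).  The retained set never violates the constraint,
checked post hoc in the tests on every call.

## Mendelian randomisation and colocalisation

`mr_ivw` pools per-instrument Wald ratios `theta_j = b_out/b_exp`,
`se_j = se_out/|b_exp|` by inverse variance — algebraically a weighted
regression of outcome on exposure effects through the origin, which is the
oracle it is tested against.  Instruments with a zero exposure effect are
rejected.  Fixed-effect weighting only; MR-Egger/median estimators are out
of scope.

`coloc_abf` computes per-SNP Wakefield log approximate Bayes factors
`0.5 log(1-r) + 0.5 r z^2` with `r = W/(W + se^2)`, prior effect sd 0.2
(quantitative) or 0.15 (case-control), and accumulates the five regional
hypothesis sums in log space (`S3 = S1 S2 - S4`, clamped at zero if
floating error makes it negative), with per-SNP association priors
p1 = p2 = 1e-4, p12 = 1e-5 — the method's published defaults, since only
"default priors" is specified.  Posteriors PP0..PP4 are normalised with
log-sum-exp.

The instrument screen runs colocalisation on a 100 kb window around each
instrument and excludes it when PP3 (distinct causal variants) exceeds 0.5
— evidence of an outcome effect not mediated by the exposure.  The 0.5
cutoff is this package's operationalisation; the source analyses report
which instruments were excluded but not the rule.  Instruments without
regional data are kept with a warning.

Benjamini-Hochberg adjustment is delegated to statsmodels and checked
against a brute-force step-up implementation; the Wald test is
`p = 2 Phi(-|est/se|)`.

## Problem sizes in the test-suite

Calibration suites run at the default study conditions: the 3-iteration
cFDR null at n = 10,000 SNPs over 50 seeds; GPS type-1 error over 200
replicate pairs of 5,000 SNPs with 199 permutations each (199 gives 0.05
resolution at the tested level); enrichment calibration over 200 repeats
of a 4,000-SNP genome with an 80-gene frame, 10 special genes and B = 100
resamples; two-groups recovery over 50 fits of 10,000 points; MR coverage
over 500 replicates of 25 instruments.  Oracle-equivalence tests use
exhaustive enumeration on instances of at most 10 variants and 2-D
quadrature on 20-SNP toys (tolerance 1e-3).

## Known limitations

* The v-value construction is this package's own pinned variant of the
  conditional-FDR idea; it is verified against an independent quadrature
  oracle and its own calibration criteria, not bit-compatible with any
  external implementation.
* The AR(1) block-LD world has no long-range LD, so MHC-style pathology is
  represented only by the exclusion interval, never stressed.
* Case-control statistics are generated directly on the log-odds scale;
  rare-disease ascertainment effects and case-control imbalance beyond the
  effective-sample-size approximation are not modelled.
* The GPS GEV tail fit is a convenience for small permutation p-values;
  for p far below 1/n_perm its extrapolation is unverified.
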